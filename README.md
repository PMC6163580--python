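# peptergent

Analysis toolkit for coarse-grained (CG) simulations of *peptergents* —
short amphipathic peptides that act like detergents, wrapping membrane
proteins in a belt of antiparallel beta strands. Given CG structures or
trajectories (GRO or PDB, one bead per residue backbone position), the
package answers the questions such studies turn on:

- **How much beta structure is there, and how is it arranged?**
  A backbone-bead beta criterion (pseudo-dihedral + cross-strand
  contact), strand segmentation, sheet pairing with orientation and
  registry, and strand tilt against a membrane normal.
- **How much protein surface do the peptides cover?**
  Shrake–Rupley solvent-accessible surface areas (SASA) on CG beads and
  the buried interface between two groups,
  `(SASA_A + SASA_B − SASA_AB) / 2`.
- **How do detergents and peptides aggregate?**
  Single-linkage clustering of molecules, residue contact maps, and a
  hydrophobic-burial score.
- **Is a candidate sequence a plausible peptergent?**
  Amphipathy checks: strict hydrophobic/hydrophilic alternation, net
  neutrality, and charge complementarity between the sequence halves.

Because real CG trajectories are microseconds of MD, the package also
ships deterministic **synthetic generators** — ideal sheets and barrels,
self-avoiding coils, a seven-helix bundle "membrane protein", and seeded
detergent shells — so every analysis can be validated against fixtures
with known ground truth.

## Worked example

```python
from peptergent import synthetic as syn
from peptergent import assign_beta, beta_fraction, find_strands, pair_strands
from peptergent import interface_area, SASAParams
from peptergent.assembly import cluster_molecules

# two ideal antiparallel strands, one residue out of register
system, frame = syn.make_sheet(2, 10, orientation="antiparallel", registry_shift=1)
assignment = assign_beta(frame, system)
print(f"beta content: {beta_fraction(assignment):.1f}%")

strands = find_strands(assignment, system, frame)
pairing = pair_strands(strands, frame, system)[0]
print(f"pairing: {pairing.seg_a.chain_id}-{pairing.seg_b.chain_id} "
      f"{pairing.orientation}, registry shift {pairing.registry_shift}")

# a membrane-protein mimic wrapped in three seeded detergent patches
protein = syn.make_cylinder_protein()
shell_sys, shell_frame = syn.make_detergent_shell(
    protein, n_detergent=24, seed=7, n_patches=3
)
area = interface_area(
    shell_frame, shell_sys,
    shell_sys.group("protein"), shell_sys.group("detergent"),
    SASAParams(n_sphere_points=240),
)
print(f"protein-detergent buried interface: {area.area:.2f} nm^2")

clusters = cluster_molecules(shell_frame, shell_sys, "detergent", cutoff=0.6)
print(f"detergent aggregates: {clusters.n_clusters} "
      f"(sizes {sorted(clusters.sizes.values())})")
```

Output:

```
beta content: 100.0%
pairing: A-B antiparallel, registry shift 1
protein-detergent buried interface: 14.19 nm^2
detergent aggregates: 3 (sizes [8, 8, 8])
```

## Command line

The `peptergent` command wraps the same analyses. Every numeric default
comes from the parameter dataclasses; a YAML config can set any of them
and explicit flags win. Each run writes a `<stage>.log` echoing the
fully resolved parameters.

```
peptergent fixtures detergent_shell --n-detergent 24 --n-patches 3 \
    --seed 7 --out-dir shellfx
peptergent clusters shellfx/fixture.gro --molecule-group detergent \
    --group 'detergent=res:PCH,DTL' --out-dir out
peptergent interface shellfx/fixture.gro \
    --group 'protein=res:LEU,SER' --group 'detergent=res:PCH,DTL' \
    --group-a protein --group-b detergent --out-dir out
peptergent beta sheet.gro --trajectory assembly.gro --out-dir out
peptergent design VKVKVKVEVEVE
peptergent report system.gro --config analysis.yaml --out-dir out
```

GRO files carry no chain identifiers, so groups are selected by residue
name (`name=res:PCH,DTL`) or, for PDB input, by chain wildcard
(`name=D*`). Outputs are CSV/TSV with fixed float formatting, so
identical configurations reproduce identical bytes.

## Scientific conventions

- **Beta criterion.** A backbone bead *i* is beta when (a) the unsigned
  pseudo-dihedral over beads *i−1, i, i+1, i+2* of its chain exceeds
  100° and (b) two bonded consecutive backbone beads *j, j+1* — both
  within 0.6 nm of bead *i* — support it, where same-chain partners
  must be at least 4 positions away in sequence. Distances honour the
  minimum-image convention for orthorhombic boxes.
- **SASA.** Shrake–Rupley with a deterministic golden-spiral sphere
  sample (960 points by default), probe radius 0.256 nm and bead radius
  0.26 nm (regular CG particle). Only beads inside the analysed
  selection occlude one another.
- **Clustering.** One chain = one molecule; two molecules join an
  aggregate when any inter-molecular bead pair is within the cutoff
  (0.6 nm default), i.e. single linkage.

See `docs/methods.md` for derivations, fixture geometry, parameter
tables and numerical error bounds.

## Reproduction

```
pip install --no-build-isolation -e .[test]
python -m pytest -q tests/            # unit, property and acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script reports the package's headline quantities
(closed-form SASA errors, fixture beta content, registry recovery,
interface areas, micelle recovery, burial scores, design checks) as
JSON; rerunning with the same seed byte-reproduces the file. One
acceptance test (`test_criterion_1_bacteriorhodopsin_surface_area`)
downloads a PDB entry from the RCSB and fails on machines without
network access; everything else runs fully offline.
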