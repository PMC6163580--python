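# Methods

Models, parameters and numerical choices behind the `peptergent`
analyses, plus the geometry conventions of the synthetic fixtures and
their known limitations.

## 1. Coarse-grained data model

A structure is a flat list of beads (`peptergent.model.Bead`), one per
CG particle; bead names `BB` and `CA` mark the per-residue backbone
position. Chains are the ordered backbone beads sharing a `chain_id`;
consecutive backbone beads of a chain are bonded by construction.
Coordinates are in nanometres, times in picoseconds. Only orthorhombic
boxes are supported; triclinic input is rejected with an explicit error.
Minimum-image displacements use `d − L·round(d/L)` per axis.

File I/O:

- **GRO** (fixed-column) is parsed in-package so that malformed input
  produces line-numbered `ParseError`s. GRO carries no chain field, so
  chains are re-inferred from residue numbering (a decrease starts a new
  chain) and relabelled `A, B, C, …`. Multi-frame GRO files are
  concatenated blocks; frame times come from a `t=` tag in the title.
- **PDB** reading/writing delegates to biotite; coordinates are
  converted Å → nm, multi-model files become trajectories, and `CRYST1`
  supplies the box.

Residue hydropathy classes and bead radii come from a YAML table
(`peptergent/data/bead_classes.yaml` by default): the 20 standard amino
acids, the non-natural ADA (2-aminodecanoic acid, hydrophobic) and ABZ
(aminobenzoyl, hydrophobic) found in detergent-like peptides, and the
detergent bead residues PCH (polar head) / DTL (hydrophobic tail).
Unknown residue names fall back to class `other` with the default
radius rather than failing.

## 2. Beta-structure criterion

CG force fields keep no hydrogen bonds, so secondary structure is
assigned geometrically on backbone beads. Bead *i* of a chain is
**evaluable** when positions *i−1 … i+2* exist (chains shorter than 4
beads contribute none) and is **beta** when both hold:

1. **Extension.** The unsigned pseudo-dihedral of beads
   *(i−1, i, i+1, i+2)* exceeds `angle_min` = 100°. The dihedral is
   computed with the two-plane atan2 formula and folded to [0°, 180°],
   where 180° is the fully extended trans arrangement. Degenerate
   windows (coincident or collinear points) raise; inside
   `assign_beta` they simply mark the bead non-beta.
2. **Cross-strand support.** There exist bonded consecutive backbone
   beads *j, j+1*, both within `contact_dist` = 0.6 nm of bead *i*,
   with each partner either on another chain or at least
   `min_seq_sep` = 4 sequence positions away on bead *i*'s own chain.

The beta fraction of a frame is the percentage of evaluable beads in
the beta state. Candidate partners are found with a KD-tree (periodic
when the frame has a box), making the assignment O(n log n); the test
suite checks bead-for-bead equality against a naive triple-loop oracle
on randomized fixtures.

**Strand segmentation** groups runs of ≥ `min_strand_len` = 3
consecutive beta beads of one chain. **Pairing**: two segments pair
when their mean nearest-bead distance is below 0.7 nm. Orientation is
the sign of the dot product of the segment direction vectors.
**Registry** is the shift *s* (|s| ≤ 3) minimising the mean distance
between bead *k* of one full backbone chain and bead *k+s* of the other
(the antiparallel partner is traversed reversed); ties prefer smaller
|s|. Registry is computed over the full chains rather than the
truncated beta segments because the dihedral window removes one bead at
the N side and two at the C side of each strand, which would otherwise
bias the shift by the truncation asymmetry. **Tilt** is the acute angle
between a segment direction and a reference axis.

## 3. Surface areas and interfaces

SASA uses the Shrake–Rupley method: each bead's sphere of radius
*r + p* is sampled and a point counts as accessible when no other
selected bead's expanded sphere contains it. Parameters:

| parameter | default | rationale |
|---|---|---|
| probe radius *p* | 0.256 nm | radius of a regular CG water/particle |
| bead radius *r* | 0.26 nm | regular CG particle, from the class table |
| sphere points | 960 | see error bounds below |

Points are a deterministic golden-spiral (Fibonacci) lattice, so
results are exactly reproducible; neighbour search uses a KD-tree
prefilter. Occlusion counts **only beads inside the analysed
selection** — that is what makes the buried-interface identity below
meaningful. Periodic boundaries are not applied inside SASA; a warning
is emitted when a selection spans more than half the box, because a
molecule wrapped across the boundary must be made whole first.

Buried interface between disjoint groups A and B:

```
interface = (SASA(A) + SASA(B) − SASA(A ∪ B)) / 2
```

It is symmetric, non-negative, zero for distant groups and bounded by
min(SASA(A), SASA(B)); the suite asserts all four properties.

**Error bounds** (measured against closed forms): a single bead is
exact to < 1% at 960 points (the spiral integrates a full sphere almost
exactly); two overlapping spheres match the analytic spherical-cap
formula to ≤ 0.2% at 960 points over separations 0.15–0.9 nm, and the
error decreases monotonically with the point count. An independent
cross-check against `mdtraj.shrake_rupley` on a 20-bead sheet agrees to
< 1%.

**Hydrophobic burial** of a group = 1 − (context SASA of its
hydrophobic beads) / (their isolated-bead reference area 4π(r+p)²),
clamped to [0, 1].

## 4. Aggregates and contacts

Molecules are chains. Single-linkage clustering joins two molecules
when any inter-molecular bead pair is within the cutoff (default
0.6 nm, minimum image). Implementation: KD-tree pair enumeration plus
sparse connected components; cluster labels are the lowest member
molecule's ordinal, so output is deterministic. Contact maps list
residue pairs of two disjoint groups whose minimum bead distance is
within the cutoff.

## 5. Design heuristics

A peptergent candidate sequence (one-letter string or dash/space
separated three-letter tokens; non-natural residues via the class
table) is checked against four rules, each reported separately:

1. length equals the target (default 12),
2. hydrophobic/hydrophilic alternation ≥ 0.8 (fraction of adjacent
   pairs that alternate; charged residues count as hydrophilic),
3. positive net charge in the N-terminal half and negative in the
   C-terminal half (halves split at ceil(n/2)),
4. zero net charge.

## 6. Synthetic fixtures

All generators are deterministic; those that use randomness take a
`seed` and derive everything from `numpy.random.default_rng(seed)`.

Geometry constants: backbone bond 0.35 nm, backbone angle 140°,
inter-strand spacing 0.48 nm. Strands are built by NeRF extension with
a constant pseudo-dihedral.

- `make_strand`: lone zigzag strand, default dihedral 170° (slightly
  twisted, like real beta strands).
- `make_sheet`: parallel or antiparallel strands stacked 0.48 nm apart
  with optional integer registry shift. **Sheet strands are planar
  (dihedral 180°), not twisted.** At these constants the contact margin
  is √(0.48² + 0.35²) = 0.594 nm against the 0.6 nm cutoff, so any
  out-of-plane pucker > 0.004 nm pushes edge-strand beads out of
  contact; the "every interior bead is beta" ground truth is only
  constructible in the planar limit. Antiparallel strands are built by
  reversing the bead order, which preserves the pleat phase.
  Registry shifts beyond |1| move edge beads out of cross-strand reach,
  so ground-truth fixtures use shifts in {−1, 0, 1}.
- `make_barrel`: strands on a cylinder of radius
  `inter_strand / (2 sin(π/n))` (or an explicit radius within 0.7–1.5×
  of it), optionally tilted about the radial axis. Barrel strands keep
  the 170° twist: on a curved surface the rotating pleat distributes
  offsets so all interior beads stay in contact; tilted barrels lose a
  small fraction of edge contacts, which is expected.
- `make_coil`: self-avoiding random walk with fixed 0.35 nm steps and
  an exclusion diameter (default 0.4 nm), restarting on dead ends.
  **Note:** at the 0.4 nm default a coil can legitimately contain beta
  beads — an intra-chain loopback at ≥ 4 sequence separation satisfies
  the criterion. Fixtures that need *zero beta by construction* build
  coils with `exclusion = 0.6` (= the contact cutoff), which makes the
  contact condition unsatisfiable within a chain.
- `make_cylinder_protein`: seven 25-residue helices on a 1.1 nm bundle
  radius — a membrane-protein mimic with hydrophobic (LEU) midsection
  and polar (SER) caps, group `protein`. It is a stand-in of roughly
  bacteriorhodopsin-like dimensions, not a real structure: its backbone-
  bead SASA (~82 nm², reported by the acceptance script) is smaller
  than a real CG membrane protein's because it has no side-chain beads
  and idealised packing.
- `make_detergent_shell`: head-out/tail-in 4-bead detergents (PCH +
  3 × DTL, 0.3 nm spacing) on a cylindrical shell (2.2 nm). With
  `n_patches=k` the molecules sit on tight per-patch grids (0.45 nm
  pitch — above the placement floor, below the 0.6 nm linkage cutoff),
  giving exactly k connected aggregates as clustering ground truth;
  without it heads are placed by rejection sampling with a minimum
  separation and the generator raises on overcrowded shells.
- `make_interpolated_trajectory`: linear interpolation between two
  frames — an idealised "assembly" trajectory for monotone-trend tests,
  not physical dynamics.

`peptergent.cgmap` maps an all-atom PDB to a MARTINI-style CG model
(backbone bead at the N/CA/C/O centroid plus side-chain beads at
standard atom-group centroids) for the real-protein surface check; it
requires downloading the PDB entry and is therefore exercised only by
the networked acceptance test.

## 7. Determinism

Golden-spiral SASA sampling, KD-tree clustering with ordinal labels,
seeded generators, and fixed-format CSV/TSV output (`%.6f`) make every
pipeline byte-reproducible under identical configurations; the
acceptance suite asserts this end to end.

## 8. Known limitations

- SASA ignores periodic images (warned, see §3); unwrap molecules
  first.
- Only orthorhombic boxes are supported throughout.
- The beta criterion evaluates no bead within two positions of a chain
  end (dihedral window), so short chains under-report beta content
  relative to per-residue assignments.
- Fixture ground truths (planar sheets, exclusion-0.6 coils) are
  conventions chosen to make properties constructible, as documented in
  §6; they are idealisations, not simulation snapshots.
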