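"""Seeded generators for every geometry class the analyses assume.

Ideal extended strands, multi-strand sheets (parallel/antiparallel,
optional registry shift), beta barrels, self-avoiding random coils, a
cylindrical helical-bundle membrane-protein mimic, a detergent shell
around it, and linearly interpolated trajectories.  Every generator is
a pure function of its arguments (seed included).

Geometry conventions: 0.35 nm consecutive-bead spacing and 0.48 nm
inter-strand spacing, the canonical CA-trace dimensions of beta
sheets.  Fixtures are backbone-only (one bead per residue, named BB)
with alternating hydrophobic/polar residue classes so that amphipathy
metrics are exercised.
"""

from __future__ import annotations

import itertools

import numpy as np

from .model import (
    Bead,
    BeadSystem,
    ClassTable,
    Frame,
    Trajectory,
)

#: default consecutive-bead spacing (nm) of an extended CA trace
DEFAULT_RISE = 0.35
#: default spacing (nm) between adjacent strands of a sheet
DEFAULT_INTER_STRAND = 0.48
#: default pseudo-dihedral (degrees) of the ideal extended strand
DEFAULT_ZIGZAG_DIHEDRAL = 170.0
#: default CA pseudo-bond angle (degrees) of the extended zigzag
DEFAULT_BOND_ANGLE = 140.0

_TABLE = None


def _table() -> ClassTable:
    global _TABLE
    if _TABLE is None:
        _TABLE = ClassTable.default()
    return _TABLE


def _make_beads(coords_per_chain, residue_names_per_chain, chain_ids, groups):
    """Assemble a BeadSystem + Frame from per-chain coordinates."""
    beads = []
    coords = []
    idx = 0
    group_members = {g: set() for g in groups}
    for chain_xyz, res_names, cid in zip(
        coords_per_chain, residue_names_per_chain, chain_ids
    ):
        for r, (xyz, rname) in enumerate(zip(chain_xyz, res_names)):
            entry = _table().lookup(rname)
            beads.append(
                Bead(
                    index=idx,
                    name="BB",
                    residue_index=r + 1,
                    residue_name=rname,
                    chain_id=cid,
                    is_backbone=True,
                    radius=entry.radius,
                    hydropathy_class=entry.hydropathy,
                )
            )
            for g, chain_set in groups.items():
                if cid in chain_set:
                    group_members[g].add(idx)
            coords.append(xyz)
            idx += 1
    system = BeadSystem(beads, groups=group_members)
    return system, Frame(np.array(coords))


def _chain_labels(n, prefix=""):
    base = [
        "".join(t)
        for k in range(1, 3)
        for t in itertools.product("ABCDEFGHIJKLMNOPQRSTUVWXYZ", repeat=k)
    ]
    return [prefix + base[i] for i in range(n)]


def _alternating_residues(n_res, start_hydrophobic=True):
    """VAL/THR alternation: hydrophobic on one face of the zigzag."""
    pair = ("VAL", "THR") if start_hydrophobic else ("THR", "VAL")
    return [pair[r % 2] for r in range(n_res)]


def _nerf_chain(n_res, bond, bond_angle_deg, dihedral_deg):
    """Chain-build with constant bond length, bond angle and dihedral.

    A constant dihedral close to 180 degrees yields an extended,
    slowly twisting strand — the CA-trace analogue of the natural
    beta-strand twist."""
    theta = np.radians(bond_angle_deg)
    coords = np.zeros((n_res, 3))
    coords[1] = (bond, 0.0, 0.0)
    if n_res > 2:
        coords[2] = coords[1] + bond * np.array(
            [-np.cos(theta), np.sin(theta), 0.0]
        )
    for k in range(3, n_res):
        phi = np.radians(dihedral_deg)
        a, b, c = coords[k - 3], coords[k - 2], coords[k - 1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        n = np.cross(b - a, bc)
        n /= np.linalg.norm(n)
        m = np.cross(n, bc)
        d2 = bond * np.array(
            [
                -np.cos(theta),
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
            ]
        )
        coords[k] = c + d2[0] * bc + d2[1] * m + d2[2] * n
    return coords


def _canonical_strand(n_res, rise, zigzag_dihedral, bond_angle):
    """Strand template: end-to-end axis on +x, mean zigzag plane normal
    on +y, centred at the origin."""
    coords = _nerf_chain(n_res, rise, bond_angle, zigzag_dihedral)
    coords -= coords.mean(axis=0)
    axis = coords[-1] - coords[0]
    axis /= np.linalg.norm(axis)
    # rotate axis -> +x
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, x)
    s, c = np.linalg.norm(v), np.dot(axis, x)
    if s > 1e-12:
        vx = np.array(
            [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
        )
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        coords = coords @ rot.T
    elif c < 0:
        coords[:, 0] *= -1
    # rotate about x so the thin direction of the zigzag lies on y
    _, _, vt = np.linalg.svd(coords - coords.mean(axis=0))
    normal = vt[2]
    ny, nz = normal[1], normal[2]
    norm = np.hypot(ny, nz)
    if norm > 1e-12:
        cos_a, sin_a = ny / norm, -nz / norm
        rot_x = np.array(
            [[1, 0, 0], [0, cos_a, -sin_a], [0, sin_a, cos_a]]
        )
        coords = coords @ rot_x.T
    return coords - coords.mean(axis=0)


def make_strand(
    n_res: int,
    rise: float = DEFAULT_RISE,
    zigzag_dihedral: float = DEFAULT_ZIGZAG_DIHEDRAL,
    bond_angle: float = DEFAULT_BOND_ANGLE,
    chain_id: str = "A",
    group: str = "peptide",
) -> tuple[BeadSystem, Frame]:
    """One ideal extended strand; every interior pseudo-dihedral equals
    ``zigzag_dihedral`` (unsigned) and consecutive beads sit ``rise``
    apart.  Residues alternate hydrophobic (VAL) / polar (THR)."""
    if n_res < 4:
        raise ValueError("a strand needs at least 4 residues")
    coords = _canonical_strand(n_res, rise, zigzag_dihedral, bond_angle)
    return _make_beads(
        [coords],
        [_alternating_residues(n_res)],
        [chain_id],
        {group: {chain_id}},
    )


def make_sheet(
    n_strands: int,
    n_res: int,
    inter_strand: float = DEFAULT_INTER_STRAND,
    orientation: str = "antiparallel",
    registry_shift: int = 0,
    rise: float = DEFAULT_RISE,
    zigzag_dihedral: float = 180.0,
    bond_angle: float = DEFAULT_BOND_ANGLE,
    chain_prefix: str = "",
    group: str = "peptide",
) -> tuple[BeadSystem, Frame]:
    """A stack of ideal strands spaced ``inter_strand`` apart along y.

    ``orientation`` is 'parallel' or 'antiparallel' (alternate strands
    reversed).  ``registry_shift`` displaces alternate strands along
    the strand axis by that many residues, so that bead k of a shifted
    strand sits against bead k+shift of its neighbour — the registry
    the strand-pairing detector reports.  Hydrophobic residues lie on
    one face of every strand.

    Sheet strands default to the planar pleat (pseudo-dihedral 180,
    the ideal-sheet limit): at canonical spacings the inter-strand
    contact margin is a few thousandths of a nm, and any out-of-plane
    pucker would push edge-strand beads out of contact range.
    """
    if n_strands < 2:
        raise ValueError("a sheet needs at least 2 strands")
    if orientation not in ("parallel", "antiparallel"):
        raise ValueError(f"invalid orientation {orientation!r}")
    template = _canonical_strand(n_res, rise, zigzag_dihedral, bond_angle)
    axial_rise = (template[-1, 0] - template[0, 0]) / (n_res - 1)
    chains = _chain_labels(n_strands, chain_prefix)
    coords_per_chain = []
    for j in range(n_strands):
        coords = template.copy()
        if j % 2 == 1:
            if orientation == "antiparallel":
                # reversed traversal of the same pleat keeps the strands
                # in phase, as backbone packing does in a real sheet
                coords = coords[::-1].copy()
            coords[:, 0] += registry_shift * axial_rise
        coords[:, 1] += j * inter_strand
        coords_per_chain.append(coords)
    return _make_beads(
        coords_per_chain,
        [_alternating_residues(n_res)] * n_strands,
        chains,
        {group: set(chains)},
    )


def make_barrel(
    n_strands: int,
    n_res: int,
    radius: float | None = None,
    inter_strand: float = DEFAULT_INTER_STRAND,
    tilt_deg: float = 0.0,
    rise: float = DEFAULT_RISE,
    zigzag_dihedral: float = DEFAULT_ZIGZAG_DIHEDRAL,
    chain_prefix: str = "",
    group: str = "peptide",
) -> tuple[BeadSystem, Frame]:
    """Strands on a cylinder about the z axis, antiparallel alternating,
    hydrophobic residues facing inward (pattern-level).

    Unlike flat sheets, barrel strands keep the twisted (170 degree)
    pleat: on a cylinder the rotating pleat distributes bead offsets
    around the surface and keeps every strand in contact with both
    neighbours, whereas a flat pleat points whole bead rows radially
    out of range.

    When ``radius`` is None it is chosen so neighbouring strands sit at
    ``inter_strand``; an explicit radius leaving neighbours further than
    1.5x that spacing (or closer than 0.7x) is rejected as infeasible.
    """
    if n_strands < 4:
        raise ValueError("a barrel needs at least 4 strands")
    chord_factor = 2.0 * np.sin(np.pi / n_strands)
    if radius is None:
        radius = inter_strand / chord_factor
    spacing = radius * chord_factor
    if not 0.7 * inter_strand <= spacing <= 1.5 * inter_strand:
        raise ValueError(
            f"radius {radius:.3f} nm puts neighbour strands at "
            f"{spacing:.3f} nm, incompatible with {inter_strand:.2f} nm sheets"
        )
    template = _canonical_strand(n_res, rise, zigzag_dihedral, DEFAULT_BOND_ANGLE)
    # template axis on x -> rotate to z
    to_z = np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    template_z = template @ to_z.T
    tilt = np.radians(tilt_deg)
    chains = _chain_labels(n_strands, chain_prefix)
    coords_per_chain = []
    for j in range(n_strands):
        coords = template_z.copy()
        if j % 2 == 1:
            coords = coords[::-1].copy()  # antiparallel: reversed traversal
        if abs(tilt) > 1e-12:
            # tilt in the (tangential, axial) plane about the radial (x) axis
            rot = np.array(
                [
                    [1, 0, 0],
                    [0, np.cos(tilt), -np.sin(tilt)],
                    [0, np.sin(tilt), np.cos(tilt)],
                ]
            )
            coords = coords @ rot.T
        phi = 2.0 * np.pi * j / n_strands
        place = np.array(
            [
                [np.cos(phi), -np.sin(phi), 0],
                [np.sin(phi), np.cos(phi), 0],
                [0, 0, 1],
            ]
        )
        coords = (coords + np.array([radius, 0.0, 0.0])) @ place.T
        coords_per_chain.append(coords)
    return _make_beads(
        coords_per_chain,
        [_alternating_residues(n_res)] * n_strands,
        chains,
        {group: set(chains)},
    )


def make_coil(
    n_res: int,
    bond: float = DEFAULT_RISE,
    exclusion: float = 0.4,
    seed: int = 0,
    chain_id: str = "A",
    group: str = "peptide",
    max_restarts: int = 50,
    max_step_tries: int = 200,
) -> tuple[BeadSystem, Frame]:
    """Self-avoiding random walk: bond lengths exactly ``bond``, every
    non-bonded pair at least ``exclusion`` apart; identical coordinates
    for identical seeds."""
    if n_res < 2:
        raise ValueError("a coil needs at least 2 residues")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        coords = np.zeros((n_res, 3))
        ok = True
        for k in range(1, n_res):
            placed = False
            for _ in range(max_step_tries):
                step = rng.normal(size=3)
                step *= bond / np.linalg.norm(step)
                cand = coords[k - 1] + step
                if k < 2 or np.all(
                    np.linalg.norm(coords[: k - 1] - cand, axis=1) >= exclusion
                ):
                    coords[k] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return _make_beads(
                [coords],
                [_alternating_residues(n_res)],
                [chain_id],
                {group: {chain_id}},
            )
    raise RuntimeError(
        f"could not place a self-avoiding walk of {n_res} residues "
        f"(bond {bond}, exclusion {exclusion})"
    )


def make_cylinder_protein(
    n_helices: int = 7,
    n_res_per_helix: int = 25,
    bundle_radius: float = 1.1,
    helix_radius: float = 0.23,
    helix_rise: float = 0.15,
    hydrophobic_fraction: float = 0.6,
    chain_prefix: str = "H",
) -> tuple[BeadSystem, Frame]:
    """Helical-bundle membrane-protein mimic (one BB bead per residue on
    an ideal helix), helices parallel to z on a circle of
    ``bundle_radius``; the central ``hydrophobic_fraction`` of each
    helix is hydrophobic (LEU), the caps polar (SER).

    Defaults sketch a seven-helix bundle of bacteriorhodopsin-like
    dimensions (~3.8 nm tall, ~2.7 nm across).
    """
    if n_helices < 1 or n_res_per_helix < 1:
        raise ValueError("counts must be >= 1")
    chains = _chain_labels(n_helices, chain_prefix)
    coords_per_chain, residues_per_chain = [], []
    turn = 2.0 * np.pi / 3.6  # residues per helical turn
    half_cap = (1.0 - hydrophobic_fraction) / 2.0
    for j in range(n_helices):
        phi0 = 2.0 * np.pi * j / n_helices
        t = np.arange(n_res_per_helix)
        local = np.column_stack(
            [
                helix_radius * np.cos(turn * t),
                helix_radius * np.sin(turn * t),
                helix_rise * t,
            ]
        )
        local[:, 2] -= local[:, 2].mean()
        center = bundle_radius * np.array([np.cos(phi0), np.sin(phi0), 0.0])
        coords_per_chain.append(local + center)
        frac = (t + 0.5) / n_res_per_helix
        residues_per_chain.append(
            [
                "LEU" if half_cap <= f <= 1.0 - half_cap else "SER"
                for f in frac
            ]
        )
    return _make_beads(
        coords_per_chain, residues_per_chain, chains, {"protein": set(chains)}
    )


def make_detergent_shell(
    protein: tuple[BeadSystem, Frame],
    n_detergent: int = 30,
    shell_radius: float = 2.2,
    seed: int = 0,
    n_patches: int | None = None,
    patch_halfwidth: float = 0.35,
    tail_beads: int = 3,
    tail_spacing: float = 0.3,
    min_separation: float = 0.35,
    chain_prefix: str = "D",
    max_tries: int = 2000,
) -> tuple[BeadSystem, Frame]:
    """Place detergent chains tail-inward on a cylindrical shell around
    a protein fixture and return the augmented system.

    Each detergent is a polar head bead (PCH) at ``shell_radius`` plus
    ``tail_beads`` hydrophobic beads (DTL) stepping radially inward.
    With ``n_patches`` set, molecules are distributed evenly over that
    many angular patches; patch members sit on a tight local grid
    (0.45 nm pitch, between the separation floor and the 0.6 nm
    single-linkage cutoff) with a small seeded jitter, so each patch
    is one connected aggregate and patches stay well separated —
    ground truth for micelle-recovery checks.  Raises when
    ``n_detergent`` heads cannot keep ``min_separation`` between each
    other (overcrowded shell).
    """
    prot_system, prot_frame = protein
    rng = np.random.default_rng(seed)
    z_span = prot_frame.coordinates[:, 2]
    z_lo, z_hi = z_span.min() + 0.2, z_span.max() - 0.2
    heads = []
    if n_patches:
        pitch = 0.45  # nm, grid step inside a patch
        per_patch = [
            n_detergent // n_patches + (1 if p < n_detergent % n_patches else 0)
            for p in range(n_patches)
        ]
        for p, count in enumerate(per_patch):
            theta_p = 2.0 * np.pi * p / n_patches
            n_col = max(1, int(np.ceil(np.sqrt(count))))
            for m in range(count):
                col, row = m % n_col, m // n_col
                theta = (
                    theta_p
                    + (col - (n_col - 1) / 2) * pitch / shell_radius
                    + rng.uniform(-0.01, 0.01)
                )
                z = np.clip(
                    (z_lo + z_hi) / 2 + row * pitch + rng.uniform(-0.02, 0.02),
                    z_lo,
                    z_hi + pitch * (count // n_col),
                )
                heads.append(
                    np.array(
                        [
                            shell_radius * np.cos(theta),
                            shell_radius * np.sin(theta),
                            z,
                        ]
                    )
                )
    else:
        for _ in range(n_detergent):
            placed = False
            for _ in range(max_tries):
                theta = rng.uniform(0.0, 2.0 * np.pi)
                z = rng.uniform(z_lo, z_hi)
                head = np.array(
                    [shell_radius * np.cos(theta), shell_radius * np.sin(theta), z]
                )
                if all(
                    np.linalg.norm(head - h) >= min_separation for h in heads
                ):
                    heads.append(head)
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"overcrowded shell: could not place detergent "
                    f"{len(heads) + 1} of {n_detergent}"
                )
    # assemble beads: copy protein, then append detergent chains
    beads = list(prot_system.beads)
    coords = [prot_frame.coordinates]
    groups = {name: set(members) for name, members in prot_system.groups.items()}
    groups.setdefault("detergent", set())
    idx = len(beads)
    for d, head in enumerate(heads):
        cid = f"{chain_prefix}{d + 1}"
        inward = -head * np.array([1.0, 1.0, 0.0])
        norm = np.linalg.norm(inward)
        inward = inward / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        positions = [head] + [
            head + inward * tail_spacing * (k + 1) for k in range(tail_beads)
        ]
        names = ["PCH"] + ["DTL"] * tail_beads
        for r, (xyz, rname) in enumerate(zip(positions, names)):
            entry = _table().lookup(rname)
            beads.append(
                Bead(
                    index=idx,
                    name="BB",
                    residue_index=r + 1,
                    residue_name=rname,
                    chain_id=cid,
                    is_backbone=True,
                    radius=entry.radius,
                    hydropathy_class=entry.hydropathy,
                )
            )
            groups["detergent"].add(idx)
            coords.append(xyz[None, :])
            idx += 1
    system = BeadSystem(beads, groups=groups)
    return system, Frame(np.concatenate(coords, axis=0))


def combine(
    *fixtures: tuple[BeadSystem, Frame],
    offsets=None,
) -> tuple[BeadSystem, Frame]:
    """Merge fixtures into one system, translating fixture i by
    ``offsets[i]`` (nm).  Chain ids are prefixed with the fixture
    ordinal to stay unique; groups with equal names are unioned."""
    if offsets is None:
        offsets = [np.zeros(3)] * len(fixtures)
    beads, coords = [], []
    groups: dict[str, set[int]] = {}
    idx = 0
    for f, ((system, frame), off) in enumerate(zip(fixtures, offsets)):
        remap = {}
        for bead in system.beads:
            remap[bead.index] = idx
            beads.append(
                Bead(
                    index=idx,
                    name=bead.name,
                    residue_index=bead.residue_index,
                    residue_name=bead.residue_name,
                    chain_id=f"{f}{bead.chain_id}" if len(fixtures) > 1 else bead.chain_id,
                    is_backbone=bead.is_backbone,
                    radius=bead.radius,
                    hydropathy_class=bead.hydropathy_class,
                )
            )
            idx += 1
        coords.append(frame.coordinates + np.asarray(off, dtype=float))
        for name, members in system.groups.items():
            groups.setdefault(name, set()).update(remap[m] for m in members)
    return BeadSystem(beads, groups=groups), Frame(np.concatenate(coords))


def make_interpolated_trajectory(
    system: BeadSystem,
    start: Frame,
    end: Frame,
    n_frames: int,
) -> Trajectory:
    """Linear interpolation between two frames; times 0..n_frames-1 ps.
    A geometric stand-in for a relaxation trajectory — no dynamics."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if start.n_beads != end.n_beads or start.n_beads != system.n_beads:
        raise ValueError("bead counts of system, start and end must match")
    frames = []
    for k in range(n_frames):
        lam = k / (n_frames - 1)
        frames.append(
            Frame(
                (1.0 - lam) * start.coordinates + lam * end.coordinates,
                box=start.box,
                time=float(k),
            )
        )
    return Trajectory(frames, system)
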