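"""Beta-structure assignment from backbone-bead (or CA) positions.

With one bead per residue, phi/psi angles do not exist, so beta
structure is scored geometrically: a backbone bead is in a beta sheet
when (a) the pseudo-dihedral over four consecutive backbone beads
exceeds ``angle_min`` (the chain is locally extended) and (b) two
bonded-consecutive backbone beads from a sequence-distant part of the
system both lie within ``contact_dist`` of it (an adjacent strand is
packed against it).  The defaults — 100 degrees and 0.6 nm — are the
thresholds calibrated against atomistic beta sheets for this criterion.

Derived quantities: per-system beta percentage, per-frame time series,
maximal strand segments, inter-strand pairing with orientation and
registry shift, and strand tilt against a reference axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import BeadSystem, Frame, Trajectory, min_image_displacement


@dataclass(frozen=True)
class BetaParams:
    """Thresholds of the beta criterion.

    angle_min:
        minimum pseudo-dihedral (degrees) over window (i-1, i, i+1, i+2)
        for bead i to count as extended.  Default 100.
    contact_dist:
        maximum distance (nm) for the inter-strand contact. Default 0.6
        (6 Angstrom).
    min_seq_sep:
        minimum residue separation, on the same chain, for a bead pair
        to qualify as an inter-strand contact; beads on other chains
        always qualify.  Default 4 — the shortest separation that
        excludes the dihedral window itself.
    min_strand_len:
        minimum number of consecutive beta beads to report a strand.
    """

    angle_min: float = 100.0
    contact_dist: float = 0.6
    min_seq_sep: int = 4
    min_strand_len: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.angle_min <= 180:
            raise ValueError("angle_min must be in (0, 180]")
        if self.contact_dist <= 0:
            raise ValueError("contact_dist must be > 0")
        if self.min_seq_sep < 2:
            raise ValueError("min_seq_sep must be >= 2")


@dataclass
class BetaAssignment:
    """Per-backbone-bead beta state.

    ``beta`` maps backbone bead index -> bool for every evaluable bead
    (beads with a full dihedral window); ``dihedrals`` holds the window
    angle in degrees; ``partners`` lists, for beads marked beta, the
    contact pairs (j, j+1) that satisfied the proximity criterion.
    """

    beta: dict[int, bool] = field(default_factory=dict)
    dihedrals: dict[int, float] = field(default_factory=dict)
    partners: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_evaluable(self) -> int:
        return len(self.beta)

    @property
    def n_beta(self) -> int:
        return sum(self.beta.values())

    def beta_indices(self) -> list[int]:
        return sorted(i for i, state in self.beta.items() if state)


def dihedral(p1, p2, p3, p4) -> float:
    """Unsigned dihedral angle of four points, in degrees within [0, 180].

    180 degrees is the planar-trans (fully extended) arrangement.
    Raises ValueError for degenerate geometry (coincident consecutive
    points or collinear central bond with an outer point).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-12:
        raise ValueError("undefined dihedral: central points coincide")
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("undefined dihedral: collinear points")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / norm_b2
    return float(abs(np.degrees(np.arctan2(y, x))))


def _window_dihedrals(coords, order):
    """Dihedral per evaluable bead of one chain's backbone order."""
    out = {}
    for k in range(1, len(order) - 2):
        quad = coords[[order[k - 1], order[k], order[k + 1], order[k + 2]]]
        try:
            out[order[k]] = dihedral(*quad)
        except ValueError:
            out[order[k]] = np.nan
    return out


def assign_beta(
    frame: Frame, system: BeadSystem, params: BetaParams | None = None
) -> BetaAssignment:
    """Assign the beta state to every evaluable backbone bead.

    Distances use the minimum-image convention when the frame has a
    box.  Chains with fewer than four backbone beads contribute no
    evaluable beads.
    """
    params = params or BetaParams()
    coords = frame.coordinates
    result = BetaAssignment()

    # chain-position bookkeeping for the sequence-separation rule
    chain_of: dict[int, str] = {}
    pos_of: dict[int, int] = {}
    for cid, order in system.chains.items():
        for pos, idx in enumerate(order):
            chain_of[idx] = cid
            pos_of[idx] = pos

    for cid, order in system.chains.items():
        result.dihedrals.update(_window_dihedrals(coords, order))

    evaluable = sorted(result.dihedrals)
    if not evaluable:
        return result

    # candidate contact beads: all backbone beads, searched via KD-tree.
    bb = np.concatenate([np.array(o) for o in system.chains.values()])
    bb.sort()
    bb_coords = coords[bb]
    box = frame.box
    if box is not None:
        tree_coords = np.mod(bb_coords, box)
        tree = cKDTree(tree_coords, boxsize=box)
        query_coords = np.mod(coords, box)
    else:
        tree = cKDTree(bb_coords)
        query_coords = coords

    bonded = system.bonds

    for i in evaluable:
        ang = result.dihedrals[i]
        extended = (not np.isnan(ang)) and ang > params.angle_min
        if not extended:
            result.beta[i] = False
            continue
        near = tree.query_ball_point(query_coords[i], params.contact_dist)
        near_idx = set(int(bb[k]) for k in near)
        pairs = []
        for j in near_idx:
            jp = j + 1
            if jp not in near_idx or (min(j, jp), max(j, jp)) not in bonded:
                continue
            ok = True
            for m in (j, jp):
                if chain_of.get(m) == chain_of[i]:
                    if abs(pos_of[m] - pos_of[i]) < params.min_seq_sep:
                        ok = False
                        break
            if ok:
                pairs.append((j, jp))
        result.beta[i] = bool(pairs)
        if pairs:
            result.partners[i] = sorted(pairs)
    return result


def beta_fraction(assignment: BetaAssignment, system: BeadSystem | None = None) -> float:
    """Percentage of evaluable backbone beads in beta state, in [0, 100]."""
    if assignment.n_evaluable == 0:
        raise ValueError("no evaluable backbone beads: beta fraction undefined")
    return 100.0 * assignment.n_beta / assignment.n_evaluable


def beta_timeseries(
    traj: Trajectory, params: BetaParams | None = None, stride: int = 1
) -> pd.DataFrame:
    """Beta percentage per sampled frame.

    Returns a DataFrame with columns ``time_ps`` and ``beta_percent``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    params = params or BetaParams()
    records = []
    for frame in traj.frames[::stride]:
        assignment = assign_beta(frame, traj.system, params)
        records.append((frame.time, beta_fraction(assignment)))
    return pd.DataFrame(records, columns=["time_ps", "beta_percent"])


@dataclass(frozen=True)
class StrandSegment:
    """A maximal run of consecutive beta backbone beads on one chain."""

    chain_id: str
    start_residue: int
    end_residue: int
    bead_indices: tuple[int, ...]
    direction: tuple[float, float, float]  # unit vector, first -> last bead

    def __len__(self) -> int:
        return len(self.bead_indices)


def find_strands(
    assignment: BetaAssignment,
    system: BeadSystem,
    frame: Frame,
    params: BetaParams | None = None,
) -> list[StrandSegment]:
    """Maximal beta runs of length >= ``min_strand_len`` per chain."""
    params = params or BetaParams()
    segments = []
    for cid, order in system.chains.items():
        run: list[int] = []
        for idx in order + [-1]:  # sentinel flushes the last run
            if idx >= 0 and assignment.beta.get(idx, False):
                run.append(idx)
                continue
            if len(run) >= params.min_strand_len:
                vec = frame.coordinates[run[-1]] - frame.coordinates[run[0]]
                norm = np.linalg.norm(vec)
                direction = tuple(vec / norm) if norm > 0 else (0.0, 0.0, 0.0)
                segments.append(
                    StrandSegment(
                        chain_id=cid,
                        start_residue=system.beads[run[0]].residue_index,
                        end_residue=system.beads[run[-1]].residue_index,
                        bead_indices=tuple(run),
                        direction=direction,
                    )
                )
            run = []
    return segments


@dataclass(frozen=True)
class SheetPairing:
    """Two strand segments packed side by side in a sheet."""

    seg_a: StrandSegment
    seg_b: StrandSegment
    orientation: str  # 'parallel' | 'antiparallel'
    registry_shift: int
    mean_distance: float  # nm, over matched beads at the best registry


def _mean_nearest(coords_a, coords_b):
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=-1)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def _registry_shift(coords_a, coords_b, max_shift=3):
    """Registry of b against a: the shift s matching bead k of b with
    bead k+s of a that minimises the mean matched-bead distance; ties
    break toward smaller |s| (iteration order is sorted by |s|)."""
    best = (np.inf, 0)
    na, nb = len(coords_a), len(coords_b)
    for shift in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s)):
        kb = np.arange(nb)
        ka = kb + shift
        keep = (ka >= 0) & (ka < na)
        if keep.sum() < 2:
            continue
        d = np.linalg.norm(coords_a[ka[keep]] - coords_b[kb[keep]], axis=1).mean()
        if d < best[0] - 1e-12:
            best = (d, shift)
    return best


def pair_strands(
    segments: list[StrandSegment],
    frame: Frame,
    system: BeadSystem,
    pair_dist: float = 0.7,
    max_shift: int = 3,
) -> list[SheetPairing]:
    """Pair strand segments whose mean closest inter-bead distance is
    within ``pair_dist``; classify orientation by the sign of the
    direction dot product and find the registry shift that minimises
    the summed matched-bead distance (search window |shift| <= 3)."""
    if pair_dist <= 0:
        raise ValueError("pair_dist must be > 0")
    pairings = []
    coords = frame.coordinates
    for a in range(len(segments)):
        for b in range(a + 1, len(segments)):
            seg_a, seg_b = segments[a], segments[b]
            ca = coords[list(seg_a.bead_indices)]
            cb = coords[list(seg_b.bead_indices)]
            if _mean_nearest(ca, cb) > pair_dist:
                continue
            dot = float(np.dot(seg_a.direction, seg_b.direction))
            orientation = "parallel" if dot >= 0 else "antiparallel"
            # registry over the full backbone chains: beta segments are
            # truncated asymmetrically by the dihedral window, which
            # would bias the offset for antiparallel pairs
            full_a = coords[system.chains[seg_a.chain_id]]
            full_b = coords[system.chains[seg_b.chain_id]]
            fb_aligned = full_b if orientation == "parallel" else full_b[::-1]
            dist, shift = _registry_shift(full_a, fb_aligned, max_shift)
            pairings.append(
                SheetPairing(seg_a, seg_b, orientation, shift, float(dist))
            )
    return pairings


def strand_tilt(segment: StrandSegment, axis) -> float:
    """Acute angle (degrees, [0, 90]) between a strand and an axis."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("axis must be non-zero")
    cosang = abs(np.dot(segment.direction, axis / norm))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def assignment_table(
    assignment: BetaAssignment, system: BeadSystem
) -> pd.DataFrame:
    """Per-bead export: chain, residue_index, beta_state, dihedral_deg,
    n_contacts."""
    rows = []
    for i in sorted(assignment.beta):
        bead = system.beads[i]
        rows.append(
            (
                bead.chain_id,
                bead.residue_index,
                assignment.beta[i],
                assignment.dihedrals.get(i, np.nan),
                len(assignment.partners.get(i, [])),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chain", "residue_index", "beta_state", "dihedral_deg", "n_contacts"],
    )
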