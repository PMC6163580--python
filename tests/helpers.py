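"""Independent reference implementations (oracles) used only by tests.

These deliberately avoid the package's vectorised/KD-tree code paths:
the beta oracle is a naive triple loop, the clustering oracle is
union-find, and the two-sphere SASA oracle is the analytic
spherical-cap formula.
"""

from __future__ import annotations

import numpy as np

from peptergent.beta import BetaParams, dihedral
from peptergent.model import min_image_distance


def brute_force_beta(frame, system, params: BetaParams | None = None):
    """Naive bead-for-bead beta assignment: per-chain window dihedral,
    then exhaustive search over all bonded backbone pairs."""
    params = params or BetaParams()
    coords = frame.coordinates
    box = frame.box

    chain_of, pos_of = {}, {}
    for cid, order in system.chains.items():
        for pos, idx in enumerate(order):
            chain_of[idx] = cid
            pos_of[idx] = pos

    backbone = sorted(i for order in system.chains.values() for i in order)
    bonded_pairs = [
        (j, j + 1)
        for j in backbone
        if (j, j + 1) in system.bonds or (j + 1, j) in system.bonds
    ]

    beta = {}
    for cid, order in system.chains.items():
        for k in range(1, len(order) - 2):
            i = order[k]
            quad = [coords[order[k - 1]], coords[i], coords[order[k + 1]], coords[order[k + 2]]]
            try:
                ang = dihedral(*quad)
            except ValueError:
                beta[i] = False
                continue
            if ang <= params.angle_min:
                beta[i] = False
                continue
            found = False
            for j, jp in bonded_pairs:
                if any(
                    chain_of[m] == cid and abs(pos_of[m] - pos_of[i]) < params.min_seq_sep
                    for m in (j, jp)
                ):
                    continue
                dj = min_image_distance(coords[i], coords[j], box)
                djp = min_image_distance(coords[i], coords[jp], box)
                if dj <= params.contact_dist and djp <= params.contact_dist:
                    found = True
                    break
            beta[i] = found
    return beta


def union_find_clusters(frame, system, molecule_group: str, cutoff: float):
    """Brute-force union-find over all inter-molecule bead pairs."""
    sel = sorted(system.group(molecule_group))
    chains: dict[str, list[int]] = {}
    for i in sel:
        chains.setdefault(system.beads[i].chain_id, []).append(i)
    chain_ids = sorted(chains)
    parent = list(range(len(chain_ids)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    coords = frame.coordinates
    for a, ca in enumerate(chain_ids):
        for b in range(a + 1, len(chain_ids)):
            cb = chain_ids[b]
            if any(
                min_image_distance(coords[i], coords[j], frame.box) <= cutoff
                for i in chains[ca]
                for j in chains[cb]
            ):
                union(a, b)
    return {cid: find(m) for m, cid in enumerate(chain_ids)}


def two_sphere_sasa(r1, r2, d, probe):
    """Analytic SASA of two overlapping spheres (expanded by the probe).

    Each sphere loses a spherical cap of height h = R - (d^2 + R^2 - R'^2)/(2d);
    cap area = 2 pi R h.  Valid for 0 < d < R1 + R2 with neither sphere
    containing the other."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * (R1**2 + R2**2)
    if d <= abs(R1 - R2):
        raise ValueError("one sphere engulfs the other")
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
    return 4 * np.pi * R1**2 - 2 * np.pi * R1 * h1 + 4 * np.pi * R2**2 - 2 * np.pi * R2 * h2


def random_bead_fixture(seed: int, max_beads: int = 200):
    """Randomized multi-chain fixture for oracle-equivalence checks.

    Mixes compact sheets, loose coils and fully random chain placements
    so both branches of the criterion (dihedral and contact) are
    exercised; occasionally adds a periodic box."""
    from peptergent import synthetic as syn

    rng = np.random.default_rng(seed)
    kind = rng.integers(0, 3)
    if kind == 0:
        n_strands = int(rng.integers(2, 5))
        n_res = int(rng.integers(4, 13))
        system, frame = syn.make_sheet(
            n_strands, n_res, registry_shift=int(rng.integers(-1, 2))
        )
        coords = frame.coordinates + rng.normal(0, 0.03, frame.coordinates.shape)
    elif kind == 1:
        pieces = [
            syn.make_coil(int(rng.integers(5, 15)), seed=int(rng.integers(0, 2**31)))
            for _ in range(int(rng.integers(2, 5)))
        ]
        offsets = rng.uniform(-1.5, 1.5, (len(pieces), 3))
        system, frame = syn.combine(*pieces, offsets=offsets)
        coords = frame.coordinates
    else:
        pieces = [
            syn.make_strand(int(rng.integers(4, 11)))
            for _ in range(int(rng.integers(2, 4)))
        ]
        offsets = rng.uniform(-1.0, 1.0, (len(pieces), 3))
        system, frame = syn.combine(*pieces, offsets=offsets)
        coords = frame.coordinates + rng.normal(0, 0.1, frame.coordinates.shape)
    assert system.n_beads <= max_beads
    box = None
    if rng.random() < 0.3:
        span = coords.max(axis=0) - coords.min(axis=0)
        box = np.asarray(span + rng.uniform(1.0, 3.0, 3))
        coords = coords - coords.min(axis=0) + 0.2
    return system, type(frame)(coords, box=box, time=0.0)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
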