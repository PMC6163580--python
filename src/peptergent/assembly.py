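"""Aggregate clustering, contact mapping and hydrophobic burial.

Molecules (one chain = one molecule: a peptide or a detergent) are
clustered by single linkage: two molecules join the same aggregate when
any inter-molecule bead pair lies within the cutoff, under the
minimum-image convention.  This is the natural aggregation measure for
detergent micelles and peptide clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model import BeadSystem, Frame, HydropathyClass
from .surface import SASAParams, sasa


@dataclass
class ClusterSet:
    """Single-linkage clustering of molecules (chains).

    ``labels`` maps chain_id -> cluster label, where each label is the
    lowest member molecule's ordinal (deterministic).  ``sizes`` maps
    label -> molecule count.
    """

    labels: dict[str, int]
    sizes: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def members(self, label: int) -> list[str]:
        return sorted(c for c, l in self.labels.items() if l == label)


def _group_chains(system: BeadSystem, group) -> dict[str, list[int]]:
    """Partition a bead group into molecules by chain_id."""
    chains: dict[str, list[int]] = {}
    for i in sorted(group):
        chains.setdefault(system.beads[i].chain_id, []).append(i)
    return chains


def _pairs_within(frame: Frame, indices: np.ndarray, cutoff: float):
    """All bead index pairs within cutoff, minimum image when boxed."""
    coords = frame.coordinates[indices]
    if frame.box is not None:
        tree = cKDTree(np.mod(coords, frame.box), boxsize=frame.box)
    else:
        tree = cKDTree(coords)
    return tree.query_pairs(cutoff, output_type="ndarray")


def cluster_molecules(
    frame: Frame,
    system: BeadSystem,
    molecule_group: str | set,
    cutoff: float = 0.6,
) -> ClusterSet:
    """Single-linkage clustering of the molecules of a group."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    group = (
        system.group(molecule_group)
        if isinstance(molecule_group, str)
        else frozenset(molecule_group)
    )
    chains = _group_chains(system, group)
    if not chains:
        raise ValueError("empty molecule group")
    chain_ids = sorted(chains)
    mol_of_bead = {}
    all_beads = []
    for m, cid in enumerate(chain_ids):
        for i in chains[cid]:
            mol_of_bead[i] = m
            all_beads.append(i)
    all_beads = np.array(all_beads)
    pairs = _pairs_within(frame, all_beads, cutoff)
    n_mol = len(chain_ids)
    if len(pairs):
        rows = np.array([mol_of_bead[all_beads[p]] for p in pairs[:, 0]])
        cols = np.array([mol_of_bead[all_beads[p]] for p in pairs[:, 1]])
        adj = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n_mol, n_mol)
        )
    else:
        adj = coo_matrix((n_mol, n_mol))
    _, comp = connected_components(adj, directed=False)
    # relabel: cluster label = lowest molecule ordinal in the cluster
    lowest: dict[int, int] = {}
    for m, c in enumerate(comp):
        lowest.setdefault(int(c), m)
    labels = {chain_ids[m]: lowest[int(comp[m])] for m in range(n_mol)}
    sizes: dict[int, int] = {}
    for lab in labels.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    return ClusterSet(labels, sizes)


def cluster_table(clusters: ClusterSet) -> pd.DataFrame:
    """Cluster report (cluster_id, size, member_chains)."""
    rows = [
        (lab, clusters.sizes[lab], ";".join(clusters.members(lab)))
        for lab in sorted(clusters.sizes)
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "size", "member_chains"])


@dataclass
class ContactMap:
    """Residue pairs of two groups with min bead distance <= cutoff."""

    contacts: list[tuple[tuple[str, int], tuple[str, int], float]]
    cutoff: float

    def __len__(self) -> int:
        return len(self.contacts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (ca, ra, cb, rb, d)
            for (ca, ra), (cb, rb), d in self.contacts
        ]
        return pd.DataFrame(
            rows,
            columns=["chain_a", "residue_a", "chain_b", "residue_b", "distance_nm"],
        )


def contact_residues(
    frame: Frame,
    system: BeadSystem,
    group_a,
    group_b,
    cutoff: float = 0.6,
) -> ContactMap:
    """All (residue of A, residue of B) pairs with minimum bead distance
    within the cutoff; minimum image when the frame has a box."""
    set_a = system.group(group_a) if isinstance(group_a, str) else frozenset(group_a)
    set_b = system.group(group_b) if isinstance(group_b, str) else frozenset(group_b)
    if set_a & set_b:
        raise ValueError("groups must be disjoint")
    a = np.array(sorted(set_a))
    b = np.array(sorted(set_b))
    if a.size == 0 or b.size == 0:
        return ContactMap([], cutoff)
    box = frame.box
    ca, cb = frame.coordinates[a], frame.coordinates[b]
    if box is not None:
        tree = cKDTree(np.mod(cb, box), boxsize=box)
        qa = np.mod(ca, box)
    else:
        tree = cKDTree(cb)
        qa = ca
    best: dict[tuple, float] = {}
    hits = tree.query_ball_point(qa, cutoff)
    for ia, neigh in enumerate(hits):
        for ib in neigh:
            if box is not None:
                dv = qa[ia] - np.mod(cb[ib], box)
                dv -= box * np.round(dv / box)
            else:
                dv = ca[ia] - cb[ib]
            d = float(np.linalg.norm(dv))
            bead_a, bead_b = system.beads[a[ia]], system.beads[b[ib]]
            key = (
                (bead_a.chain_id, bead_a.residue_index),
                (bead_b.chain_id, bead_b.residue_index),
            )
            if d <= cutoff and d < best.get(key, np.inf):
                best[key] = d
    contacts = sorted((ka, kb, d) for (ka, kb), d in best.items())
    return ContactMap(contacts, cutoff)


def hydrophobic_burial(
    frame: Frame,
    system: BeadSystem,
    group,
    params: SASAParams | None = None,
) -> float:
    """Fraction of hydrophobic surface buried by the assembly, in [0, 1].

    1 - (SASA of hydrophobic beads in the group context) / (their
    isolated single-bead reference areas), clamped at 0.
    """
    params = params or SASAParams()
    sel = system.group(group) if isinstance(group, str) else frozenset(group)
    hydrophobic = [
        i
        for i in sorted(sel)
        if system.beads[i].hydropathy_class is HydropathyClass.HYDROPHOBIC
    ]
    if not hydrophobic:
        raise ValueError("group has no hydrophobic beads")
    context = sasa(frame, system, sel, params)
    exposed = sum(context.per_bead[i] for i in hydrophobic)
    reference = sum(
        4.0 * np.pi * (system.beads[i].radius + params.probe_radius) ** 2
        for i in hydrophobic
    )
    return float(max(0.0, 1.0 - exposed / reference))
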