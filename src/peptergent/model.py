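"""Core data model for coarse-grained / CA-reduced systems.

A system is a flat list of beads (one per CG particle or CA atom) with
chain-level backbone ordering, bonds, and named selection groups
(typically ``protein``, ``peptide`` and ``detergent``).  All coordinates
are stored in nanometres; PDB input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml


class HydropathyClass(str, Enum):
    """Residue hydropathy class used for amphipathy and burial metrics."""

    HYDROPHOBIC = "hydrophobic"
    POLAR = "polar"
    CHARGED_POS = "charged_pos"
    CHARGED_NEG = "charged_neg"
    OTHER = "other"

    @property
    def is_hydrophilic(self) -> bool:
        # charged residues count as hydrophilic for alternation purposes
        return self in (
            HydropathyClass.POLAR,
            HydropathyClass.CHARGED_POS,
            HydropathyClass.CHARGED_NEG,
        )

    @property
    def charge(self) -> int:
        if self is HydropathyClass.CHARGED_POS:
            return 1
        if self is HydropathyClass.CHARGED_NEG:
            return -1
        return 0


#: bead names recognised as the per-residue backbone position
BACKBONE_NAMES = ("BB", "CA")

#: default bead radius in nm (regular MARTINI particle)
DEFAULT_BEAD_RADIUS = 0.26


@dataclass(frozen=True)
class Bead:
    """One coarse-grained particle (or CA atom in a reduced trace)."""

    index: int
    name: str
    residue_index: int
    residue_name: str
    chain_id: str
    is_backbone: bool
    radius: float = DEFAULT_BEAD_RADIUS
    hydropathy_class: HydropathyClass = HydropathyClass.OTHER

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"bead index must be >= 0, got {self.index}")
        if self.radius <= 0:
            raise ValueError(f"bead radius must be > 0, got {self.radius}")


class BeadSystem:
    """Topology of a CG system: beads, chains, bonds and named groups.

    Parameters
    ----------
    beads:
        Ordered beads; ``bead.index`` must equal its list position.
    bonds:
        Pairs of bead indices.  Backbone beads of each chain are bonded
        consecutively by construction; extra bonds may be supplied.
    groups:
        Mapping group name -> set of bead indices.  Expected names are
        ``protein``, ``peptide`` and ``detergent`` but any name works.
    """

    def __init__(
        self,
        beads: Sequence[Bead],
        bonds: Iterable[tuple[int, int]] | None = None,
        groups: Mapping[str, Iterable[int]] | None = None,
    ) -> None:
        self.beads: list[Bead] = list(beads)
        for pos, bead in enumerate(self.beads):
            if bead.index != pos:
                raise ValueError(
                    f"bead index {bead.index} does not match its position {pos}"
                )
        # ordered backbone bead indices per chain
        self.chains: dict[str, list[int]] = {}
        for bead in self.beads:
            if bead.is_backbone:
                self.chains.setdefault(bead.chain_id, []).append(bead.index)
        n = len(self.beads)
        self.bonds: set[tuple[int, int]] = set()
        auto_bonds: list[tuple[int, int]] = []
        for order in self.chains.values():
            auto_bonds.extend(zip(order[:-1], order[1:]))
        for i, j in list(bonds or []) + auto_bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references a missing bead")
            self.bonds.add((min(i, j), max(i, j)))
        self.groups: dict[str, frozenset[int]] = {}
        for name, members in (groups or {}).items():
            members = frozenset(members)
            if any(m < 0 or m >= n for m in members):
                raise ValueError(f"group {name!r} references a missing bead")
            self.groups[name] = members

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def backbone_indices(self) -> np.ndarray:
        return np.array(
            [b.index for b in self.beads if b.is_backbone], dtype=int
        )

    def group(self, name: str) -> frozenset[int]:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(
                f"no group named {name!r}; available: {sorted(self.groups)}"
            ) from None

    def radii(self, indices: Iterable[int] | None = None) -> np.ndarray:
        if indices is None:
            return np.array([b.radius for b in self.beads])
        return np.array([self.beads[i].radius for i in indices])


@dataclass
class Frame:
    """One set of coordinates (nm) with an optional orthorhombic box."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise ValueError("box must hold 3 orthorhombic edge lengths")
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be > 0")

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Time-ordered frames over one :class:`BeadSystem`."""

    frames: list[Frame]
    system: BeadSystem

    def __post_init__(self) -> None:
        n = self.system.n_beads
        for k, fr in enumerate(self.frames):
            if fr.n_beads != n:
                raise ValueError(
                    f"frame {k} has {fr.n_beads} beads, system has {n}"
                )
        times = [fr.time for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times[:-1], times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def min_image_displacement(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Displacement b - a under the minimum-image convention.

    With no box the plain difference is returned.  Broadcasts over
    leading axes, so ``a`` and ``b`` may be arrays of points.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is None:
        return d
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Euclidean norm of :func:`min_image_displacement`."""
    return np.linalg.norm(min_image_displacement(a, b, box), axis=-1)


# ---------------------------------------------------------------------------
# residue class table


@dataclass(frozen=True)
class ResidueClass:
    hydropathy: HydropathyClass
    radius: float = DEFAULT_BEAD_RADIUS


class ClassTable:
    """Residue name -> (hydropathy class, bead radius nm) lookup.

    Unknown residues fall back to class ``other`` with the default
    radius rather than failing: non-natural residues (e.g. the ADA
    2-aminodecanoic acid of peptergent sequences) may appear under
    names no table anticipates.
    """

    def __init__(
        self,
        entries: Mapping[str, ResidueClass],
        default_radius: float = DEFAULT_BEAD_RADIUS,
    ) -> None:
        self.entries = dict(entries)
        self.default_radius = default_radius

    def __contains__(self, residue_name: str) -> bool:
        return residue_name.upper() in self.entries

    def lookup(self, residue_name: str) -> ResidueClass:
        entry = self.entries.get(residue_name.upper())
        if entry is None:
            return ResidueClass(HydropathyClass.OTHER, self.default_radius)
        return entry

    @classmethod
    def from_yaml(cls, path) -> "ClassTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "ClassTable":
        default_radius = float(raw.get("default_radius_nm", DEFAULT_BEAD_RADIUS))
        entries = {}
        for name, spec in raw.get("residues", {}).items():
            entries[name.upper()] = ResidueClass(
                HydropathyClass(spec["class"]),
                float(spec.get("radius_nm", default_radius)),
            )
        return cls(entries, default_radius)

    @classmethod
    def default(cls) -> "ClassTable":
        """Table shipped with the package: 20 standard residues plus the
        non-natural ADA (hydrophobic, isoleucine-like side chain) and ABZ
        (aminobenzoyl cap, treated as phenylalanine) plus DPC detergent
        bead residues."""
        ref = resources.files("peptergent").joinpath("data/bead_classes.yaml")
        with ref.open() as fh:
            return cls._from_mapping(yaml.safe_load(fh))
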