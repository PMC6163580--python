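"""Solvent-accessible surface area (Shrake-Rupley) and buried interfaces.

The SASA of a selection is computed with the Shrake-Rupley rolling-probe
construction: each bead is expanded by the probe radius, covered with a
deterministic golden-spiral point set, and the fraction of points not
occluded by any other expanded bead in the same selection is scaled to
the expanded sphere's area.  The probe radius default (0.256 nm) is the
radius of a regular MARTINI particle, so that areas are commensurate
with CG bead surfaces.

The buried interface between two selections A and B is

    (SASA_A + SASA_B - SASA_AB) / 2

with each term computed in its own selection context — the surface each
partner loses on association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import BeadSystem, Frame, Trajectory


@dataclass(frozen=True)
class SASAParams:
    """probe_radius: nm (default 0.256, the MARTINI particle radius);
    n_sphere_points: golden-spiral sample count per bead (default 960);
    default_bead_radius: nm fallback when a bead carries none."""

    probe_radius: float = 0.256
    n_sphere_points: int = 960
    default_bead_radius: float = 0.26

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 32:
            raise ValueError("n_sphere_points must be >= 32")


@dataclass
class SASAResult:
    per_bead: dict[int, float]  # nm^2, keyed by bead index
    total: float  # nm^2
    selection: str = ""


@dataclass(frozen=True)
class InterfaceResult:
    area: float  # nm^2
    selection_a: str = "A"
    selection_b: str = "B"


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral (Fibonacci) unit-sphere point set."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    frame: Frame,
    system: BeadSystem,
    selection,
    params: SASAParams | None = None,
    selection_name: str = "",
) -> SASAResult:
    """Shrake-Rupley SASA of a bead selection, in nm^2.

    Only beads inside the selection occlude each other; the rest of the
    system is invisible to the calculation.  Periodic images are not
    considered (selections are expected to be compact assemblies); a
    warning is emitted when a selection spans more than half the box.
    """
    params = params or SASAParams()
    sel = np.array(sorted(selection), dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    coords = frame.coordinates[sel]
    radii = np.array(
        [system.beads[i].radius or params.default_bead_radius for i in sel]
    )
    expanded = radii + params.probe_radius

    if frame.box is not None:
        span = coords.max(axis=0) - coords.min(axis=0)
        if np.any(span > frame.box / 2):
            warnings.warn(
                "selection spans more than half the box; SASA ignores "
                "periodic images",
                stacklevel=2,
            )

    unit = sphere_points(params.n_sphere_points)
    max_r = expanded.max()
    tree = cKDTree(coords)
    per_bead: dict[int, float] = {}
    for k, idx in enumerate(sel):
        pts = coords[k] + expanded[k] * unit
        # neighbours whose expanded sphere could occlude any test point
        neigh = tree.query_ball_point(coords[k], expanded[k] + max_r)
        neigh = [m for m in neigh if m != k]
        accessible = np.ones(len(pts), dtype=bool)
        for m in neigh:
            d = np.linalg.norm(pts - coords[m], axis=1)
            accessible &= d >= expanded[m]
        area = 4.0 * np.pi * expanded[k] ** 2 * accessible.mean()
        per_bead[int(idx)] = float(area)
    return SASAResult(per_bead, float(sum(per_bead.values())), selection_name)


def interface_area(
    frame: Frame,
    system: BeadSystem,
    sel_a,
    sel_b,
    params: SASAParams | None = None,
    name_a: str = "A",
    name_b: str = "B",
) -> InterfaceResult:
    """Buried interface area (SASA_A + SASA_B - SASA_AB) / 2 in nm^2."""
    params = params or SASAParams()
    set_a, set_b = frozenset(sel_a), frozenset(sel_b)
    if not set_a or not set_b:
        raise ValueError("selections must be non-empty")
    if set_a & set_b:
        raise ValueError("selections must be disjoint")
    area_a = sasa(frame, system, set_a, params).total
    area_b = sasa(frame, system, set_b, params).total
    area_ab = sasa(frame, system, set_a | set_b, params).total
    return InterfaceResult((area_a + area_b - area_ab) / 2.0, name_a, name_b)


def interface_timeseries(
    traj: Trajectory,
    sel_a,
    sel_b,
    params: SASAParams | None = None,
    stride: int = 1,
) -> pd.DataFrame:
    """Interface area per sampled frame: columns time_ps, area_nm2."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    params = params or SASAParams()
    records = [
        (fr.time, interface_area(fr, traj.system, sel_a, sel_b, params).area)
        for fr in traj.frames[::stride]
    ]
    return pd.DataFrame(records, columns=["time_ps", "area_nm2"])


def sasa_table(result: SASAResult, system: BeadSystem) -> pd.DataFrame:
    """Per-bead SASA export (chain, residue_index, bead, area_nm2)."""
    rows = [
        (
            system.beads[i].chain_id,
            system.beads[i].residue_index,
            system.beads[i].name,
            area,
        )
        for i, area in sorted(result.per_bead.items())
    ]
    return pd.DataFrame(rows, columns=["chain", "residue_index", "bead", "area_nm2"])
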