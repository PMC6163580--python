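"""Readers and writers for GRO and PDB structures and trajectories.

GRO files (fixed-column, nm) are parsed in-package so that malformed
records can be reported with their line number; PDB files go through
biotite and are converted from Angstrom to nm on read.  Trajectories are
concatenated GRO blocks or multi-model PDB files.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Mapping

import numpy as np

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .model import (
    BACKBONE_NAMES,
    Bead,
    BeadSystem,
    ClassTable,
    Frame,
    Trajectory,
)


class ParseError(ValueError):
    """Malformed record in a structure file; carries the line number."""


class StructureError(ValueError):
    """Structurally inconsistent input (bead counts, empty files...)."""


_GRO_TIME_RE = re.compile(r"\bt\s*=\s*([0-9.eE+-]+)")


def _build_system(
    names, res_ids, res_names, chain_ids, class_table: ClassTable,
    backbone_names=BACKBONE_NAMES,
) -> BeadSystem:
    beads = []
    for i, (name, rid, rname, cid) in enumerate(
        zip(names, res_ids, res_names, chain_ids)
    ):
        entry = class_table.lookup(rname)
        beads.append(
            Bead(
                index=i,
                name=name,
                residue_index=int(rid),
                residue_name=rname,
                chain_id=str(cid),
                is_backbone=name in backbone_names,
                radius=entry.radius,
                hydropathy_class=entry.hydropathy,
            )
        )
    return BeadSystem(beads)


def _infer_gro_chains(res_ids) -> list[str]:
    """GRO carries no chain field; start a new chain whenever the residue
    number decreases (GROMACS writes molecules with restarting resids)."""
    chains = []
    chain_no = 0
    prev = None
    for rid in res_ids:
        if prev is not None and rid < prev:
            chain_no += 1
        chains.append(_chain_label(chain_no))
        prev = rid
    return chains


def _chain_label(n: int) -> str:
    label = ""
    n += 1
    while n > 0:
        n, rem = divmod(n - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


# ---------------------------------------------------------------------------
# GRO


def _parse_gro_block(lines, offset, path):
    """Parse one GRO block starting at ``lines[offset]``.

    Returns (title, names, res_ids, res_names, coords, box, next_offset).
    """
    if offset >= len(lines):
        raise StructureError(f"{path}: empty input")
    title = lines[offset].rstrip("\n")
    try:
        n_atoms = int(lines[offset + 1].strip())
    except (IndexError, ValueError):
        raise ParseError(
            f"{path}, line {offset + 2}: expected atom count"
        ) from None
    if n_atoms <= 0:
        raise StructureError(f"{path}: zero beads declared at line {offset + 2}")
    names, res_ids, res_names = [], [], []
    coords = np.empty((n_atoms, 3))
    for k in range(n_atoms):
        lineno = offset + 2 + k
        try:
            line = lines[lineno].rstrip("\n")
        except IndexError:
            raise ParseError(
                f"{path}, line {lineno + 1}: unexpected end of file"
            ) from None
        # fixed columns: resid[0:5] resname[5:10] name[10:15] serial[15:20]
        # x[20:28] y[28:36] z[36:44]
        if len(line) < 44:
            raise ParseError(
                f"{path}, line {lineno + 1}: truncated coordinate record"
            )
        try:
            res_ids.append(int(line[0:5]))
            res_names.append(line[5:10].strip())
            names.append(line[10:15].strip())
            coords[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except ValueError as exc:
            raise ParseError(
                f"{path}, line {lineno + 1}: malformed coordinate record ({exc})"
            ) from None
    box_lineno = offset + 2 + n_atoms
    try:
        box_fields = [float(x) for x in lines[box_lineno].split()]
    except (IndexError, ValueError):
        raise ParseError(
            f"{path}, line {box_lineno + 1}: expected box vector line"
        ) from None
    if len(box_fields) >= 9 and any(abs(v) > 1e-9 for v in box_fields[3:]):
        raise StructureError(
            f"{path}, line {box_lineno + 1}: triclinic boxes are not supported"
        )
    box = None
    if len(box_fields) >= 3 and all(v > 0 for v in box_fields[:3]):
        box = np.array(box_fields[:3])
    return title, names, res_ids, res_names, coords, box, box_lineno + 1


def read_gro(path, class_table: ClassTable | None = None,
             backbone_names=BACKBONE_NAMES) -> tuple[BeadSystem, Frame]:
    """Read a single-frame GRO file (coordinates already in nm)."""
    class_table = class_table or ClassTable.default()
    lines = Path(path).read_text().splitlines()
    title, names, res_ids, res_names, coords, box, _ = _parse_gro_block(
        lines, 0, path
    )
    chains = _infer_gro_chains(res_ids)
    system = _build_system(
        names, res_ids, res_names, chains, class_table, backbone_names
    )
    m = _GRO_TIME_RE.search(title)
    time = float(m.group(1)) if m else 0.0
    return system, Frame(coords, box=box, time=time)


def write_gro(path, system: BeadSystem, frame: Frame, title: str = "peptergent") -> None:
    with open(path, "w") as fh:
        _write_gro_block(fh, system, frame, title)


def _write_gro_block(fh, system, frame, title):
    fh.write(f"{title} t= {frame.time:.3f}\n")
    fh.write(f"{system.n_beads:5d}\n")
    for bead, xyz in zip(system.beads, frame.coordinates):
        fh.write(
            "%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n"
            % (
                bead.residue_index % 100000,
                bead.residue_name[:5],
                bead.name[:5],
                (bead.index + 1) % 100000,
                xyz[0], xyz[1], xyz[2],
            )
        )
    if frame.box is not None:
        fh.write("%10.5f%10.5f%10.5f\n" % tuple(frame.box))
    else:
        fh.write("%10.5f%10.5f%10.5f\n" % (0.0, 0.0, 0.0))


def read_gro_trajectory(path, system: BeadSystem) -> Trajectory:
    """Read concatenated GRO blocks as a trajectory."""
    lines = Path(path).read_text().splitlines()
    offset = 0
    frames = []
    k = 0
    while offset < len(lines) and lines[offset].strip():
        title, _, _, _, coords, box, offset = _parse_gro_block(lines, offset, path)
        if coords.shape[0] != system.n_beads:
            raise StructureError(
                f"{path}: frame {k + 1} has {coords.shape[0]} beads, "
                f"system has {system.n_beads}"
            )
        m = _GRO_TIME_RE.search(title)
        frames.append(Frame(coords, box=box, time=float(m.group(1)) if m else np.nan))
        k += 1
    if not frames:
        raise StructureError(f"{path}: no frames found")
    return _finalize_trajectory(frames, system)


def write_gro_trajectory(path, traj: Trajectory, title: str = "peptergent") -> None:
    with open(path, "w") as fh:
        for frame in traj:
            _write_gro_block(fh, traj.system, frame, title)


def _finalize_trajectory(frames, system) -> Trajectory:
    times = np.array([fr.time for fr in frames])
    increasing = np.all(np.diff(times) > 0) if len(times) > 1 else True
    if np.any(np.isnan(times)) or not increasing:
        for k, fr in enumerate(frames):
            fr.time = float(k)
    return Trajectory(frames, system)


# ---------------------------------------------------------------------------
# PDB


def _atoms_from_pdb(path):
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        raise ParseError(f"{path}: malformed PDB ({exc})") from None
    if stack.array_length() == 0:
        raise StructureError(f"{path}: zero beads")
    return stack


def _pdb_box(stack):
    box_mat = stack.box
    if box_mat is None:
        return None
    box_mat = np.asarray(box_mat)
    if box_mat.ndim == 3:
        box_mat = box_mat[0]
    off_diag = box_mat - np.diag(np.diag(box_mat))
    if np.any(np.abs(off_diag) > 1e-6):
        raise StructureError("triclinic boxes are not supported")
    diag = np.diag(box_mat) / 10.0
    if np.all(diag > 0):
        return diag
    return None


def read_pdb(path, class_table: ClassTable | None = None,
             backbone_names=BACKBONE_NAMES) -> tuple[BeadSystem, Frame]:
    """Read the first model of a PDB file; Angstrom -> nm on the fly."""
    class_table = class_table or ClassTable.default()
    stack = _atoms_from_pdb(path)
    atoms = stack[0] if isinstance(stack, struc.AtomArrayStack) else stack
    system = _build_system(
        atoms.atom_name, atoms.res_id, atoms.res_name, atoms.chain_id,
        class_table, backbone_names,
    )
    return system, Frame(atoms.coord / 10.0, box=_pdb_box(stack))


def read_pdb_trajectory(path, system: BeadSystem) -> Trajectory:
    """Read a multi-model PDB as a trajectory (models become frames)."""
    stack = _atoms_from_pdb(path)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    box = _pdb_box(stack)
    # biotite requires equal atom counts across models; detect ragged
    # model sizes from the raw records for a frame-numbered error
    if stack.array_length() != system.n_beads:
        raise StructureError(
            f"{path}: frame 1 has {stack.array_length()} beads, "
            f"system has {system.n_beads}"
        )
    frames = [
        Frame(stack.coord[m] / 10.0, box=box, time=np.nan)
        for m in range(stack.stack_depth())
    ]
    return _finalize_trajectory(frames, system)


def _to_atom_array(system: BeadSystem, frame: Frame):
    n = system.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = frame.coordinates * 10.0
    atoms.chain_id = np.array([b.chain_id[:4] for b in system.beads])
    atoms.res_id = np.array([b.residue_index for b in system.beads])
    atoms.res_name = np.array([b.residue_name[:5] for b in system.beads])
    atoms.atom_name = np.array([b.name[:6] for b in system.beads])
    atoms.element = np.array(["C"] * n)
    atoms.hetero = np.array([False] * n)
    if frame.box is not None:
        atoms.box = np.diag(frame.box * 10.0)
    return atoms


def write_pdb(path, system: BeadSystem, frame: Frame) -> None:
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_to_atom_array(system, frame))
    pdb_file.write(str(path))


def write_pdb_trajectory(path, traj: Trajectory) -> None:
    arrays = [_to_atom_array(traj.system, fr) for fr in traj]
    stack = struc.stack(arrays)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# format-dispatching entry points (the module surface used by the CLI)


def read_structure(path, format: str | None = None,
                   class_table: ClassTable | None = None,
                   backbone_names=BACKBONE_NAMES) -> tuple[BeadSystem, Frame]:
    """Read a structure file; ``format`` in {'gro', 'pdb'} or inferred
    from the suffix."""
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "gro":
        return read_gro(path, class_table, backbone_names)
    if fmt == "pdb":
        return read_pdb(path, class_table, backbone_names)
    raise ValueError(f"unknown structure format {fmt!r}")


def read_trajectory(path, system: BeadSystem, format: str | None = None) -> Trajectory:
    """Read a trajectory; ``format`` in {'multi_gro', 'multi_model_pdb'}
    or inferred from the suffix."""
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt in ("gro", "multi_gro"):
        return read_gro_trajectory(path, system)
    if fmt in ("pdb", "multi_model_pdb"):
        return read_pdb_trajectory(path, system)
    raise ValueError(f"unknown trajectory format {fmt!r}")
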