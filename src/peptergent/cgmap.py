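"""MARTINI-style coarse-graining of atomistic protein structures.

Maps an all-atom PDB structure to one backbone bead (BB, the centroid
of N/CA/C/O) plus zero or more side-chain beads per residue, following
the MARTINI side-chain bead counts.  Used for surface-area checks on
real membrane proteins — e.g. bacteriorhodopsin (PDB 1PY6), whose CG
protein surface is the reference for the probe-0.256 nm SASA.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

import numpy as np

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .model import Bead, BeadSystem, ClassTable, Frame

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"

#: MARTINI-like side-chain mappings: residue -> list of atom groups,
#: each group becoming one side-chain bead at the group centroid.
SIDECHAIN_MAP: dict[str, list[list[str]]] = {
    "ALA": [],
    "GLY": [],
    "CYS": [["CB", "SG"]],
    "SER": [["CB", "OG"]],
    "THR": [["CB", "OG1", "CG2"]],
    "VAL": [["CB", "CG1", "CG2"]],
    "LEU": [["CB", "CG", "CD1", "CD2"]],
    "ILE": [["CB", "CG1", "CG2", "CD1"]],
    "MET": [["CB", "CG", "SD", "CE"]],
    "PRO": [["CB", "CG", "CD"]],
    "ASN": [["CB", "CG", "OD1", "ND2"]],
    "ASP": [["CB", "CG", "OD1", "OD2"]],
    "GLN": [["CB", "CG", "CD", "OE1", "NE2"]],
    "GLU": [["CB", "CG", "CD", "OE1", "OE2"]],
    "LYS": [["CB", "CG", "CD"], ["CE", "NZ"]],
    "ARG": [["CB", "CG", "CD"], ["NE", "CZ", "NH1", "NH2"]],
    "HIS": [["CB", "CG"], ["CD2", "NE2"], ["ND1", "CE1"]],
    "PHE": [["CB", "CG"], ["CD1", "CE1"], ["CD2", "CE2", "CZ"]],
    "TYR": [["CB", "CG"], ["CD1", "CE1"], ["CD2", "CE2", "CZ", "OH"]],
    "TRP": [["CB", "CG"], ["CD1", "NE1"], ["CD2", "CE2"], ["CE3", "CZ2", "CZ3", "CH2"]],
}

_BACKBONE_ATOMS = ("N", "CA", "C", "O")


def fetch_pdb(pdb_id: str, dest: str | Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry from the RCSB (requires network access)."""
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    url = RCSB_URL.format(pdb_id=pdb_id.upper())
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest


def coarse_grain_pdb(
    path: str | Path,
    class_table: ClassTable | None = None,
    model: int = 1,
) -> tuple[BeadSystem, Frame]:
    """MARTINI-style CG model of the protein part of an atomistic PDB.

    One BB bead per residue at the backbone centroid, plus side-chain
    beads at the MARTINI group centroids; waters, ligands and
    hydrogens are dropped.  Coordinates are converted to nm; all beads
    are assigned to group ``protein``.
    """
    class_table = class_table or ClassTable.default()
    pdb_file = pdbio.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=model)
    atoms = atoms[struc.filter_amino_acids(atoms) & (atoms.element != "H")]
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no protein atoms")
    beads: list[Bead] = []
    coords: list[np.ndarray] = []
    idx = 0
    for res in struc.residue_iter(atoms):
        rname = str(res.res_name[0])
        entry = class_table.lookup(rname)
        names = list(res.atom_name)
        bb_sel = [k for k, n in enumerate(names) if n in _BACKBONE_ATOMS]
        if not bb_sel:
            continue
        positions = [("BB", res.coord[bb_sel].mean(axis=0))]
        for g, grp in enumerate(SIDECHAIN_MAP.get(rname, [])):
            sel = [k for k, n in enumerate(names) if n in grp]
            if sel:
                positions.append((f"SC{g + 1}", res.coord[sel].mean(axis=0)))
        for bead_name, xyz in positions:
            beads.append(
                Bead(
                    index=idx,
                    name=bead_name,
                    residue_index=int(res.res_id[0]),
                    residue_name=rname,
                    chain_id=str(res.chain_id[0]),
                    is_backbone=bead_name == "BB",
                    radius=entry.radius,
                    hydropathy_class=entry.hydropathy,
                )
            )
            coords.append(xyz / 10.0)  # Angstrom -> nm
            idx += 1
    system = BeadSystem(beads, groups={"protein": range(len(beads))})
    return system, Frame(np.array(coords))
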