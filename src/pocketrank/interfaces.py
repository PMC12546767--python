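"""Readers for the standard formats the tool touches.

SMILES lists and SDF files populate the ligand registry (canonicalised so
identical molecules share features regardless of input form); PDB files
yield pocket structures cropped to the residues within a heavy-atom radius
of a reference ligand, or to an explicit residue list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class InputError(ValueError):
    pass


@dataclass
class PocketStructure:
    """A pocket as a residue subset of a PDB structure."""

    pocket_id: str
    residues: list  # (chain, residue number, one-letter type, coords (k,3))
    source: str = ""

    @property
    def sequence(self) -> str:
        return "".join(r[2] for r in self.residues)

    def record(self) -> dict:
        return {
            "pocket_id": self.pocket_id,
            "sequence": self.sequence,
            "residues": self.residues,
        }

    def __len__(self):
        return len(self.residues)


def read_ligands(path) -> dict:
    """Ligand registry from a ``.smi`` (id-whitespace-smiles or
    smiles-whitespace-id) or ``.sdf`` file.  Parse failures are collected
    and reported; duplicate ids are an error."""
    from rdkit import Chem

    path = Path(path)
    registry, failures = {}, []

    def add(lid, mol, raw):
        if mol is None:
            failures.append((lid, raw))
            return
        if lid in registry:
            raise InputError(f"duplicate ligand_id {lid!r}")
        registry[lid] = {
            "ligand_id": lid,
            "smiles": Chem.MolToSmiles(mol),  # canonical form
        }

    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    try:
        if path.suffix.lower() == ".sdf":
            supplier = Chem.SDMolSupplier(str(path), sanitize=True)
            for i, mol in enumerate(supplier):
                lid = (
                    mol.GetProp("_Name")
                    if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name")
                    else f"mol_{i}"
                )
                add(lid, mol, f"record {i}")
        else:
            # .smi convention here: id-whitespace-smiles; a single column is
            # bare SMILES with generated ids
            with open(path) as fh:
                for i, line in enumerate(fh):
                    parts = line.split()
                    if not parts:
                        continue
                    if len(parts) == 1:
                        lid, smi = f"mol_{i}", parts[0]
                    else:
                        lid, smi = parts[0], parts[1]
                    add(lid, Chem.MolFromSmiles(smi), smi)
    finally:
        RDLogger.EnableLog("rdApp.error")
    if failures:
        logger.warning(
            "failed to parse %d ligand(s): %s", len(failures), [f[0] for f in failures]
        )
    if not registry:
        raise InputError(f"no valid ligands in {path}")
    return registry


def extract_pocket(
    pdb_path,
    reference=None,
    residue_list=None,
    radius: float = 6.0,
    pocket_id: str | None = None,
) -> PocketStructure:
    """Crop a pocket out of a PDB file.

    `reference` names a hetero residue (the co-crystallised ligand); every
    protein residue with a heavy atom within `radius` angstroms of any of
    its heavy atoms is kept.  `residue_list` — (chain, resnum) pairs —
    bypasses the distance rule.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_path = Path(pdb_path)
    structure = pdb.PDBFile.read(str(pdb_path)).get_structure(model=1)
    heavy = structure[structure.element != "H"]
    protein = heavy[struc.filter_amino_acids(heavy)]
    if protein.array_length() == 0:
        raise InputError(f"no protein residues in {pdb_path}")

    if residue_list is not None:
        wanted = {(str(c), int(r)) for c, r in residue_list}
        keep = np.array(
            [
                (str(c), int(r)) in wanted
                for c, r in zip(protein.chain_id, protein.res_id)
            ]
        )
    else:
        if reference is None:
            raise InputError("need a reference residue name or an explicit residue list")
        ref = heavy[heavy.res_name == reference]
        if ref.array_length() == 0:
            raise InputError(f"reference residue {reference!r} absent from {pdb_path}")
        d2 = (
            ((protein.coord[:, None, :] - ref.coord[None, :, :]) ** 2).sum(-1)
        )
        near_atom = (d2 <= radius**2).any(axis=1)
        near_res = {
            (str(c), int(r))
            for c, r in zip(
                protein.chain_id[near_atom], protein.res_id[near_atom]
            )
        }
        keep = np.array(
            [
                (str(c), int(r)) in near_res
                for c, r in zip(protein.chain_id, protein.res_id)
            ]
        )

    sel = protein[keep]
    residues = []
    for chain, resnum in sorted(
        {(str(c), int(r)) for c, r in zip(sel.chain_id, sel.res_id)}
    ):
        m = (sel.chain_id == chain) & (sel.res_id == resnum)
        res_name = str(sel.res_name[m][0])
        one = THREE_TO_ONE.get(res_name, "X")
        residues.append((chain, resnum, one, sel.coord[m].copy()))
    if not residues:
        raise InputError(f"empty pocket extracted from {pdb_path}")
    return PocketStructure(
        pocket_id=pocket_id or f"{pdb_path.stem}:{reference or 'list'}",
        residues=residues,
        source=pdb_path.name,
    )
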