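"""Molecule, activity-table and pharmacophore-model I/O.

Molecules are carried as :class:`MoleculeRecord` objects wrapping an RDKit
mol plus zero or more 3D conformers (coordinates in Å, exactly as stored in
the SDF — no re-centering or axis convention changes on input, since fit
values depend on absolute geometry). Activities are IC50 values in μM.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

log = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


class ChemIOError(RuntimeError):
    """Fatal I/O error: unreadable file, empty dataset, schema mismatch."""


@dataclass
class MoleculeRecord:
    """A compound: id, topology, 3D conformers, optional activity.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    mol : rdkit.Chem.Mol
        Topology (and, via RDKit conformers, geometry).
    conformers : list of (n_atoms, 3) float arrays
        Heavy-atom coordinates in Å, one array per conformer.
    activity_ic50 : float, optional
        Experimental IC50 in μM; must be positive when present.
    properties : dict
        Open descriptor cache (MW, logP, ... filled lazily by filters).
    """

    id: str
    mol: Chem.Mol
    conformers: list = field(default_factory=list)
    activity_ic50: float | None = None
    properties: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.mol.GetNumAtoms()
        conf = []
        for c in self.conformers:
            arr = np.asarray(c, dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(
                    f"{self.id}: conformer shape {arr.shape} != ({n}, 3)")
            conf.append(arr)
        self.conformers = conf
        if self.activity_ic50 is not None and not self.activity_ic50 > 0:
            raise ValueError(f"{self.id}: IC50 must be > 0")

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    def has_3d(self) -> bool:
        return len(self.conformers) > 0

    @classmethod
    def from_smiles(cls, id: str, smiles: str, **kw) -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ChemIOError(f"{id}: unparsable SMILES {smiles!r}")
        return cls(id=id, mol=mol, **kw)


def _record_from_rdkit(mol: Chem.Mol, fallback_id: str) -> MoleculeRecord:
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    rid = name.strip() or fallback_id
    confs = [np.array(c.GetPositions(), dtype=float) for c in mol.GetConformers()]
    act = None
    if mol.HasProp("IC50_uM"):
        act = float(mol.GetProp("IC50_uM"))
    return MoleculeRecord(id=rid, mol=Chem.Mol(mol, True), conformers=confs,
                          activity_ic50=act)


def read_molecules(path, fmt: str = "sdf") -> tuple[list[MoleculeRecord], int]:
    """Read molecules from an SDF (V2000) or SMILES file.

    Returns ``(records, n_skipped)``. Per-molecule parse failures are logged
    and counted, so ``len(records) + n_skipped`` equals the number of input
    blocks. Zero parsable molecules is a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    records, skipped = [], 0
    if fmt == "sdf":
        try:
            supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        except OSError as exc:
            raise ChemIOError(f"unreadable SDF {path}: {exc}") from exc
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                log.warning("skipping unparsable SDF block %d in %s", i, path)
                continue
            records.append(_record_from_rdkit(mol, fallback_id=f"mol{i}"))
    elif fmt == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                skipped += 1
                log.warning("skipping unparsable SMILES line %d in %s", i, path)
                continue
            rid = parts[1] if len(parts) > 1 else f"mol{i}"
            records.append(MoleculeRecord(id=rid, mol=mol))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not records:
        raise ChemIOError(f"no parsable molecules in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ChemIOError(f"duplicate molecule ids in {path}")
    return records, skipped


def write_molecules(records, path) -> None:
    """Write records to SDF; every conformer of a record becomes a conformer
    of its mol block (first conformer only is emitted per molecule block,
    additional conformers as extra blocks with the same id suffixed)."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for rec in records:
        mol = Chem.Mol(rec.mol)
        mol.RemoveAllConformers()
        for arr in rec.conformers:
            conf = Chem.Conformer(mol.GetNumAtoms())
            for j, xyz in enumerate(arr):
                conf.SetAtomPosition(j, tuple(float(v) for v in xyz))
            mol.AddConformer(conf, assignId=True)
        mol.SetProp("_Name", rec.id)
        if rec.activity_ic50 is not None:
            mol.SetProp("IC50_uM", repr(rec.activity_ic50))
        if mol.GetNumConformers() == 0:
            writer.write(mol)
        else:
            for cid in range(mol.GetNumConformers()):
                writer.write(mol, confId=cid)
    writer.close()


def read_activity_table(path) -> pd.DataFrame:
    """Read a (compound id, IC50 μM) CSV.

    The header must contain an id-like column and an IC50-like column
    (case-insensitive match on 'id'/'compound' and 'ic50'). IC50 values must
    be positive numbers; a bad row is a fatal error naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # empty or malformed
        raise ChemIOError(f"unreadable activity table {path}: {exc}") from exc
    if df.empty:
        raise ChemIOError(f"empty activity table: {path}")
    id_col = next((c for c in df.columns
                   if c.lower() in ("id", "compound", "compound_id", "compound no.")), None)
    ic_col = next((c for c in df.columns if "ic50" in c.lower()), None)
    if id_col is None or ic_col is None:
        raise ChemIOError(f"{path}: need an id column and an IC50 column, "
                          f"got {list(df.columns)}")
    out = pd.DataFrame({"id": df[id_col].astype(str),
                        "ic50_uM": pd.to_numeric(df[ic_col], errors="coerce")})
    for i, v in out["ic50_uM"].items():
        if not np.isfinite(v) or v <= 0:
            raise ChemIOError(f"{path}: row {i} (id={out['id'][i]}): "
                              f"IC50 must be a positive number, got {df[ic_col][i]!r}")
    if out["id"].duplicated().any():
        dups = out["id"][out["id"].duplicated()].tolist()
        raise ChemIOError(f"{path}: duplicate compound ids {dups}")
    return out


# --- pharmacophore model documents -----------------------------------------

def write_model(model, path) -> None:
    """Serialize a PharmacophoreModel to a versioned JSON document."""
    doc = {"schema_version": MODEL_SCHEMA_VERSION, "model": model.to_dict()}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_model(path):
    """Read a model document written by :func:`write_model`."""
    from .pharmacophore import PharmacophoreModel
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ChemIOError(f"unreadable model document {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ChemIOError(
            f"{path}: schema version {version!r} != {MODEL_SCHEMA_VERSION}")
    return PharmacophoreModel.from_dict(doc["model"])
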