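"""Ligand library reading, validation and deduplication.

Supported formats: SDF (V2000), SMILES (``.smi``; one molecule per line with
an optional whitespace-separated name), canonical SMILES (``can``, treated as
a SMILES dialect), MOL, MOL2 and PDB.  Parsing is delegated to RDKit; records
that fail sanitisation are reported, never fatal.

Validation enforces graph-level completeness only (an id, at least one heavy
atom, valid valences); 3-D conformers are the job of the external conformer
generator.  "Repetitive" records are detected by canonical structure —
canonical isomeric SMILES — rather than by identifier, with first occurrence
winning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # rejection reasons are reported through our own channel

SUPPORTED_FORMATS = ("sdf", "smiles", "smi", "can", "mol", "mol2", "pdb")


class LigandFormatError(ValueError):
    pass


@dataclass
class LigandRecord:
    """One library compound: identifier, molecular graph, optional 3-D coordinates."""

    ligand_id: str
    mol: Chem.Mol
    coords_3d: np.ndarray | None = None  # (n_atoms, 3) Å, heavy+H as stored
    source_file: str = ""
    record_index: int = 0  # 1-based position in the source file

    @property
    def n_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()


@dataclass
class RejectedRecord:
    ligand_id: str
    reason: str  # machine-readable: "unparseable", "incomplete:<why>", "duplicate:<of-id>"
    source_file: str = ""
    record_index: int = 0


def _record_id(mol: Chem.Mol | None, stem: str, index: int) -> str:
    """Title-line / property name, else synthesised ``<file-stem>_<index>`` (1-based)."""
    if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name").strip():
        return mol.GetProp("_Name").strip()
    return f"{stem}_{index}"


def _conformer_coords(mol: Chem.Mol) -> np.ndarray | None:
    if mol.GetNumConformers() == 0:
        return None
    conf = mol.GetConformer()
    if not conf.Is3D():
        return None
    return np.asarray(conf.GetPositions(), dtype=float)


def _iter_sdf(path: Path) -> Iterator[tuple[Chem.Mol | None, int]]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
    for i, mol in enumerate(supplier, start=1):
        yield mol, i


def _iter_smiles(path: Path) -> Iterator[tuple[Chem.Mol | None, int]]:
    index = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            index += 1
            parts = line.split(None, 1)
            mol = Chem.MolFromSmiles(parts[0])
            if mol is not None and len(parts) > 1:
                mol.SetProp("_Name", parts[1].strip())
            yield mol, index


def _iter_mol2(path: Path) -> Iterator[tuple[Chem.Mol | None, int]]:
    text = path.read_text()
    blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
    for i, block in enumerate(blocks, start=1):
        yield Chem.MolFromMol2Block(block, sanitize=True, removeHs=False), i


def _iter_single(path: Path, fmt: str) -> Iterator[tuple[Chem.Mol | None, int]]:
    if fmt == "mol":
        mol = Chem.MolFromMolFile(str(path), sanitize=True, removeHs=False)
    else:  # pdb
        mol = Chem.MolFromPDBFile(str(path), sanitize=True, removeHs=False)
    yield mol, 1


def read_library(
    path: str | Path,
    format: str | None = None,
    rejected: list[RejectedRecord] | None = None,
) -> Iterator[LigandRecord]:
    """Stream :class:`LigandRecord` objects from a ligand library file.

    Parameters
    ----------
    path : library file.
    format : one of ``sdf, smiles/smi, can, mol, mol2, pdb``; inferred from
        the file suffix when omitted.
    rejected : optional list collecting unparseable records (id synthesised
        from file stem + index) instead of only logging them.

    Raises :class:`LigandFormatError` when no record of a non-empty file can
    be parsed; an empty file yields an empty stream with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("smi", "can"):
        fmt = "smiles"
    if fmt not in ("sdf", "smiles", "mol", "mol2", "pdb"):
        raise LigandFormatError(f"unsupported format {fmt!r}; supported: {SUPPORTED_FORMATS}")

    if path.stat().st_size == 0:
        logger.warning("ligand library %s is empty", path.name)
        return

    if fmt == "sdf":
        records = _iter_sdf(path)
    elif fmt == "smiles":
        records = _iter_smiles(path)
    elif fmt == "mol2":
        records = _iter_mol2(path)
    else:
        records = _iter_single(path, fmt)

    n_total = n_parsed = 0
    for mol, index in records:
        n_total += 1
        if mol is None:
            reason = RejectedRecord(
                ligand_id=f"{path.stem}_{index}",
                reason="unparseable",
                source_file=path.name,
                record_index=index,
            )
            logger.warning("rejected record %d of %s: unparseable", index, path.name)
            if rejected is not None:
                rejected.append(reason)
            continue
        n_parsed += 1
        yield LigandRecord(
            ligand_id=_record_id(mol, path.stem, index),
            mol=mol,
            coords_3d=_conformer_coords(mol),
            source_file=path.name,
            record_index=index,
        )
    if n_total and not n_parsed:
        raise LigandFormatError(f"no record of {path.name} could be parsed as {fmt}")


def canonical_key(mol: Chem.Mol, use_stereo: bool = True) -> str:
    """Canonical structure key: canonical SMILES, stereo included by default.

    Invariant under atom reordering of the input record.
    """
    return Chem.MolToSmiles(mol, isomericSmiles=use_stereo)


def validate_and_dedupe(
    records: Iterable[LigandRecord], use_stereo: bool = True
) -> tuple[list[LigandRecord], list[tuple[LigandRecord, str]]]:
    """Split a record stream into validated-unique ``kept`` and ``rejected`` lists.

    A record is rejected as incomplete when it has no id or no heavy atoms;
    later records with a canonical structure key already seen are rejected as
    duplicates (first occurrence wins).  ``|kept| + |rejected| == |input|``.
    """
    kept: list[LigandRecord] = []
    rejected: list[tuple[LigandRecord, str]] = []
    seen: dict[str, str] = {}
    for rec in records:
        if not rec.ligand_id or not rec.ligand_id.strip():
            rejected.append((rec, "incomplete:missing-id"))
            continue
        if rec.mol is None or rec.mol.GetNumHeavyAtoms() < 1:
            rejected.append((rec, "incomplete:no-heavy-atoms"))
            continue
        try:
            key = canonical_key(rec.mol, use_stereo=use_stereo)
        except Exception:
            rejected.append((rec, "incomplete:uncanonicalisable"))
            continue
        if key in seen:
            rejected.append((rec, f"duplicate:{seen[key]}"))
            continue
        seen[key] = rec.ligand_id
        kept.append(rec)
    return kept, rejected
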