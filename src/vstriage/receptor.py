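"""Receptor preparation: clean a raw PDB into a single-chain, ligand/water/ion-free structure.

The cleaning step mirrors what a screening pipeline does before handing the
receptor to the docking engine's own preparation tools: drop pre-existing
ligands, water molecules and ions, keep a single chain, and renumber atom
serials.  Protonation, charge assignment and PDBQT conversion are left to the
external engine-preparation tools.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .geometry import Box

logger = logging.getLogger(__name__)

#: Residue names recognised as water (case-insensitive).
WATER_NAMES = frozenset({"HOH", "WAT", "H2O"})

#: Monoatomic-ion residue names commonly deposited as HETATM groups.
ION_NAMES = frozenset({"NA", "CL", "MG", "ZN", "CA", "K", "MN", "FE"})


class ReceptorError(ValueError):
    pass


class ChainNotFoundError(ReceptorError):
    def __init__(self, chain: str, available: Iterable[str]):
        self.chain = chain
        self.available = sorted(set(available))
        super().__init__(
            f"chain not found: {chain!r}; available chains: {{{', '.join(self.available)}}}"
        )


@dataclass(frozen=True)
class Atom:
    """One ATOM/HETATM record (PDB fixed-column convention, coordinates in Å)."""

    record_kind: str  # "ATOM" or "HETATM"
    serial: int
    name: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_number: int
    x: float
    y: float
    z: float
    occupancy: float | None = None
    b_factor: float | None = None
    element: str = ""


@dataclass(frozen=True)
class ReceptorStructure:
    atoms: tuple[Atom, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ReceptorError(f"non-finite coordinate in atom serial {a.serial}")

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class CleaningReport:
    """Per-category counts of records removed by :func:`clean_receptor`."""

    kept: int = 0
    other_chains: int = 0
    waters: int = 0
    ions: int = 0
    het_ligands: int = 0
    alt_locations: int = 0
    removed_by_residue: dict[str, int] = field(default_factory=dict)


def _is_water(residue_name: str) -> bool:
    return residue_name.strip().upper() in WATER_NAMES


def _is_ion(residue_name: str) -> bool:
    return residue_name.strip().upper() in ION_NAMES


def clean_receptor(
    raw: ReceptorStructure,
    keep_chain: str,
    het_whitelist: Iterable[str] = (),
    report: CleaningReport | None = None,
) -> ReceptorStructure:
    """Return a single-chain receptor with waters, ions and ligands removed.

    Parameters
    ----------
    raw : structure to clean (first model of a PDB file).
    keep_chain : chain identifier to retain.
    het_whitelist : residue names of HETATM groups (e.g. essential cofactors)
        to keep despite the default ligand/water/ion removal.  Only groups on
        ``keep_chain`` are retained, so the single-chain invariant holds.
    report : optional mutable report receiving per-category removal counts.

    The operation is idempotent and never alters coordinates; atom serials are
    renumbered consecutively from 1.  Alternate locations other than '' / 'A'
    are dropped.
    """
    if not raw.atoms:
        raise ReceptorError("empty receptor structure")
    if keep_chain not in raw.chains:
        raise ChainNotFoundError(keep_chain, raw.chains)

    whitelist = {r.strip().upper() for r in het_whitelist}
    rep = report if report is not None else CleaningReport()
    kept: list[Atom] = []
    for a in raw.atoms:
        if a.chain_id != keep_chain:
            rep.other_chains += 1
            continue
        if a.alt_loc not in ("", " ", "A"):
            rep.alt_locations += 1
            continue
        resname = a.residue_name.strip().upper()
        if a.record_kind == "HETATM" and resname not in whitelist:
            if _is_water(resname):
                rep.waters += 1
            elif _is_ion(resname):
                rep.ions += 1
            else:
                rep.het_ligands += 1
            rep.removed_by_residue[resname] = rep.removed_by_residue.get(resname, 0) + 1
            continue
        # ATOM records named as water do occur in sloppy files; drop them too.
        if _is_water(resname) and resname not in whitelist:
            rep.waters += 1
            continue
        kept.append(a)

    if not kept:
        raise ReceptorError(
            f"cleaning chain {keep_chain!r} left no atoms "
            "(chain may contain only water/ligand records)"
        )
    rep.kept = len(kept)
    renumbered = tuple(replace(a, serial=i) for i, a in enumerate(kept, start=1))
    return ReceptorStructure(atoms=renumbered, source_id=raw.source_id)


def receptor_grid_bounds(r: ReceptorStructure, margin: float = 0.0) -> Box:
    """Axis-aligned bounding box of all atoms, expanded by ``margin`` on every face.

    Used to derive the blind-docking grid box that must enclose the whole
    protein surface.
    """
    if not r.atoms:
        raise ReceptorError("empty receptor structure")
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    xs = [a.x for a in r.atoms]
    ys = [a.y for a in r.atoms]
    zs = [a.z for a in r.atoms]
    lo = (min(xs) - margin, min(ys) - margin, min(zs) - margin)
    hi = (max(xs) + margin, max(ys) + margin, max(zs) + margin)
    centre = tuple((l + h) / 2.0 for l, h in zip(lo, hi))
    edges = tuple(h - l for l, h in zip(lo, hi))
    return Box(centre=centre, edges=edges)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# PDB fixed-column I/O (ATOM/HETATM records only; first MODEL of NMR files)
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, model: int = 1) -> ReceptorStructure:
    """Read ATOM/HETATM records from a PDB file (first model by default)."""
    path = Path(path)
    atoms: list[Atom] = []
    current_model = 1
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current_model = int(line.split()[1])
                continue
            if rec == "ENDMDL":
                current_model += 1
                continue
            if rec not in ("ATOM", "HETATM") or current_model != model:
                continue
            try:
                atoms.append(
                    Atom(
                        record_kind=rec,
                        serial=int(line[6:11]),
                        name=line[12:16].strip(),
                        alt_loc=line[16:17].strip(),
                        residue_name=line[17:20].strip(),
                        chain_id=line[21:22],
                        residue_number=int(line[22:26]),
                        x=float(line[30:38]),
                        y=float(line[38:46]),
                        z=float(line[46:54]),
                        occupancy=float(line[54:60]) if line[54:60].strip() else None,
                        b_factor=float(line[60:66]) if line[60:66].strip() else None,
                        element=line[76:78].strip() if len(line) >= 78 else "",
                    )
                )
            except ValueError as exc:
                raise ReceptorError(f"malformed PDB record in {path.name}: {line.rstrip()!r}") from exc
    return ReceptorStructure(atoms=tuple(atoms), source_id=path.stem)


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: element right-justified in cols 13-14 for 1-letter elements
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2 or (not element and len(name) == 4):
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(structure: ReceptorStructure, path: str | Path) -> None:
    """Write fixed-column ATOM/HETATM records; missing occupancy/B default to 1.00/0.00."""
    with open(path, "w") as fh:
        for a in structure.atoms:
            occ = a.occupancy if a.occupancy is not None else 1.00
            b = a.b_factor if a.b_factor is not None else 0.00
            fh.write(
                f"{a.record_kind:<6s}{a.serial:>5d} {_format_atom_name(a.name, a.element)}"
                f"{a.alt_loc or ' '}{a.residue_name:>3s} {a.chain_id:1s}{a.residue_number:>4d}    "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{occ:6.2f}{b:6.2f}          "
                f"{a.element:>2s}\n"
            )
        fh.write("END\n")
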