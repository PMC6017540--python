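"""The 16-parameter compound summary table, iterative filtering and top-N selection.

Every docked compound gets one row holding, in fixed order: MW, cLogS, cLogP,
HBD, HBA, PSA, rotatable_bonds, ΔG, Ki, LE, BEI, SEI, NSEI, NBEI, nBEI, mBEI.
The table is a pandas DataFrame indexed by ``ligand_id`` and is written as
both ``output.csv`` and ``output.tsv`` (and ``filtered_output.{csv,tsv}``
after filtering), so it can be eyeballed in a spreadsheet or re-read by this
package.

Filters are ordered chains of ``parameter <cmp> threshold`` conditions and can
be applied iteratively; compounds whose value for a filtered parameter is
undefined (NaN — e.g. SEI of a compound with zero PSA) are excluded by any
filter on that parameter but survive filters on other columns.
"""

from __future__ import annotations

import math
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .descriptors import DescriptorSet
from .efficiency import compute_indices

#: The 16 summary parameters, in canonical column order.
SUMMARY_COLUMNS = (
    "MW", "cLogS", "cLogP", "HBD", "HBA", "PSA", "rotatable_bonds",
    "dG", "Ki", "LE", "BEI", "SEI", "NSEI", "NBEI", "nBEI", "mBEI",
)

_COMPARATORS = {
    "<=": lambda s, t: s <= t,
    ">=": lambda s, t: s >= t,
    "<": lambda s, t: s < t,
    ">": lambda s, t: s > t,
    "=": lambda s, t: s == t,
    "==": lambda s, t: s == t,
}


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class FilterCondition:
    parameter: str
    comparator: str  # one of <=, >=, <, >, =
    threshold: float

    def __post_init__(self) -> None:
        if self.parameter not in SUMMARY_COLUMNS:
            raise FilterError(
                f"unknown parameter {self.parameter!r}; valid parameters: "
                f"{', '.join(SUMMARY_COLUMNS)}"
            )
        if self.comparator not in _COMPARATORS:
            raise FilterError(f"unknown comparator {self.comparator!r}")


def parse_filter(expr: str) -> FilterCondition:
    """Parse ``"PSA<50"`` / ``"cLogP <= 5"`` style filter expressions."""
    for op in ("<=", ">=", "==", "<", ">", "="):
        if op in expr:
            left, right = expr.split(op, 1)
            try:
                thr = float(right.strip())
            except ValueError as exc:
                raise FilterError(f"non-numeric threshold in filter {expr!r}") from exc
            return FilterCondition(left.strip(), "=" if op == "==" else op, thr)
    raise FilterError(f"no comparator found in filter {expr!r}")


def build_summary(
    descriptors: Mapping[str, DescriptorSet],
    energies: Sequence[tuple[str, float]] | Mapping[str, float],
    T: float = 298.15,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Assemble the per-compound summary table.

    Parameters
    ----------
    descriptors : ligand id → :class:`DescriptorSet`.
    energies : ligand id → best-pose ΔG (kcal/mol); an ordered sequence of
        ``(id, dG)`` pairs fixes the row order (mapping order otherwise).

    Returns ``(table, failures)``; a ligand with an energy but no descriptors
    becomes a failure entry and the run continues.
    """
    pairs = list(energies.items()) if isinstance(energies, Mapping) else list(energies)
    rows: list[dict] = []
    index: list[str] = []
    failures: list[tuple[str, str]] = []
    for lid, dg in pairs:
        d = descriptors.get(lid)
        if d is None:
            failures.append((lid, "no descriptors for docked ligand"))
            continue
        idx = compute_indices(dg, d, T=T)
        rows.append(
            {
                "MW": d.MW, "cLogS": d.cLogS, "cLogP": d.cLogP, "HBD": d.HBD,
                "HBA": d.HBA, "PSA": d.PSA, "rotatable_bonds": d.rotatable_bonds,
                "dG": dg, "Ki": idx.Ki, "LE": idx.LE, "BEI": idx.BEI,
                "SEI": idx.SEI, "NSEI": idx.NSEI, "NBEI": idx.NBEI,
                "nBEI": idx.nBEI, "mBEI": idx.mBEI,
            }
        )
        index.append(lid)
    table = pd.DataFrame(rows, index=pd.Index(index, name="ligand_id"), columns=list(SUMMARY_COLUMNS))
    return table, failures


def apply_filters(
    rows: pd.DataFrame, conditions: Iterable[FilterCondition | str]
) -> pd.DataFrame:
    """Apply an ordered chain of conditions; row order is preserved.

    NaN values never satisfy a condition, so a filter on an undefined index
    drops that compound.
    """
    out = rows
    for cond in conditions:
        if isinstance(cond, str):
            cond = parse_filter(cond)
        elif cond.parameter not in rows.columns:
            raise FilterError(
                f"unknown parameter {cond.parameter!r}; valid parameters: "
                f"{', '.join(rows.columns)}"
            )
        mask = _COMPARATORS[cond.comparator](out[cond.parameter], cond.threshold)
        out = out[mask.fillna(False)]
    return out


def top_n_by_dG(rows: pd.DataFrame, n: int) -> pd.DataFrame:
    """The ``n`` most-negative-ΔG rows, sorted ascending by ΔG.

    Ties are broken by ligand id (stable, deterministic).  ``n`` larger than
    the table returns everything.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    # stable sort: first by id, then by dG, so equal energies fall back to id order
    ordered = rows.sort_index(kind="mergesort").sort_values("dG", kind="mergesort")
    return ordered.head(n)


def summarize_distribution(rows: pd.DataFrame, parameter: str, threshold: float) -> float:
    """Percentage of compounds with ``parameter`` strictly below ``threshold``.

    E.g. the share of a cluster's hits with PSA < 50 Å², a quick polarity
    read-out when comparing binding sites.  NaN for an empty table.
    """
    if parameter not in rows.columns:
        raise FilterError(f"unknown parameter {parameter!r}")
    if len(rows) == 0:
        return math.nan
    return 100.0 * float((rows[parameter] < threshold).sum()) / len(rows)


# ---------------------------------------------------------------------------
# Result-bundle I/O
# ---------------------------------------------------------------------------

def write_summary(rows: pd.DataFrame, out_dir: str | Path, basename: str = "output") -> tuple[Path, Path]:
    """Write ``<basename>.csv`` and ``<basename>.tsv`` (comma / tab, dot decimal)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{basename}.csv"
    tsv_path = out_dir / f"{basename}.tsv"
    rows.to_csv(csv_path, float_format="%.6g")
    rows.to_csv(tsv_path, sep="\t", float_format="%.6g")
    return csv_path, tsv_path


def read_summary(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith(".tsv") else ","
    return pd.read_csv(path, sep=sep, index_col="ligand_id")


def copy_filtered_poses(
    filtered: pd.DataFrame, pose_dir: str | Path, out_dir: str | Path
) -> list[str]:
    """Copy the pose PDB files of surviving ligands into a filtered subdirectory."""
    pose_dir, out_dir = Path(pose_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    copied = []
    for lid in filtered.index:
        src = pose_dir / f"{lid}.pdb"
        if src.exists():
            shutil.copyfile(src, out_dir / src.name)
            copied.append(lid)
    return copied
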