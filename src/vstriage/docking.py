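"""Parse docking-engine outputs and extract the lowest-energy pose per ligand.

Two engine dialects are read:

* **Vina result PDBQT** — one ``MODEL``/``ENDMDL`` block per pose, each with a
  ``REMARK VINA RESULT: <affinity> <rmsd_lb> <rmsd_ub>`` line; affinity is the
  predicted binding free energy in kcal/mol.
* **AutoDock DLG** — the docking log; each run is echoed in ``DOCKED:``-prefixed
  lines, with the score on the ``Estimated Free Energy of Binding`` line.

Ligand identity is taken from the result filename stem (one result file per
ligand, the layout screening pipelines produce).  Best poses are written back
out as plain PDB files so any structure viewer can inspect them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

#: PDBQT/AutoDock atom types regarded as hydrogen (excluded from pose centroids).
_HYDROGEN_TYPES = frozenset({"H", "HD", "HS"})


class DockingParseError(ValueError):
    pass


@dataclass
class DockedPose:
    """One scored pose: ligand id, binding free energy and heavy-atom coordinates."""

    ligand_id: str
    dG: float  # kcal/mol; more negative = stronger predicted binding
    coords: np.ndarray  # (n_heavy, 3) Å
    engine: str  # "vina" | "ad4"
    pose_rank: int  # 1 = best (minimum dG) within the ligand's result file

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def _element_of_pdbqt_atom(line: str) -> str:
    # AutoDock atom type lives in cols 78-79 of PDBQT ATOM records
    atype = line[77:79].strip() if len(line) > 77 else ""
    if not atype:
        atype = line[12:16].strip()[:1]
    return atype.upper()


def _parse_pdbqt_atoms(lines: Iterable[str]) -> np.ndarray:
    coords = []
    for line in lines:
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if _element_of_pdbqt_atom(line) in _HYDROGEN_TYPES:
            continue
        coords.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
    return np.asarray(coords, dtype=float)


def _rank_poses(poses: list[DockedPose], source: str) -> list[DockedPose]:
    """Assign ranks by energy.  Engines occasionally emit unsorted models; those
    are re-ranked with a warning.  Ties keep first-occurrence order (stable sort)."""
    energies = [p.dG for p in poses]
    if energies != sorted(energies):
        warnings.warn(f"{source}: poses out of energy order; re-ranking", stacklevel=3)
        poses = sorted(poses, key=lambda p: p.dG)
    for rank, p in enumerate(poses, start=1):
        p.pose_rank = rank
    return poses


def parse_vina_result(path: str | Path, ligand_id: str | None = None) -> list[DockedPose]:
    """Read all poses of one ligand from a Vina output PDBQT.

    Returns poses ordered by rank (rank 1 = minimum dG).  A file with no
    ``MODEL`` blocks yields an empty list with a warning; a malformed
    ``REMARK VINA RESULT`` line raises :class:`DockingParseError` naming the
    line number.
    """
    path = Path(path)
    lid = ligand_id or path.stem
    poses: list[DockedPose] = []
    model_lines: list[str] | None = None
    model_dg: float | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                model_lines, model_dg = [], None
                continue
            if line.startswith("ENDMDL"):
                if model_lines is None:
                    raise DockingParseError(f"{path.name}:{lineno}: ENDMDL outside MODEL")
                if model_dg is None:
                    raise DockingParseError(
                        f"{path.name}: MODEL ending at line {lineno} has no REMARK VINA RESULT"
                    )
                coords = _parse_pdbqt_atoms(model_lines)
                if coords.size == 0:
                    raise DockingParseError(f"{path.name}: pose ending at line {lineno} has no atoms")
                poses.append(DockedPose(lid, model_dg, coords, "vina", pose_rank=len(poses) + 1))
                model_lines = None
                continue
            if model_lines is None:
                continue
            if line.startswith("REMARK VINA RESULT"):
                fields = line.split(":", 1)[-1].split()
                try:
                    model_dg = float(fields[0])
                except (IndexError, ValueError) as exc:
                    raise DockingParseError(
                        f"{path.name}:{lineno}: malformed REMARK VINA RESULT line: {line.rstrip()!r}"
                    ) from exc
                continue
            model_lines.append(line)
    if not poses:
        logger.warning("%s: no MODEL blocks found", path.name)
        return []
    return _rank_poses(poses, path.name)


def parse_autodock_dlg(path: str | Path, ligand_id: str | None = None) -> list[DockedPose]:
    """Read all docked runs from an AutoDock DLG log.

    dG comes from the ``Estimated Free Energy of Binding`` line of each
    ``DOCKED:`` block; the DLG's own cluster-rank order is preserved unless
    energies are out of order.  A truncated block raises
    :class:`DockingParseError` with the byte offset of the block start.
    """
    path = Path(path)
    lid = ligand_id or path.stem
    poses: list[DockedPose] = []
    block: list[str] | None = None
    block_offset = 0
    offset = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("DOCKED:"):
                payload = line[7:].lstrip(" ")
                if payload.startswith("MODEL"):
                    block = []
                    block_offset = offset
                elif block is not None:
                    if payload.startswith("ENDMDL"):
                        poses.append(_finish_dlg_block(block, lid, path, block_offset, len(poses)))
                        block = None
                    else:
                        block.append(payload)
            offset += len(line.encode())
    if block is not None:
        raise DockingParseError(
            f"{path.name}: truncated DOCKED block starting at byte offset {block_offset}"
        )
    if not poses:
        logger.warning("%s: no DOCKED blocks found", path.name)
        return []
    return _rank_poses(poses, path.name)


def _finish_dlg_block(
    block: list[str], lid: str, path: Path, offset: int, n_before: int
) -> DockedPose:
    dg = None
    for line in block:
        if "Estimated Free Energy of Binding" in line:
            after_eq = line.split("=", 1)[-1]
            try:
                dg = float(after_eq.split()[0])
            except (IndexError, ValueError) as exc:
                raise DockingParseError(
                    f"{path.name}: malformed energy line in block at byte offset {offset}"
                ) from exc
            break
    if dg is None:
        raise DockingParseError(
            f"{path.name}: DOCKED block at byte offset {offset} lacks an energy line"
        )
    coords = _parse_pdbqt_atoms(block)
    if coords.size == 0:
        raise DockingParseError(f"{path.name}: DOCKED block at byte offset {offset} has no atoms")
    return DockedPose(lid, dg, coords, "ad4", pose_rank=n_before + 1)


# ---------------------------------------------------------------------------
# Directory-level extraction
# ---------------------------------------------------------------------------

_PARSERS = {".pdbqt": parse_vina_result, ".dlg": parse_autodock_dlg}


def write_pose_pdb(pose: DockedPose, path: str | Path) -> None:
    """Write a pose's heavy-atom coordinates as a minimal PDB file."""
    with open(path, "w") as fh:
        fh.write(f"REMARK  ligand {pose.ligand_id}  dG {pose.dG:.3f} kcal/mol  engine {pose.engine}\n")
        for i, (x, y, z) in enumerate(pose.coords, start=1):
            fh.write(
                f"HETATM{i:>5d}  C   LIG A   1    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def read_pose_pdb(path: str | Path) -> np.ndarray:
    coords = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                coords.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
    return np.asarray(coords, dtype=float)


def extract_best_poses(
    results_dir: str | Path,
    pose_dir: str | Path | None = None,
    engine: str | None = None,
) -> tuple[list[tuple[str, float]], dict[str, DockedPose], list[tuple[str, str]]]:
    """Extract the lowest-energy pose of every ligand in a results directory.

    Parameters
    ----------
    results_dir : directory with one result file per ligand
        (``<ligand_id>.pdbqt`` for Vina, ``<ligand_id>.dlg`` for AutoDock).
    pose_dir : when given, the best pose of each ligand is written there as
        ``<ligand_id>.pdb``.
    engine : restrict to ``"vina"`` or ``"ad4"`` files; default: both.

    Returns ``(table, best_poses, failures)`` where ``table`` is a list of
    ``(ligand_id, dG)`` rows in filename order, ``best_poses`` maps ligand id
    to its rank-1 pose, and ``failures`` lists ``(filename, reason)`` for
    unreadable files.  Unreadable files never abort the run.
    """
    results_dir = Path(results_dir)
    suffixes = {".pdbqt"} if engine == "vina" else {".dlg"} if engine == "ad4" else set(_PARSERS)
    files = sorted(p for p in results_dir.iterdir() if p.suffix.lower() in suffixes)
    if not files:
        logger.warning("no result files found in %s", results_dir)

    table: list[tuple[str, float]] = []
    best: dict[str, DockedPose] = {}
    failures: list[tuple[str, str]] = []
    if pose_dir is not None:
        pose_dir = Path(pose_dir)
        pose_dir.mkdir(parents=True, exist_ok=True)
    for f in files:
        try:
            poses = _PARSERS[f.suffix.lower()](f)
        except (DockingParseError, OSError, ValueError) as exc:
            failures.append((f.name, str(exc)))
            continue
        if not poses:
            failures.append((f.name, "no poses in file"))
            continue
        pose = poses[0]  # rank 1 = minimum dG by parser contract
        table.append((pose.ligand_id, pose.dG))
        best[pose.ligand_id] = pose
        if pose_dir is not None:
            write_pose_pdb(pose, pose_dir / f"{pose.ligand_id}.pdb")
    return table, best, failures
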