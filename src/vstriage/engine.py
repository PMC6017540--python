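"""Adapters that drive external docking engines (AutoDock 4, Vina).

Nothing in this package re-implements docking: this module only prepares the
engine configuration files, builds per-ligand command lines, invokes the
binaries, and lays results out the way :mod:`vstriage.docking` expects (one
result file per ligand, named by ligand id).  A dry-run mode writes the full
command manifest without executing anything, so the whole screen is testable
engine-free; tests use a stub executable through ``engine_cmd``.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .geometry import Box
from .receptor import read_pdb, receptor_grid_bounds

BLIND_MARGIN = 5.0  # Å added around the receptor bounds in blind mode
DEFAULT_SPACING = 0.375  # Å, AutoDock grid spacing

ENGINE_BINARIES = {"vina": "vina", "ad4": "autodock4"}


class EngineConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ScreenConfig:
    """The persisted record of a screen's choices: engine, mode, grid geometry, inputs."""

    engine: str  # "vina" | "ad4"
    mode: str  # "blind" | "targeted"
    receptor_path: str
    library_path: str
    grid_centre: tuple[float, float, float] | None = None  # required in targeted mode
    box_edges: tuple[float, float, float] | None = None
    spacing: float = DEFAULT_SPACING
    lipinski: bool = False

    def __post_init__(self) -> None:
        if self.engine not in ("vina", "ad4"):
            raise EngineConfigError(f"engine must be 'vina' or 'ad4', got {self.engine!r}")
        if self.mode not in ("blind", "targeted"):
            raise EngineConfigError(f"mode must be 'blind' or 'targeted', got {self.mode!r}")
        if self.mode == "targeted" and (self.grid_centre is None or self.box_edges is None):
            raise EngineConfigError("targeted mode requires explicit grid_centre and box_edges")
        if self.spacing <= 0:
            raise EngineConfigError(f"spacing must be > 0, got {self.spacing}")
        if self.box_edges is not None and any(e <= 0 for e in self.box_edges):
            raise EngineConfigError(f"box edges must be > 0, got {self.box_edges}")

    def resolve_box(self) -> Box:
        """The docking box: explicit in targeted mode; receptor bounds + margin in blind mode."""
        if self.mode == "targeted":
            return Box(centre=self.grid_centre, edges=self.box_edges, spacing=self.spacing)
        receptor = read_pdb(self.receptor_path)
        box = receptor_grid_bounds(receptor, margin=BLIND_MARGIN)
        return Box(centre=box.centre, edges=box.edges, spacing=self.spacing)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "engine": self.engine,
            "mode": self.mode,
            "receptor_path": self.receptor_path,
            "library_path": self.library_path,
            "grid_centre": list(self.grid_centre) if self.grid_centre else None,
            "box_edges": list(self.box_edges) if self.box_edges else None,
            "spacing": self.spacing,
            "lipinski": self.lipinski,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("grid_centre", "box_edges"):
            if data.get(key) is not None:
                data[key] = tuple(float(v) for v in data[key])
        return cls(**data)


CONFIG_TEMPLATE = """\
# Screen configuration
engine: vina          # vina | ad4
mode: targeted        # blind (whole surface) | targeted (one site)
receptor_path: receptor.pdb
library_path: ligands.sdf
grid_centre: [56.5, 31.333, 22.113]   # ignored in blind mode
box_edges: [15.0, 15.0, 15.0]
spacing: 0.375
lipinski: false       # apply the rule-of-five filter during ligand prep
"""


def write_config_template(path: str | Path) -> None:
    Path(path).write_text(CONFIG_TEMPLATE)


# ---------------------------------------------------------------------------
# Engine input files
# ---------------------------------------------------------------------------

def write_vina_config(box: Box, path: str | Path, receptor: str = "", ligand: str = "") -> None:
    """Vina config dialect: center_x/y/z + size_x/y/z key-value lines.

    Vina has no grid-spacing keyword; the spacing is recorded as a comment so
    the file round-trips the full geometry.
    """
    cx, cy, cz = box.centre
    ex, ey, ez = box.edges
    lines = []
    if receptor:
        lines.append(f"receptor = {receptor}")
    if ligand:
        lines.append(f"ligand = {ligand}")
    lines += [
        f"center_x = {cx:.3f}", f"center_y = {cy:.3f}", f"center_z = {cz:.3f}",
        f"size_x = {ex:.3f}", f"size_y = {ey:.3f}", f"size_z = {ez:.3f}",
    ]
    if box.spacing is not None:
        lines.append(f"# spacing = {box.spacing:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vina_config(path: str | Path) -> Box:
    values: dict[str, float] = {}
    spacing = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("# spacing"):
            spacing = float(line.split("=", 1)[1])
            continue
        if "=" not in line or line.startswith("#"):
            continue
        key, val = (s.strip() for s in line.split("=", 1))
        if key.startswith(("center_", "size_")):
            values[key] = float(val)
    try:
        centre = tuple(values[f"center_{a}"] for a in "xyz")
        edges = tuple(values[f"size_{a}"] for a in "xyz")
    except KeyError as exc:
        raise EngineConfigError(f"incomplete vina config {path}: missing {exc}") from exc
    return Box(centre=centre, edges=edges, spacing=spacing)


def write_ad4_gpf(box: Box, path: str | Path, receptor: str = "receptor.pdbqt") -> None:
    """Minimal AutoDock grid-parameter file: npts, spacing, gridcenter."""
    spacing = box.spacing if box.spacing is not None else DEFAULT_SPACING
    npts = tuple(max(2, 2 * round(e / spacing / 2)) for e in box.edges)  # even point counts
    cx, cy, cz = box.centre
    Path(path).write_text(
        f"npts {npts[0]} {npts[1]} {npts[2]}\n"
        f"spacing {spacing:.3f}\n"
        f"gridcenter {cx:.3f} {cy:.3f} {cz:.3f}\n"
        f"receptor {receptor}\n"
    )


def read_ad4_gpf(path: str | Path) -> Box:
    npts = spacing = centre = None
    for line in Path(path).read_text().splitlines():
        fields = line.split()
        if not fields:
            continue
        if fields[0] == "npts":
            npts = tuple(int(v) for v in fields[1:4])
        elif fields[0] == "spacing":
            spacing = float(fields[1])
        elif fields[0] == "gridcenter":
            centre = tuple(float(v) for v in fields[1:4])
    if npts is None or spacing is None or centre is None:
        raise EngineConfigError(f"incomplete GPF {path}")
    return Box(centre=centre, edges=tuple(n * spacing for n in npts), spacing=spacing)


def write_engine_config(cfg: ScreenConfig, out_dir: str | Path, ligand: str = "") -> Path:
    """Write the engine input file(s) for a screen; returns the main config path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    box = cfg.resolve_box()
    if cfg.engine == "vina":
        path = out_dir / "vina.conf"
        write_vina_config(box, path, receptor=cfg.receptor_path, ligand=ligand)
    else:
        path = out_dir / "grid.gpf"
        write_ad4_gpf(box, path, receptor=cfg.receptor_path)
    return path


# ---------------------------------------------------------------------------
# Screen orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    results_dir: Path
    manifest: list[tuple[str, list[str]]]  # (ligand_id, argv)
    completed: list[str] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)


def run_screen(
    cfg: ScreenConfig,
    ligand_files: Sequence[tuple[str, str | Path]],
    out_dir: str | Path,
    engine_cmd: str | None = None,
    dry_run: bool = False,
) -> ScreenResult:
    """Dock every ligand, one engine invocation each.

    Parameters
    ----------
    ligand_files : ``(ligand_id, prepared ligand file)`` pairs; identities are
        never reordered and each appears in the manifest exactly once.
    engine_cmd : path to the engine executable; default looked up on PATH
        (``vina`` / ``autodock4``).  Tests pass a stub here.
    dry_run : write ``manifest.tsv`` with the exact command lines and return
        without executing; no result files are produced.

    Outside dry-run a missing binary raises :class:`FileNotFoundError` naming
    the expected executable.  Per-ligand engine failures are recorded in
    ``failures`` and the screen continues.
    """
    out_dir = Path(out_dir)
    results_dir = out_dir / "results"
    results_dir.mkdir(parents=True, exist_ok=True)
    conf_path = write_engine_config(cfg, out_dir)

    manifest: list[tuple[str, list[str]]] = []
    binary = engine_cmd or ENGINE_BINARIES[cfg.engine]
    for lid, lfile in ligand_files:
        out_file = results_dir / (f"{lid}.pdbqt" if cfg.engine == "vina" else f"{lid}.dlg")
        if cfg.engine == "vina":
            argv = [binary, "--config", str(conf_path), "--ligand", str(lfile), "--out", str(out_file)]
        else:
            argv = [binary, "-p", str(conf_path), "-l", str(lfile), "-o", str(out_file)]
        manifest.append((lid, argv))

    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write("ligand_id\tcommand\n")
        for lid, argv in manifest:
            fh.write(f"{lid}\t{' '.join(argv)}\n")

    result = ScreenResult(results_dir=results_dir, manifest=manifest)
    if dry_run:
        return result

    if shutil.which(binary) is None and not Path(binary).exists():
        raise FileNotFoundError(
            f"docking engine executable {binary!r} not found; install it, pass engine_cmd, "
            "or use dry_run=True"
        )
    for lid, argv in manifest:
        proc = subprocess.run(argv, capture_output=True, text=True)
        if proc.returncode != 0:
            result.failures.append((lid, proc.stderr.strip() or f"exit code {proc.returncode}"))
        else:
            result.completed.append(lid)
    return result
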