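"""Synthetic fixtures: toy ligand libraries, receptor structures and simulated screens.

Everything the pipeline consumes can be generated here deterministically, so
every stage is exercisable without downloads, compound libraries or docking
engines:

* :func:`make_ligand_library` writes a V2000 SDF of chemically sane drug-like
  molecules, built from a curated scaffold × substituent template grid (no
  stochastic graph generation, which risks invalid valences), spanning
  NPOL ≈ 2–8 and MW ≈ 150–550.
* :func:`make_receptor_pdb` writes a toy multi-chain receptor with waters and
  ions, for exercising receptor cleaning.
* :func:`simulate_blind_screen` emulates a blind-docking run: per-ligand
  Vina-dialect result files whose best-pose centroids scatter (Gaussian,
  ``pose_sigma``) around planted binding sites and whose energies draw from a
  per-site normal.  The ground-truth site assignment is written alongside, so
  site-clustering recovery is checkable.

The energy model is deliberately simple — per-site normal, independent of
ligand identity — which is sufficient to exercise ranking, filtering and the
ligand-efficiency plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

# Scaffold templates with one substitution slot.  All combinations are valid
# molecules by construction; the grid spans polarity (NPOL) and size (MW).
_SCAFFOLDS = (
    "c1ccc({R})cc1",                      # benzene
    "c1ccc2[nH]c({R})cc2c1",              # indole
    "c1ccc(-c2ccc({R})cc2)cc1",           # biphenyl
    "c1ccc(OCC(=O)N{R})cc1",              # phenoxyacetamide (as N-substituent slot)
    "O=C(Nc1ccc({R})cc1)c1ccccc1",        # benzanilide
    "c1ccc(CN2CCN(CC2){R})cc1",           # benzylpiperazine (N slot)
    "c1ccc(S(=O)(=O)N{R})cc1",            # benzenesulfonamide (N slot)
    "c1cnc({R})nc1",                      # pyrimidine
    "c1ccc2nc({R})sc2c1",                 # benzothiazole
    "O=C(O)c1ccc({R})cc1",                # benzoic acid
    "c1ccc(CC(=O)N2CCC(CC2){R})cc1",      # phenylacetyl piperidine (C slot)
    "c1ccc(-n2cnc({R})c2)cc1",            # phenylimidazole
)

_SUBSTITUENTS = (
    "C", "CC", "CCC", "OC", "OCC", "N", "NC", "Cl", "F", "Br",
    "C(=O)O", "C(=O)NC", "S(=O)(=O)C", "C#N", "OC(F)(F)F", "CN(C)C",
)

_MW_RANGE = (150.0, 550.0)
_NPOL_RANGE = (2, 8)


def _enumerate_templates() -> list[str]:
    """All valid scaffold×substituent SMILES within the target MW/NPOL window."""
    from rdkit.Chem import Descriptors

    out = []
    for scaffold in _SCAFFOLDS:
        for sub in _SUBSTITUENTS:
            smi = scaffold.replace("{R}", sub)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            mw = Descriptors.MolWt(mol)
            npol = sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))
            if _MW_RANGE[0] <= mw <= _MW_RANGE[1] and _NPOL_RANGE[0] <= npol <= _NPOL_RANGE[1]:
                out.append(Chem.MolToSmiles(mol))
    # unique, deterministic order
    return sorted(set(out))


def ligand_id(i: int) -> str:
    """Canonical synthetic ligand identifier, 1-based."""
    return f"lig_{i:04d}"


def make_ligand_library(n: int, seed: int, path: str | Path) -> Path:
    """Write an ``n``-record V2000 SDF of template-derived drug-like molecules.

    Records are a seeded sample (without replacement while templates last,
    then cycling) of the template grid; identical seeds give byte-identical
    files.  Record titles are ``lig_0001`` … so they join against simulated
    docking results.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    templates = _enumerate_templates()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(templates))
    chosen = [templates[order[i % len(templates)]] for i in range(n)]
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for i, smi in enumerate(chosen, start=1):
            mol = Chem.MolFromSmiles(smi)
            AllChem.Compute2DCoords(mol)
            mol.SetProp("_Name", ligand_id(i))
            writer.write(mol)
    finally:
        writer.close()
    return path


def make_receptor_pdb(
    path: str | Path,
    n_chain_a: int = 50,
    n_chain_b: int = 50,
    n_waters: int = 30,
    ions: Sequence[str] = ("NA", "CL"),
    seed: int = 0,
) -> Path:
    """Write a toy two-chain receptor PDB with waters and monoatomic ions.

    Chain atoms trace a coarse helix (so the structure has nontrivial
    extent); waters and ions scatter uniformly in the bounding region.
    """
    rng = np.random.default_rng(seed)
    lines = []
    serial = 0

    def atom_line(kind, name, res, chain, resno, x, y, z, element):
        nonlocal serial
        serial += 1
        return (
            f"{kind:<6s}{serial:>5d}  {name:<3s} {res:>3s} {chain}{resno:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n"
        )

    for chain, n_atoms, x0 in (("A", n_chain_a, 0.0), ("B", n_chain_b, 30.0)):
        for i in range(n_atoms):
            t = i * 100.0 * math.pi / 180.0
            x = x0 + 2.3 * math.cos(t)
            y = 2.3 * math.sin(t)
            z = 1.5 * i
            lines.append(atom_line("ATOM", "CA", "ALA", chain, i + 1, x, y, z, "C"))
    for i in range(n_waters):
        x, y, z = rng.uniform(-10, 40), rng.uniform(-10, 10), rng.uniform(0, 60)
        lines.append(atom_line("HETATM", "O", "HOH", "A", 500 + i, x, y, z, "O"))
    for i, ion in enumerate(ions):
        x, y, z = rng.uniform(-10, 40), rng.uniform(-10, 10), rng.uniform(0, 60)
        lines.append(atom_line("HETATM", ion[:2], ion, "A", 600 + i, x, y, z, ion[:2]))
    path = Path(path)
    path.write_text("".join(lines) + "END\n")
    return path


# ---------------------------------------------------------------------------
# Simulated blind screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimScreenSpec:
    """Conditions of a simulated blind screen.

    ``site_centres`` are the planted binding sites (Å); ``site_weights`` the
    probability a ligand binds each site; best-pose centroids scatter with
    isotropic ``pose_sigma`` around the site; energies are normal with the
    per-site mean/sd (kcal/mol).
    """

    n_ligands: int
    site_centres: tuple[tuple[float, float, float], ...]
    site_weights: tuple[float, ...]
    dG_mean: tuple[float, ...]  # per site, kcal/mol
    dG_sd: tuple[float, ...]  # per site, kcal/mol
    pose_sigma: float = 1.0  # Å
    n_poses: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.site_centres)
        if not (len(self.site_weights) == len(self.dG_mean) == len(self.dG_sd) == k):
            raise ValueError("site_centres, site_weights, dG_mean, dG_sd must have equal length")
        if any(w < 0 for w in self.site_weights) or not math.isclose(
            sum(self.site_weights), 1.0, abs_tol=1e-9
        ):
            raise ValueError("site_weights must be non-negative and sum to 1")
        if self.pose_sigma <= 0:
            raise ValueError("pose_sigma must be > 0")


# Offsets of the 8-atom rigid dummy ligand; they sum to zero so the heavy-atom
# centroid equals the sampled pose centre exactly.
_DUMMY_OFFSETS = np.array(
    [
        [1.5, 0.0, 0.0], [-1.5, 0.0, 0.0], [0.0, 1.5, 0.0], [0.0, -1.5, 0.0],
        [0.0, 0.0, 1.5], [0.0, 0.0, -1.5], [0.75, 0.75, 0.75], [-0.75, -0.75, -0.75],
    ]
)


def _write_vina_result(path: Path, poses: list[tuple[float, np.ndarray]]) -> None:
    with open(path, "w") as fh:
        for m, (dg, coords) in enumerate(poses, start=1):
            fh.write(f"MODEL {m}\n")
            fh.write(f"REMARK VINA RESULT:    {dg:8.3f}      0.000      0.000\n")
            fh.write("ROOT\n")
            for i, (x, y, z) in enumerate(coords, start=1):
                fh.write(
                    f"ATOM  {i:>5d}  C   LIG A   1    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  0.00  0.00    +0.000 C \n"
                )
            fh.write("ENDROOT\nENDMDL\n")


def simulate_blind_screen(spec: SimScreenSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write per-ligand Vina-dialect result files plus the ground truth.

    Returns ``(results_dir, truth_path)``.  ``ground_truth.tsv`` holds one row
    per ligand: id, planted site index (0-based), best dG.  Identical specs
    (including seed) produce identical directory contents.
    """
    out_dir = Path(out_dir)
    results_dir = out_dir / "results"
    results_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    centres = np.asarray(spec.site_centres, dtype=float)
    sites = rng.choice(len(centres), size=spec.n_ligands, p=np.asarray(spec.site_weights))

    truth_path = out_dir / "ground_truth.tsv"
    with open(truth_path, "w") as truth:
        truth.write("ligand_id\tsite\tdG\n")
        for i in range(spec.n_ligands):
            lid = ligand_id(i + 1)
            s = int(sites[i])
            best_centre = centres[s] + rng.normal(0.0, spec.pose_sigma, size=3)
            best_dg = rng.normal(spec.dG_mean[s], spec.dG_sd[s])
            poses = [(best_dg, best_centre + _DUMMY_OFFSETS)]
            for _ in range(spec.n_poses - 1):
                # lower-ranked poses: strictly worse energies, looser geometry
                worse_dg = poses[-1][0] + abs(rng.normal(0.4, 0.2)) + 1e-3
                worse_centre = centres[s] + rng.normal(0.0, 3 * spec.pose_sigma, size=3)
                poses.append((worse_dg, worse_centre + _DUMMY_OFFSETS))
            _write_vina_result(results_dir / f"{lid}.pdbqt", poses)
            truth.write(f"{lid}\t{s}\t{best_dg:.4f}\n")
    return results_dir, truth_path


def read_ground_truth(path: str | Path) -> dict[str, int]:
    """ligand id → planted site index from a ``ground_truth.tsv``."""
    out: dict[str, int] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            lid, site, _ = line.rstrip("\n").split("\t")
            out[lid] = int(site)
    return out
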