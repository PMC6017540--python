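import textwrap

import numpy as np
import pytest

from vstriage import SimScreenSpec, simulate_blind_screen
from vstriage.descriptors import DescriptorSet
from vstriage.simulate import make_receptor_pdb


@pytest.fixture()
def two_chain_pdb(tmp_path):
    """Toy receptor: 50 ATOM chain A, 50 ATOM chain B, 30 HOH, 2 ions (NA, CL)."""
    return make_receptor_pdb(tmp_path / "receptor.pdb", seed=11)


@pytest.fixture()
def three_model_vina(tmp_path):
    """Vina result with three in-order poses: -7.1, -6.8, -6.5 kcal/mol."""
    return _write_vina(tmp_path / "ligA.pdbqt", [-7.1, -6.8, -6.5])


def _write_vina(path, energies, centres=None):
    lines = []
    for m, dg in enumerate(energies, start=1):
        cx, cy, cz = centres[m - 1] if centres else (m * 1.0, 0.0, 0.0)
        lines.append(f"MODEL {m}")
        lines.append(f"REMARK VINA RESULT:    {dg:8.3f}      0.000      0.000")
        lines.append("ROOT")
        for i, dx in enumerate((-1.0, 0.0, 1.0), start=1):
            lines.append(
                f"ATOM  {i:>5d}  C   LIG A   1    "
                f"{cx + dx:8.3f}{cy:8.3f}{cz:8.3f}  0.00  0.00    +0.000 C "
            )
        lines.append("ENDROOT")
        lines.append("ENDMDL")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def write_vina_file():
    return _write_vina


def _write_dlg(path, energies):
    chunks = []
    for m, dg in enumerate(energies, start=1):
        chunks.append(
            textwrap.dedent(
                f"""\
                DOCKED: MODEL        {m}
                DOCKED: USER    Estimated Free Energy of Binding    =  {dg:+.2f} kcal/mol
                DOCKED: ATOM      1  C   LIG A   1      {m:6.3f}   0.000   0.000  0.00  0.00    +0.000 C
                DOCKED: ATOM      2  C   LIG A   1      {m + 1:6.3f}   0.000   0.000  0.00  0.00    +0.000 C
                DOCKED: ENDMDL
                """
            )
        )
    path.write_text("".join(chunks))
    return path


@pytest.fixture()
def write_dlg_file():
    return _write_dlg


@pytest.fixture()
def descriptor_set():
    """Hand-buildable descriptor rows for index algebra tests."""

    def make(MW=350.0, PSA=80.0, NHEA=25, NPOL=4, cLogP=2.5, cLogS=-3.0, HBD=1, HBA=None, rot=4):
        return DescriptorSet(
            MW=MW, cLogS=cLogS, cLogP=cLogP, HBD=min(HBD, NPOL),
            HBA=NPOL if HBA is None else HBA, PSA=PSA,
            rotatable_bonds=rot, NHEA=NHEA, NPOL=NPOL,
        )

    return make


@pytest.fixture()
def simulated_screen(tmp_path):
    """A seeded 60-ligand, 3-site blind screen with ground truth."""
    spec = SimScreenSpec(
        n_ligands=60,
        site_centres=((0.0, 0.0, 0.0), (30.0, 0.0, 0.0), (0.0, 30.0, 0.0)),
        site_weights=(0.5, 0.3, 0.2),
        dG_mean=(-8.3, -10.5, -6.5),
        dG_sd=(0.4, 0.7, 0.5),
        pose_sigma=1.0,
        seed=7,
    )
    results_dir, truth = simulate_blind_screen(spec, tmp_path / "screen")
    return spec, results_dir, truth


def brute_force_single_linkage(points: np.ndarray, cutoff: float) -> list[set[int]]:
    """Independent union-find oracle over the pairwise-distance graph."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= cutoff:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())
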