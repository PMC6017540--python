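import stat
import textwrap

import pytest

from vstriage.docking import parse_vina_result
from vstriage.engine import (
    EngineConfigError,
    ScreenConfig,
    read_ad4_gpf,
    read_vina_config,
    run_screen,
    write_ad4_gpf,
    write_config_template,
    write_engine_config,
)
from vstriage.geometry import Box
from vstriage.receptor import read_pdb, receptor_grid_bounds

ACTIVE_SITE_CENTRE = (56.500, 31.333, 22.113)


def _targeted_cfg(receptor, library, engine="vina"):
    return ScreenConfig(
        engine=engine,
        mode="targeted",
        receptor_path=str(receptor),
        library_path=str(library),
        grid_centre=ACTIVE_SITE_CENTRE,
        box_edges=(15.0, 15.0, 15.0),
        spacing=0.375,
    )


class TestScreenConfig:
    def test_targeted_requires_centre(self, tmp_path):
        with pytest.raises(EngineConfigError, match="targeted"):
            ScreenConfig(engine="vina", mode="targeted", receptor_path="r.pdb",
                         library_path="l.sdf")

    def test_invalid_geometry_rejected_before_any_engine_call(self, tmp_path):
        with pytest.raises(EngineConfigError, match="spacing"):
            ScreenConfig(engine="vina", mode="targeted", receptor_path="r.pdb",
                         library_path="l.sdf", grid_centre=(0, 0, 0),
                         box_edges=(15, 15, 15), spacing=0.0)
        with pytest.raises(EngineConfigError, match="edges"):
            ScreenConfig(engine="vina", mode="targeted", receptor_path="r.pdb",
                         library_path="l.sdf", grid_centre=(0, 0, 0),
                         box_edges=(15, -1, 15))

    def test_yaml_round_trip(self, tmp_path, two_chain_pdb):
        cfg = _targeted_cfg(two_chain_pdb, "lib.sdf")
        path = tmp_path / "screen.yaml"
        cfg.to_yaml(path)
        assert ScreenConfig.from_yaml(path) == cfg

    def test_template_parses_as_a_valid_config(self, tmp_path):
        path = tmp_path / "template.yaml"
        write_config_template(path)
        cfg = ScreenConfig.from_yaml(path)
        assert cfg.grid_centre == pytest.approx(ACTIVE_SITE_CENTRE)
        assert cfg.spacing == 0.375


class TestEngineConfigFiles:
    def test_vina_config_echoes_grid_numbers(self, tmp_path, two_chain_pdb):
        cfg = _targeted_cfg(two_chain_pdb, "lib.sdf")
        path = write_engine_config(cfg, tmp_path)
        text = path.read_text()
        for number in ("56.500", "31.333", "22.113", "15.000"):
            assert number in text
        box = read_vina_config(path)
        assert box.centre == pytest.approx(ACTIVE_SITE_CENTRE)
        assert box.edges == pytest.approx((15.0, 15.0, 15.0))
        assert box.spacing == pytest.approx(0.375)

    def test_gpf_round_trip(self, tmp_path):
        box = Box(centre=(45.361, 16.583, 2.583), edges=(15.0, 15.0, 15.0), spacing=0.375)
        path = tmp_path / "grid.gpf"
        write_ad4_gpf(box, path)
        reread = read_ad4_gpf(path)
        assert reread.centre == pytest.approx(box.centre)
        assert reread.spacing == pytest.approx(0.375)
        # npts quantises edges to whole grid points; within one spacing step
        assert reread.edges == pytest.approx(box.edges, abs=2 * 0.375)

    def test_blind_box_contains_whole_receptor(self, tmp_path, two_chain_pdb):
        cfg = ScreenConfig(engine="vina", mode="blind", receptor_path=str(two_chain_pdb),
                           library_path="lib.sdf")
        box = cfg.resolve_box()
        receptor = read_pdb(two_chain_pdb)
        tight = receptor_grid_bounds(receptor, margin=0.0)
        assert all(b <= t for b, t in zip(box.lo, tight.lo))
        assert all(b >= t for b, t in zip(box.hi, tight.hi))
        for atom in receptor.atoms:
            assert box.contains((atom.x, atom.y, atom.z))


def _stub_engine(tmp_path, crash_for=()):
    """A stand-in engine executable writing a fixed single-pose Vina result."""
    script = tmp_path / "stub_vina.py"
    crash_list = ",".join(crash_for)
    script.write_text(
        textwrap.dedent(
            f"""\
            #!/usr/bin/env python
            import sys
            args = dict(zip(sys.argv[1::2], sys.argv[2::2]))
            out, ligand = args["--out"], args["--ligand"]
            crash = "{crash_list}".split(",") if "{crash_list}" else []
            if any(c and c in ligand for c in crash):
                sys.exit(1)
            with open(out, "w") as fh:
                fh.write("MODEL 1\\n")
                fh.write("REMARK VINA RESULT:      -6.100      0.000      0.000\\n")
                fh.write("ATOM      1  C   LIG A   1       1.000   2.000   3.000  0.00  0.00    +0.000 C \\n")
                fh.write("ENDMDL\\n")
            """
        )
    )
    script.chmod(script.stat().st_mode | stat.S_IXUSR)
    return str(script)


class TestRunScreen:
    def _ligands(self, tmp_path, n):
        ligand_dir = tmp_path / "ligands"
        ligand_dir.mkdir()
        out = []
        for i in range(n):
            p = ligand_dir / f"lig{i}.pdbqt"
            p.write_text("ATOM      1  C   LIG A   1       0.000   0.000   0.000\n")
            out.append((f"lig{i}", p))
        return out

    def test_dry_run_writes_manifest_and_no_results(self, tmp_path, two_chain_pdb):
        cfg = _targeted_cfg(two_chain_pdb, "lib.sdf")
        ligands = self._ligands(tmp_path, 3)
        result = run_screen(cfg, ligands, tmp_path / "run", dry_run=True)
        manifest = (tmp_path / "run" / "manifest.tsv").read_text().splitlines()
        assert len(manifest) == 4  # header + one command per ligand
        assert [m.split("\t")[0] for m in manifest[1:]] == ["lig0", "lig1", "lig2"]
        assert list(result.results_dir.iterdir()) == []

    def test_manifest_covers_each_ligand_exactly_once_in_order(self, tmp_path, two_chain_pdb):
        cfg = _targeted_cfg(two_chain_pdb, "lib.sdf")
        ligands = self._ligands(tmp_path, 7)
        result = run_screen(cfg, ligands, tmp_path / "run", dry_run=True)
        assert [lid for lid, _ in result.manifest] == [lid for lid, _ in ligands]

    def test_stub_engine_produces_parseable_results(self, tmp_path, two_chain_pdb):
        cfg = _targeted_cfg(two_chain_pdb, "lib.sdf")
        ligands = self._ligands(tmp_path, 5)
        result = run_screen(cfg, ligands, tmp_path / "run", engine_cmd=_stub_engine(tmp_path))
        assert len(result.completed) == 5 and result.failures == []
        for lid, _ in ligands:
            poses = parse_vina_result(result.results_dir / f"{lid}.pdbqt")
            assert poses[0].dG == -6.1

    def test_crashing_ligand_recorded_run_continues(self, tmp_path, two_chain_pdb):
        cfg = _targeted_cfg(two_chain_pdb, "lib.sdf")
        ligands = self._ligands(tmp_path, 5)
        stub = _stub_engine(tmp_path, crash_for=("lig2",))
        result = run_screen(cfg, ligands, tmp_path / "run", engine_cmd=stub)
        assert len(result.completed) == 4
        assert [lid for lid, _ in result.failures] == ["lig2"]

    def test_missing_binary_names_expected_executable(self, tmp_path, two_chain_pdb):
        cfg = _targeted_cfg(two_chain_pdb, "lib.sdf")
        ligands = self._ligands(tmp_path, 1)
        with pytest.raises(FileNotFoundError, match="no_such_engine"):
            run_screen(cfg, ligands, tmp_path / "run", engine_cmd="no_such_engine")
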