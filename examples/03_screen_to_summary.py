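"""From simulated docking results to the filtered 16-parameter summary.

Simulates a blind screen over three planted binding sites, extracts each
ligand's best pose, builds the summary table, then filters and ranks it.
"""

from pathlib import Path
from tempfile import mkdtemp

from vstriage import (
    apply_filters,
    build_summary,
    compute_descriptors,
    extract_best_poses,
    read_library,
    summarize_distribution,
    top_n_by_dG,
    validate_and_dedupe,
    write_summary,
)
from vstriage.simulate import SimScreenSpec, make_ligand_library, simulate_blind_screen

workdir = Path(mkdtemp())
n = 120
make_ligand_library(n, seed=1, path=workdir / "library.sdf")
spec = SimScreenSpec(
    n_ligands=n,
    site_centres=((0.0, 0.0, 0.0), (30.0, 0.0, 0.0), (0.0, 30.0, 0.0)),
    site_weights=(0.5, 0.3, 0.2),
    dG_mean=(-8.3, -10.5, -6.5),  # kcal/mol: site 2 is the high-affinity pocket
    dG_sd=(0.4, 0.7, 0.5),
    seed=1,
)
results_dir, _ = simulate_blind_screen(spec, workdir / "screen")

table, best, failures = extract_best_poses(results_dir, pose_dir=workdir / "poses")
print(f"extracted best poses for {len(table)} ligands ({len(failures)} failures)")

kept, _ = validate_and_dedupe(read_library(workdir / "library.sdf"))
descriptors = {r.ligand_id: compute_descriptors(r) for r in kept}
rows, _ = build_summary(descriptors, table)
write_summary(rows, workdir / "summary")
print(f"summary: {len(rows)} compounds x {len(rows.columns)} parameters")
print(rows.iloc[:3, [0, 2, 5, 7, 9, 10, 11]].round(3))

filtered = apply_filters(rows, ["PSA<120", "cLogP<5"])
print(f"\nafter PSA<120 and cLogP<5: {len(filtered)} compounds remain")
print(f"share with PSA < 50 Å²: {summarize_distribution(rows, 'PSA', 50):.0f}%")

top = top_n_by_dG(filtered, 10)
print("\ntop 10 by ΔG (kcal/mol):")
print(top[["dG", "LE", "BEI", "SEI"]].round(3))
# More negative ΔG = stronger predicted binding; LE normalises it per heavy
# atom, BEI/SEI normalise potency by size and polar surface.
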