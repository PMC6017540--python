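"""Clean a raw receptor PDB down to a single docking-ready chain.

Builds a toy two-chain receptor (with waters and ions), strips everything
but chain A, and derives the blind-docking grid box.
"""

from pathlib import Path
from tempfile import mkdtemp

from vstriage import clean_receptor, read_pdb, receptor_grid_bounds, write_pdb
from vstriage.receptor import CleaningReport
from vstriage.simulate import make_receptor_pdb

workdir = Path(mkdtemp())
raw_path = make_receptor_pdb(workdir / "receptor.pdb", seed=11)

raw = read_pdb(raw_path)
report = CleaningReport()
clean = clean_receptor(raw, keep_chain="A", report=report)
write_pdb(clean, workdir / "receptor_clean.pdb")

print(f"raw atoms: {len(raw)}  (chains {sorted(raw.chains)})")
print(
    f"removed: {report.other_chains} other-chain, {report.waters} water, "
    f"{report.ions} ion atoms"
)
print(f"clean atoms: {len(clean)}  (chain A only, serials renumbered 1..{len(clean)})")

box = receptor_grid_bounds(clean, margin=5.0)
print(f"blind-docking box centre {tuple(round(c, 2) for c in box.centre)} Å, "
      f"edges {tuple(round(e, 2) for e in box.edges)} Å")
# The box encloses the whole chain plus a 5 Å margin — the search space a
# blind docking run must cover.
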