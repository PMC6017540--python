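"""Read a ligand library, validate/deduplicate it, and compute descriptors.

Shows the rule-of-five filter and the HBA = N+O count convention used
throughout the summary.
"""

from pathlib import Path
from tempfile import mkdtemp

from vstriage import compute_descriptors, lipinski_pass, read_library, validate_and_dedupe
from vstriage.simulate import make_ligand_library

workdir = Path(mkdtemp())
lib = make_ligand_library(30, seed=1, path=workdir / "library.sdf")

kept, rejected = validate_and_dedupe(read_library(lib))
print(f"{len(kept)} kept, {len(rejected)} rejected (incomplete or repetitive records)")

n_pass = 0
for rec in kept[:5]:
    d = compute_descriptors(rec)
    ok, violations = lipinski_pass(d)
    n_pass += ok
    print(
        f"{rec.ligand_id}: MW {d.MW:6.1f}  cLogP {d.cLogP:5.2f}  PSA {d.PSA:6.1f}  "
        f"HBD {d.HBD}  HBA(N+O) {d.HBA}  rule-of-five: {'pass' if ok else violations}"
    )
# MW in Da, PSA in Å²; HBA here is the Lipinski nitrogen+oxygen count, so it
# doubles as NPOL in the efficiency indices downstream.
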