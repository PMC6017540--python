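# vstriage

Post-processing and hit triage for structure-based virtual screening.

Large-scale docking campaigns produce thousands of per-ligand result files
and a single question: *which compounds are worth buying?* Raw binding free
energies (ΔG) alone are a poor guide — potency gains often come from simply
adding bulk or polarity. `vstriage` implements the bespoke stages around the
docking engines (AutoDock 4 and AutoDock Vina, which it drives but never
re-implements): receptor and ligand preparation, result parsing and best-pose
extraction, a 16-parameter physicochemical + ligand-efficiency summary per
compound, automated binding-site detection from blind-docking poses,
iterative property filtering, and the ligand-efficiency-index (LEI) plots
used to pick hits in drug-like chemical space. It is aimed at
structure-based drug-discovery practitioners who run AutoDock-family screens
and want the triage step scripted, reproducible and testable.

## The quantities at the core

A docking score ΔG (kcal/mol) is converted to a predicted inhibition
constant at a 1 M reference state,

```
Ki = exp(ΔG / RT),   pKi = −log10 Ki,      (R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K)
```

and pKi is normalised by molecular size and polarity into the LEI family:

| index | definition | reads as |
|-------|-----------|----------|
| LE    | ΔG / NHEA | binding energy per heavy atom |
| BEI   | pKi / (MW/1000) | potency per kDa |
| SEI   | pKi / (PSA/100) | potency per 100 Å² polar surface |
| NSEI  | pKi / NPOL | potency per polar (N+O) atom |
| NBEI  | pKi / NHEA | potency per heavy atom |
| nBEI  | −log10(Ki/NHEA) = pKi + log10 NHEA | size-adjusted potency (log form) |
| mBEI  | −log10(Ki/MW) = pKi + log10 MW | mass-adjusted potency (log form) |

On the SEI–BEI plane, compounds with equal PSA/MW ratio *r* lie on the
origin line BEI = 10·r·SEI; the reference ratios
0.753, 0.320, 0.200, 0.150, 0.110, 0.090 partition the plane into poor
(≳0.32), acceptable (≈0.20) and good (0.15–0.09) drug-like space. On the
NSEI–nBEI plane compounds fall on diagonals of slope NPOL, sorting the
library by polarity class at a glance.

Blind-docking poses are grouped into binding-site clusters by single-linkage
proximity of best-pose centroids (5 Å default cutoff); a site is reported as
a cluster only when **more than 10** ligands land there, and each cluster
yields a 15 × 15 × 15 Å targeted-docking grid box (0.375 Å spacing) centred
on its centroid.

## Worked example

`examples/03_screen_to_summary.py` simulates a 120-ligand blind screen over
three planted binding sites, extracts each ligand's best pose, and builds,
filters and ranks the summary:

```
extracted best poses for 120 ligands (0 failures)
summary: 120 compounds x 16 parameters
                MW  cLogP    PSA      dG     LE     BEI     SEI
ligand_id
lig_0001   152.149  1.393  46.53 -12.226 -1.111  58.901  19.260
lig_0002   199.275  1.375  46.17  -6.588 -0.507  24.233  10.459
lig_0003   166.176  1.783  46.53  -8.391 -0.699  37.013  13.219

after PSA<120 and cLogP<5: 120 compounds remain
share with PSA < 50 Å²: 80%

top 10 by ΔG (kcal/mol):
               dG     LE     BEI      SEI
lig_0001  -12.226 -1.111  58.901   19.260
lig_0014  -11.746 -0.904  48.053   12.967
...
```

The 16 parameters per compound are, in order: MW, cLogS, cLogP, HBD, HBA,
PSA, rotatable bonds, ΔG, Ki, LE, BEI, SEI, NSEI, NBEI, nBEI, mBEI. ΔG is in
kcal/mol (more negative = stronger predicted binding), Ki in molar, LE in
kcal/mol per heavy atom; BEI/SEI are the size- and surface-normalised
potencies plotted for hit selection. The other examples cover receptor
cleaning, library validation, site clustering and the six-plot bundle.

A thin CLI mirrors the same stages for shell pipelines:

```sh
vstriage simulate -o work                           # synthetic screen (demo input)
vstriage extract --results work/results -o work/ex
vstriage summarise --library work/library.sdf --energies work/ex/energies.tsv -o work/out
vstriage filter --summary work/out/output.csv --where "PSA<50" -o work/hits
vstriage cluster-sites --poses work/results -o work/sites
```

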