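# Methods

This note records the models, conventions and numerical choices behind
`vstriage`, and what its synthetic test conditions do and do not establish
about real screening data.

## Scope and model of the pipeline

The package covers the computation *around* docking, not docking itself.
AutoDock 4 (AD4) and AutoDock Vina are external executables driven through a
narrow adapter (`vstriage.engine`); their search algorithms and scoring
functions are never re-implemented, and every test runs against either a
dry-run manifest or a stub executable. Ligand conformer generation and
energy minimisation are likewise delegated to external tools: ligand
validation enforces graph-level completeness only (an identifier, at least
one heavy atom, valid valences) and deliberately keeps records without 3-D
coordinates.

## Receptor preparation

Cleaning reduces a deposited PDB to what a docking grid should see: one
chain, no pre-existing ligands, waters or ions. The category dictionaries
are explicit because depositions vary: waters are residues named HOH/WAT/H2O
(case-insensitive); monoatomic ions are HETATM groups named NA, CL, MG, ZN,
CA, K, MN or FE. Any other HETATM group is treated as a ligand and removed
unless whitelisted — the whitelist is the mechanism for retaining essential
cofactors without the code guessing intent. Alternate locations other than
blank/'A' are dropped; only the first MODEL of multi-model files is read.
Coordinates pass through bit-identical; serials are renumbered from 1.
Cleaning is idempotent.

PDB I/O is a deliberately small fixed-column reader/writer rather than a
structure-object library: the cleaning contract operates on raw record
categories (record kind, chain, altLoc, residue name) and the tests require
exact coordinate and occupancy/B-factor pass-through, which maps one-to-one
onto fixed-column lines.

## Descriptors

All descriptors are topological (independent of 3-D coordinates and atom
order), computed with RDKit:

- **MW** — average atomic masses, Da.
- **PSA** — Ertl topological PSA (TPSA), Å²; the standard reading of "PSA"
  in library triage.
- **cLogP** — Crippen atom-contribution estimate.
- **cLogS** — ESOL (Delaney) regression,
  `0.16 − 0.63·cLogP − 0.0062·MW + 0.066·RB − 0.74·AP` (log10 mol/L), with
  AP the aromatic fraction of heavy atoms. Both cLogP and cLogS are
  model-dependent estimates; the method names are recorded in
  `DESCRIPTOR_METHODS`.
- **HBD/HBA** — Lipinski OH+NH and N+O counts. Under the N+O convention HBA
  equals NPOL on every molecule; this identity is asserted in the tests and
  keeps rule-of-five semantics canonical. A count-based convention was
  chosen over RDKit's pharmacophore-style acceptor definition precisely so
  the rule-of-five thresholds retain their original meaning.
- **Rotatable bonds** — strict definition (non-ring single bonds between
  non-terminal heavy atoms, amide C–N excluded).

Elements outside the Crippen/TPSA parameterisation (anything beyond
H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I) raise an error naming the element
rather than returning silently wrong values.

The rule-of-five filter (MW ≤ 500, cLogP ≤ 5, HBD ≤ 5, HBA ≤ 10) passes a
compound with at most `max_violations` failures (default 0) and always
reports which rules failed.

## Ligand libraries

Supported formats: SDF (V2000), SMILES (one molecule per line, optional
name), canonical-SMILES files treated as a SMILES dialect, MOL, MOL2 and
PDB. Unparseable records are reported and skipped, never fatal; a wholly
unparseable file is a format error. Missing titles are synthesised as
`<file-stem>_<index>` (1-based) so downstream joins never fail.

"Repetitive" records are detected structurally: the canonical key is the
canonical isomeric SMILES, invariant under atom reordering; first occurrence
wins. Stereochemistry is included in the key by default because two
stereoisomers can dock differently; `use_stereo=False` relaxes this for
libraries with unreliable stereo annotation.

## Docking output parsing

Vina result PDBQT files are read MODEL-by-MODEL, the affinity taken from the
first numeric field of each `REMARK VINA RESULT` line; AD4 DLG logs are read
from their `DOCKED:`-prefixed echo, the energy from the
`Estimated Free Energy of Binding` line. Within a file, rank 1 is the
minimum-ΔG pose; out-of-order models (engines occasionally emit them) are
re-ranked by energy with a warning, ties keeping file order. Hydrogens
(AutoDock types H/HD/HS) are excluded from pose coordinates, so pose
centroids are heavy-atom centroids. Ligand identity comes from the result
filename stem, matching the one-file-per-ligand layout the adapter produces.
Parse failures of individual files are collected and reported; the
extraction run always continues.

Ki is always recomputed from ΔG (never read from AD4's printout) so AD4 and
Vina rows are commensurable; the temperature is configurable and defaults to
298.15 K.

## Efficiency indices

`pKi` is computed as `−log10(exp(ΔG/RT))` so the identity
`pKi = −log10 Ki` holds to machine precision, as do the algebraic ties the
tests assert at 1e−9 relative tolerance: `BEI·MW/1000 = pKi`,
`SEI·PSA/100 = pKi`, `NSEI·NPOL = pKi`, `nBEI − pKi = log10 NHEA`,
`mBEI − pKi = log10 MW`. NBEI and mBEI follow the published LEI-framework
definitions (`NBEI = pKi/NHEA`; `mBEI = −log10(Ki/MW)` with MW in Da). LE is
stored as ΔG/NHEA, carrying the sign of ΔG (negative = favourable).
Indices with vanishing denominators (SEI at PSA = 0, NSEI at NPOL = 0) are
NaN, never 0 — a zero would masquerade as an extremely inefficient compound
in sorting and plots.

The PSA/MW drug-likeness bands are cut at the midpoints between the named
reference ratios: poor > 0.260 (midpoint of 0.320/0.200), acceptable
(0.175, 0.260], good ≤ 0.175 (midpoint of 0.200/0.150). The reference lines
themselves are always drawn at the six printed ratios; the cut points are
configurable because the band edges are a visual convention, not a measured
quantity.

## Binding-site clustering

Each ligand is represented by the heavy-atom centroid of its rank-1 pose.
Candidate sites are single-linkage components at a distance cutoff —
computed as connected components of the pairwise-distance graph with edges
at distance ≤ cutoff, which is exactly the single-linkage dendrogram cut.
The default cutoff of 5 Å is of the order of a binding-pocket radius;
both the cutoff and the membership threshold are exposed on the API and CLI.

A component is a **cluster** only when its member count is strictly greater
than the threshold (default 10); smaller components are reported as
low-density sites, not clusters. Clusters are numbered 1… by descending
member count, ties broken by centroid x, then y, then z, so output is
deterministic. Each cluster carries a targeted-docking box: a cube (default
edge 15 Å, spacing 0.375 Å) centred on the cluster centroid.

Using only the best pose per ligand keeps one vote per compound; an
all-poses mode would weight ligands by conformational promiscuity and is
intentionally not the default.

## Summary, filtering, selection

The summary is a pandas DataFrame indexed by ligand id with exactly the 16
columns, in order: MW, cLogS, cLogP, HBD, HBA, PSA, rotatable_bonds, dG, Ki,
LE, BEI, SEI, NSEI, NBEI, nBEI, mBEI. It is written as `output.csv` and
`output.tsv` (UTF-8, dot decimal, 6 significant digits — the round-trip
tolerance the tests assert). Filters are ordered chains of
`parameter <cmp> threshold` conditions; NaN never satisfies a condition, so
a filter on an undefined index drops that compound while filters on other
columns leave it alone. Filtering preserves row order, is idempotent, and
conditions on distinct parameters commute. Top-N selection sorts by ΔG
ascending with ties broken by ligand id (stable). `summarize_distribution`
reports the percentage of compounds strictly below a threshold — the
polarity read-out used when comparing sites.

## Plots

Six figures per bundle: histograms of PSA, MW, cLogP and HBA
(Freedman–Diaconis bins by default; a degenerate all-equal series collapses
to one bin), plus the SEI–BEI and NSEI–nBEI planes. Every figure is saved
with its numeric series as TSV, so checks and re-plots operate on numbers,
never pixels. Gradient lines on the SEI–BEI plane pass through the origin
with slope 10·r. NSEI–nBEI guide diagonals have slope NPOL and intercept
fitted as the group mean of `nBEI − NPOL·NSEI` (= mean log10 NHEA); the line
is exact only when NHEA is constant within the NPOL group, an approximation
the plot makes explicit by fitting rather than assuming. Two-group colouring
(e.g. two binding sites) uses red for group 1 and blue for group 2.

## Engine adapter

`ScreenConfig` persists every user choice (engine, blind/targeted mode,
geometry, library, rule-of-five flag) as YAML. Targeted mode requires an
explicit grid centre and box; blind mode derives the box from the receptor
bounds plus a 5 Å margin — large enough to cover the whole surface, and
configurable since no single margin suits all receptors. Geometry is
validated before any engine call. Vina configs carry
`center_x/y/z`/`size_x/y/z` (spacing recorded as a comment, since the Vina
dialect has no spacing keyword); AD4 grids carry `npts`/`spacing`/
`gridcenter`, with npts rounded to even grid-point counts, so GPF round-trips
recover edges only to within one spacing step. The orchestration writes a
manifest covering every ligand exactly once in input order; per-ligand
engine failures are recorded and the screen continues.

## Synthetic data: what it emulates, what it does not

The generator exists to make every stage testable end-to-end with no
external data.

- **Libraries** are drawn from a curated scaffold × substituent template
  grid (~130 valid structures spanning MW 150–550 and NPOL 2–8), sampled
  without replacement while templates last. This guarantees chemical sanity
  and determinism but under-represents real-library pathologies (charged
  species, tautomers, exotic elements, broken records), which the parsers
  handle via their rejection paths instead.
- **Screens** plant binding sites and draw best-pose centroids from an
  isotropic Gaussian (default σ = 1 Å) around them, with per-site normal
  energies. The default test screen uses 60–120 ligands over three sites
  with weights (0.5, 0.3, 0.2) and energies of −8.3 ± 0.4, −10.5 ± 0.7 and
  −6.5 ± 0.5 kcal/mol — separations and spreads typical of distinct pockets
  on one receptor. Energies are independent of ligand identity, so the
  simulation exercises ranking, clustering, filtering and plotting, but says
  nothing about scoring-function accuracy.

Consequently, passing tests establish that the bookkeeping, algebra,
clustering and geometry are correct under realistic data shapes — not that
any particular receptor's sites would be recovered, which depends on the
engine, the structure and the library used.

## Problem sizes and tolerances

The test suite and the acceptance script run at desk scale: summaries of
30–120 compounds (5,000 rows for the selection check), screens of 60–120
ligands, 50 randomized clustering instances of up to 200 poses each against
a brute-force union-find oracle. Index algebra is checked at 1e−9 relative
tolerance; CSV/TSV round-trips at 6 significant digits; pose PDB round-trips
at the format's 3-decimal coordinate precision. All randomness is seeded;
the acceptance script derives every stream from its `--seed` argument.

## Known limitations

- Descriptor values are convention-dependent: a pipeline using
  pharmacophore-based HBA counts or a different logP model will disagree
  numerically while agreeing in rank ordering for most libraries.
- Single-linkage clustering chains through bridging poses: two nearby
  pockets connected by a trickle of intermediate poses merge into one
  cluster. Lowering the cutoff splits them at the cost of fragmenting
  diffuse sites.
- The ΔG → Ki conversion assumes the engine's score is a free energy at
  standard state; it inherits all scoring-function error.
- MOL2 reading depends on RDKit's Tripos atom-type interpretation and may
  reject files with non-standard types; such records land in the rejection
  report.
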