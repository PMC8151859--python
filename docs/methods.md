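# Methods

## Scope and data model

`lipidfc` implements the quantitative analysis of an untargeted lipidomics
cell-culture experiment: feature annotation, per-cell normalization,
lipid-family aggregation, left-censored imputation, bootstrap fold-change
estimation, and cell count/size summaries. It does not do spectral peak
picking (it starts from a feature table of m/z, retention time and
per-sample peak areas), retention-time modeling, batch or injection-order
correction, isotopologue handling, or any hypothesis testing — effects are
reported as interval estimates only, never as p-values.

The in-memory containers are pandas DataFrames: a feature table (feature ×
sample areas, `NaN` = below detection), sample metadata (cell line,
treatment, replicate, injection order, extracted cell count), a theoretical
library (one row per species × adduct), MS2 fragment lists, and long-format
fold-change results.

## Lipid library

Species are identified by family (18 families: FA, LPC, PC, etherPC, LPE,
PE, etherPE, PG, LPI, PI, LPS, PS, DG, TG, sterol, CE, Cer, SM), total
carbons, total double bonds and — where resolved — the chain combination.
Molecular formulas are assembled from building blocks (glycerol C3H8O3,
fatty acid CnH(2n−2d)O2, fatty alcohol CnH(2n+2−2d)O for plasmanyl chains,
phospho-headgroups as head alcohol + H3PO4 − H2O, cholesterol C27H46O, the
d18:1 sphingoid base C18H37NO2), removing one H2O per condensation bond.
Element monoisotopic masses are pinned in a versioned constants table so
results are bit-stable; the test suite cross-checks every generated species
against pyteomics' independent elemental summation at ≤ 1e-4 Da.

A plasmenyl (P-, vinyl ether) species is exactly 2.01565 Da lighter than its
plasmanyl (O-) counterpart and therefore isobaric with the plasmanyl species
carrying one more double bond; MS1 cannot distinguish them, so ether species
are generated as plasmanyl and the ambiguity is inherent in the name.
Default adducts per family are [M+H]+ (choline lipids, sphingolipids,
sterol), [M+NH4]+ (neutral glycerolipids, CE) and [M−H]− (acidic
phospholipids and FA), overridable per run; [M+Na]+ and [M+HCOO]− are
available in the adduct registry.

## Annotation

A feature matches a library row when |observed − theoretical|/theoretical ×
1e6 ≤ 10 ppm (sign convention: observed − theoretical). All in-tolerance
candidates are kept with ranks by |ppm|; rank 1 feeds downstream stages.
Within-family isobars (different chain combinations with the same total
composition) collapse onto one rank-1 name and their features are summed —
a faithful property of MS1-only identification. MS2 refinement predicts the
two [FA−H]⁻ carboxylate anions for every chain pair consistent with the sum
composition (chain lengths 10–26, up to 6 double bonds per chain) at a 15
ppm fragment tolerance (MS2 is less mass-accurate than MS1); the pair with
both fragments present and the highest summed intensity wins and is
reported unordered — no sn-position claim. Free-FA isomer labels come from
a fixed abundance-prior table (18:1→n-9, 18:2→n-6, 20:3→n-6, 20:4→n-6,
20:5→n-3, 22:6→n-3) applied to the most abundant peak of each composition;
retention time is carried but not used as a filter.

## Normalization and family aggregation

Normalized signal = peak area / extracted cell count, so results are
invariant to any global rescaling of the counts and unaffected by
treatment-induced differences in recovered cell number. Family signal is
the sum of normalized member species. When `family_sum` is called
standalone (before any imputation) censored members contribute 0 with a
recorded count; inside a fold-change comparison the default is
impute-then-sum (below), because zero-filling a censored member of a small
family (etherPE has 6 species) visibly biases the family estimate downward.
Unannotated features are excluded from family sums. QC-pool dispersion
(CV across ≥3 QC injections, threshold 0.30) produces advisory flags only.

## Censoring, imputation and the discard rule

Per lipid and per comparison (treated + matched vehicle of one cell line),
the detection limit is the minimum detected signal; the detected values'
sample mean and SD define a normal distribution, and each censored value is
drawn once from that normal truncated to (0, LOD) via the inverse-CDF
(scipy `truncnorm`). The normal is fitted on raw (not log) areas — the
positive truncation absorbs the mass below zero; a degenerate SD = 0 fit
collapses to the mean. Comparisons with more than one censored value in
either group are discarded (exactly one per group is tolerated and
imputed). Imputation happens once per comparison before bootstrapping; a
config switch (`impute_per_draw`) instead re-draws imputed values inside
every bootstrap iteration, which propagates imputation uncertainty into the
interval at extra cost.

## Bootstrap fold changes

Each of B = 10,000 draws resamples both groups with replacement at their own
sizes and computes ln(mean treated / mean control); the central value is the
mean of the draws, the interval the 2.5/97.5 percentiles (plain percentile
method, not BCa). Properties verified by the suite: antisymmetry under
group swap, exact invariance to common rescaling, agreement of the sampled
mean with exhaustive enumeration of all 3³ × 3³ = 729 resample pairs at
n = 3, and interval coverage of 88–98% at n = 10, σ_log = 0.2. All
randomness flows through one `numpy` Generator seeded per run, so identical
seeds give identical intervals to full precision.

## Cell metrics

Weighted mean diameter = Σ(bin center × bin count)/Σ(count), the bin center
being the arithmetic midpoint of its edges (a 4–9 µm bin contributes
6.5 µm); open-ended top bins are rejected. Replicate variability is the
standard error of the mean (sample SD/√n, n ≥ 2). Mortality is reported as
100 × (1 − mean treated count / mean vehicle count).

## The synthetic-study generator

The generator emulates the study design, not the instrument: 3 cell lines
(HepG2, Huh7, SNU449) × {DOX, IDA, vehicle-DOX, vehicle-IDA, untreated} × 3
replicates, a QC pool injected every fifth position, and 451 species split
across the 18 families. The etherPC (1 species, PC(O-16:0/18:1)), etherPE
(6 species, all PUFA-containing) and free-sterol (1) counts are pinned to
the detected lipidome of these cells; the remaining per-family counts are a
plausible hepatocyte split, enumerated deterministically from
abundance-ordered chain pools.

The measurement model: raw area of species *s* in sample *j* is
`baseline_per_cell[s] × cell_count[j] × exp(effect) × exp(N(0, σ_log))`,
with σ_log = 0.2 (typical peak-area CV for this kind of assay; the
replicate-level variance of the real experiment is not published, so this
default is plausible rather than fitted), per-cell baselines log-normal
across species (10^N(0, 0.4)), and m/z errors Gaussian with SD 3 ppm so
essentially every feature falls inside the 10 ppm gate (Q-ToF-class
accuracy). Raw areas scale with the extracted cell count — treated flasks
carry on average (1 − mortality) = 40% of the vehicle cells — so per-cell
normalization is exercised, not decorative. Default true effects inject
ln(1.5) on PUFA-containing etherPE and free-FA species in every condition
and zero elsewhere; vehicle-vs-untreated effects are zero by construction.

Censoring: each species' LOD is the `lod_quantile` (default 0.05) of its
own **per-cell** signal, and raw areas whose per-cell value falls below it
are emitted as missing. Taking the quantile on the per-cell scale (rather
than on raw areas) makes missingness a function of measurement noise; a
raw-area quantile would instead censor almost exclusively treated samples
(they carry 40% of the cells), i.e. missingness driven by mortality, which
the below-minimum imputation model cannot represent and which biases every
fold change. Real data sit between these idealizations; passing recovery
tests here show the inference chain is unbiased under the censoring
mechanism it models, not that it is robust to arbitrary
missing-not-at-random patterns.

Cell sizes are normal per line (means 11/12/13 µm, SD 2.5 µm) binned at
1 µm over 4–25 µm as one multinomial draw of 10⁶ cells per flask; both
drugs shift the last cell line (SNU449) by +2 µm, the others are unshifted.
QC-pool areas are the mean per-cell lipidome at a reference cell count with
σ = 0.05 noise. One master seed feeds fixed-label substreams per stage
(counts, baselines, areas, m/z, MS2, QC, injection order, sizes), so any
stage reruns identically in isolation.

What the generator does **not** emulate: retention-time drift, batch and
injection-order effects, in-source fragmentation, isotopologue overlap,
adduct correlation, and heteroscedastic noise floors. Conclusions from
passing tests are therefore about the correctness of the statistical chain
under the stated model, not about robustness to those artifacts.

## Numerical and design choices

- Imputation draws and bootstrap indices come from a single seeded
  Generator consumed in deterministic order; results are reproducible to
  the last bit for a given seed.
- Family rows whose sum is non-positive in any sample of a comparison
  (every member censored with no fit available) are reported as
  `discarded` — the log is undefined; species-level discards follow the
  more-than-one-censored rule.
- Ties in MS2 pair scoring resolve to the first candidate in deterministic
  enumeration order; ties in annotation ranking resolve by first
  occurrence at equal |ppm| (exact isobars).
- Problem sizes in the test suite (B = 200–1,000 for pipeline-level checks,
  500 Monte-Carlo datasets for coverage, the full 451-species design for
  recovery) were chosen so each property is measured well inside its
  tolerance; B = 10,000 remains the analysis default.

## Known limitations

- Species-level names are only as resolved as MS1 + the available MS2
  allow; isobaric chain combinations are reported under one name.
- The imputation model assumes detected areas are approximately normal per
  lipid within a comparison (n ≤ 6 values); with heavy right skew the
  truncated fit can under-disperse imputed values.
- The percentile bootstrap at n = 3 per group is discrete (729 support
  points); intervals at that size are coarse, which mirrors the underlying
  design rather than a software choice.
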