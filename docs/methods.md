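# Methods

`phosdia` implements the post-acquisition statistical analysis of a
two-condition, replicate-based DIA/SWATH phosphoproteomics experiment. The
input is a phosphopeptide-precursor quantification matrix (rows x samples,
with explicit missing values) together with a phosphopeptide catalog, an
optional protein-group-level total-proteome matrix, and GMT pathway
annotations. Everything upstream of the quantification matrix — acquisition,
spectral-library search, XIC extraction, decoy scoring — is out of scope.

## Preprocessing

**Normalization rows.** Rows eligible for normalization are those passing
an upstream identification q-value threshold in at least one sample. When
no eligibility flags are available (or the eligible set is empty) all rows
are used, with a warning in the empty-set case, so small inputs never
dead-end.

**Local-regression normalization.** Operates on the log2 scale. The
reference profile is the row-wise median across samples over the selected
rows; for each sample, the deviation (sample − reference) is smoothed
against the reference with LOWESS (statsmodels; default span 0.4,
configurable), and the fitted bias curve — interpolated at every row's
reference value — is subtracted from all observed cells of that sample.
The model assumes the bulk of precursors form an unregulated stable
background with no net up/down preference. A constant offset is reproduced
exactly by the smoother, so a flat shift is removed completely; the
observed/missing pattern is never changed. At least 8 usable rows per
sample are required.

**log2 transform.** Raw intensities must be positive; zeros or negatives
(which should not survive ingestion) are set missing with a logged warning.
A scale tag prevents accidental double transformation.

**Valid-value filter.** A row is kept iff it is observed in at least 70%
(configurable) of all samples jointly — with 10 samples, at least 7 — not
per condition. The filter is idempotent and order-preserving; a per-group
mode exists but is off by default.

**Downshifted-normal imputation.** Per sample with observed mean μ and
standard deviation σ, each missing cell is drawn independently from
Normal(μ − 1.8·σ, (0.3·σ)²). The downshift mimics signals near the
detection limit, the premise being that missingness is intensity-dependent
(MNAR). The phrase "shrinks the distribution to a width of 0.3 and
down-shifts by 1.8" is implemented as a shift of the *mean* by 1.8·σ and a
standard deviation of 0.3·σ, the documented behaviour of the software this
stage emulates. Imputation feeds PCA and hierarchical clustering only; the
differential test uses observed values (see below). Observed cells are
never altered.

## Differential testing

The per-row statistic is the moderated two-sample t

    d = (mean_A − mean_B) / (s + s0),    s0 = 0.1 by default,

with s the pooled equal-variance standard error of the mean difference
(Welch form available by flag). s0 adds an "artificial within-group
variance" so that rows with vanishing variance cannot become significant on
a trivial mean difference; at s0 = 0, d is exactly the classical Student t.
Conditions are taken in lexicographic order, so exchanging the two labels
flips every sign without changing the analysis. Rows with fewer than two
observed values in a group are reported as untestable with a reason code,
never silently dropped.

**Permutation FDR.** Sample labels are randomly relabelled (unrestricted —
no grouping preservation) `n_permutations` times (default 250), and d is
recomputed per row under each relabeling. For a symmetric cutoff c,

    FDR(c) = mean over permutations of #{|d*| ≥ c} / #{|d_obs| ≥ c},

and the significance cutoff c* is the smallest observed |d| with
FDR(c*) ≤ the target (default 0.01). p-values come from the pooled
permutation distribution of |d*| with a +1 continuity correction, so they
lie in (0, 1]. With 5 vs 5 samples only C(10,5) = 252 distinct relabelings
exist; sampling is with replacement and duplicates are allowed. Two
numerical choices matter:

- *Identity exclusion.* A sampled relabeling equal to the observed labeling
  (or its complement) reproduces the alternative, not the null: every true
  effect re-enters the "null" pool at full strength, which puts a floor of
  about 2/252 ≈ 0.008 on the estimated FDR and, at a 0.01 target, randomly
  blocks all discoveries in a substantial fraction of runs. Such draws are
  therefore rejected and redrawn. Explicit permutation lists supplied
  through the testing hook bypass this rule.
- *Untestable permuted rows.* A row can drop below two observations per
  group under a particular relabeling; its d* is undefined for that
  permutation and is excluded from the pooled counts.

The test runs on observed values, not imputed ones: measured on the
synthetic benchmark, testing the imputed matrix lowers sensitivity, because
downshifted draws inflate within-group variance. A switch restores the
impute-then-test behaviour for users who want it.

**Ordination and clustering.** PCA (scikit-learn, full SVD) treats samples
as observations with rows centred; explained-variance fractions are
non-increasing. Hierarchical clustering uses 1 − Pearson correlation
between sample profiles with average linkage (SciPy); a constant sample
profile is an error naming the sample, since its correlation is undefined.
Both require a complete (imputed) matrix.

## Proteome normalization and regulation calls

A differential phosphopeptide may reflect site-level phosphorylation change
or a change in the carrier protein's amount. Each phosphopeptide row is
matched to its protein group's proteome row and adjusted per sample as
log2(phospho) − log2(protein); the adjustment is exact arithmetic, so a
common offset cancels, and cells missing in either input stay missing.
Whether the original normalization was a per-sample ratio or a
difference-of-differences is not documented anywhere authoritative; the
per-sample log-difference implemented here is the natural choice and is
stated as such. The rule table for calls, given the phospho-level and
adjusted-level tests plus the protein-level mean difference:

| phospho test | adjusted test | |protein diff| | call |
|---|---|---|---|
| significant | significant | — | phospho_driven |
| significant | not | > 0.3 log2 | abundance_driven |
| significant | not | ≤ 0.3 log2 | mixed |
| not significant | — | — | not_significant |
| (no proteome match) | | | unmatched |

The 0.3-log2 protein-change threshold is this package's own default (no
numeric criterion exists upstream); with five replicates and noise ~0.5 the
protein-difference estimate has a standard error near 0.32, so
phospho-driven rows that fail the adjusted test can be miscalled
abundance-driven by protein-level noise — calls on rows near the threshold
should be read with that in mind. Normalization is applied to all matched
rows, not only enriched ones (strictly more information, same semantics).

## Enrichment

Significant phosphopeptides are collapsed to unique protein groups before
testing, so a protein with many significant sites counts once. Each term is
tested with a **two-sided** Fisher's exact test (SciPy) on the 2×2 table
(in-term/out-of-term × hit/non-hit); two-sided because under-represented
terms (enrichment factor < 1) are of interest and a one-sided enrichment
test cannot flag them. The enrichment factor is (k/n)/(K/N) — hit fraction
inside the term over the background fraction — and is undefined when the
term has no background members or there are no hits. The background
universe defaults to all protein groups quantified after quality filtering
(configurable). Raw p < 0.05 defines significance by default; a
Benjamini–Hochberg option exists but is off, matching the common practice
of reporting raw Fisher p in this setting. Term members absent from the
background are clipped with a warning; hits outside the background are an
error.

## Synthetic data generator

The generator emulates the statistical structure of the emulated study —
it is the package's verification harness, not a spectra simulator.

- **Catalog**: ~1,200 protein groups with 1 + Poisson(1.6) peptides each
  (~3,100 rows at defaults; benchmarks use 200 groups / ~500 rows), random
  sequences over the 20-letter alphabet, phosphosite residues drawn at
  S/T/Y = 0.857/0.135/0.008, and localization probabilities from a
  two-component uniform mixture placing 60% of sites above 0.75.
- **Intensities**: latent log2 abundance per row ~ Normal(20, 2), per-cell
  noise ~ Normal(0, 0.5), matrices emitted on the raw scale as 2^x. The
  log-normal choice is the generator's own; the emulated study does not
  describe its intensity distribution.
- **Effects**: a fraction (default 0.1) of rows is differential, with fixed
  magnitude |Δlog2| = 2 and random sign (signs balanced, matching the
  stable-background normalization assumption). Phospho-driven rows shift
  only in the phospho matrix; abundance-driven rows (default 0.3 of
  differential rows) shift in both their phospho row and their group's
  proteome row. Abundance-driven rows are drawn from distinct protein
  groups so each proteome row carries at most one effect. A fixed magnitude
  is the simplest distribution with the stated mean |shift| and keeps the
  benchmark interpretable.
- **Missingness**: each phospho cell is censored with probability
  1/(1 + exp(slope·(x − midpoint))) — logistic, decreasing in intensity —
  with midpoint 16 (two latent SDs below the mean) and slope 1, giving
  roughly 5–10% missing cells concentrated at low intensities. This is the
  MNAR premise that motivates downshifted imputation. MCAR and no-censoring
  modes exist for null experiments. The proteome matrix is complete.
- **Truth table**: per-row label (null / phospho_driven / abundance_driven)
  and signed effect, oriented as condition 2 − condition 1.

What the generator does *not* emulate: peptide-level correlation within a
protein, heteroscedastic noise, batch structure, interference, decoys, or
retention-time artifacts. Passing benchmarks therefore demonstrate the
correctness and calibration of the statistics under a clean MNAR log-normal
model, not performance on any particular instrument's data.

## Benchmarks computed by the package

`phosdia.evaluation` measures, on the reference design (5 vs 5, ~500 rows,
|Δlog2| = 2, noise 0.5):

- **Sensitivity / realized FDR** of the permutation test over 20 simulated
  experiments. The realized FDR stays well under the 0.05 check; sensitivity
  for phospho-driven rows sits near 0.9, the shortfall being rows whose
  condition-2 intensities fall near the censoring midpoint and lose
  observations — exactly the rows MNAR makes hard.
- **Abundance-driven recovery**: the fraction of truly abundance-driven
  rows that the regulation caller flags as abundance_driven or mixed
  (≈ 0.9 at defaults).
- **Global null**: with no injected effects, the median significant count
  over 50 experiments is 0.

`scripts/acceptance.py` recomputes all of these from scratch, plus the
run-summary arithmetic (e.g. 3,779 of 5,049 library peptides → 75%), and
writes them as JSON.

## Reproducibility

Every stochastic stage takes an explicit seed or NumPy `Generator`. The
pipeline fans a single global seed into fixed per-stage child seeds
(`numpy.random.SeedSequence`), so a rerun with the same configuration is
byte-identical, while stages remain statistically independent.

## Known limitations

- Exactly two conditions; no time series, no >2-group designs.
- Protein groups are taken as given; group inference from shared peptides
  is upstream.
- No phosphosite-occupancy (stoichiometry) estimation.
- The permutation FDR estimate is undefined guidance when fewer than ~100
  distinct relabelings exist (tiny designs); the implementation still runs
  but the estimate is coarse.
- Kinase-motif definitions are a pluggable input; the built-in set of three
  canonical families (proline-directed, basophilic, acidophilic) exists to
  make class II reachable, not to be exhaustive.
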