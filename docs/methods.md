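# Methods

`hictf` asks which transcription factors (TFs) are over-represented in
high-intensity chromatin interactions in budding yeast, where no single
architectural factor such as metazoan CTCF exists. The unit of analysis
is the *interaction*: an unordered pair of fixed-width genome bins
supported by `n` Hi-C read pairs, with `n` treated as a proxy for how
strongly (or how often) the two loci touch. The package implements two
complementary detectors over the same per-TF summary statistic, a
trend-test baseline, and a generator of synthetic data with planted
effects that makes every stage testable end to end.

## Coordinate model and filtering

Chromosomes are tiled with non-overlapping 1-kb bins (the trailing
partial kilobase of each chromosome is kept as a short bin; nothing in
the analysis depends on equal bin widths). Contacts are aggregated per
canonical bin pair; pairs whose two ends fall in the same bin are
dropped. Two filters precede all statistics:

- **close-pair filter** — intra-chromosomal pairs of identical or
  adjacent bins (genomic separation under one bin width) are removed as
  likely self-ligation artefacts; `min_separation_bins = 2` by default.
- **low-intensity filter** — interactions with fewer than
  `min_reads = 6` supporting reads are removed as noise.

The pipeline then restricts to inter-chromosomal pairs by default
(`subset = "inter"`); intra-chromosomal and mixed analyses are available
but are not the headline setting, since short-range intra-chromosomal
counts are dominated by genomic-distance decay that neither detector
models.

## The overlapping ratio

For a TF with bound bin set `B_tf` (a bin is bound when any binding
interval overlaps it by ≥ 1 bp), an interaction is *positive* when
either of its bins is bound. At an intensity threshold `T`, with
`A = {interactions : n ≥ T}` and `B` the positive set,

    ratio(T) = |A ∩ B| / |A|,

the fraction of at-least-`T` interactions touching the TF's sites.
Curves are computed on the integer grid `T = 6..100` by a single sort
and suffix sums, which is exact; points with `|A| = 0` are flagged
undefined, never reported as 0.

## Detector 1 — chi-square threshold scan

At each `T` in `7..45` (39 values) the interactions are cross-classified
into the 2×2 table (`n ≥ T` vs `n < T`) × (positive vs not), and
Pearson's chi-square with 1 df is computed in closed form; the Yates
continuity correction is off by default (conventional for enrichment
tables at these sizes) and available as a flag. Tables with an empty
margin are *untestable*: they carry no p-value and do not enter the
multiple-testing family. P-values are Bonferroni-adjusted, by default
over the global family of all testable (TF, T) cells (m ≤ n_TFs × 39); a
per-TF family (m ≤ 39) is available because the original analysis's
family is not recoverable. A TF is called significant when at least one
adjusted p falls below `alpha = 0.05`; per-TF counts of raw- and
adjusted-significant thresholds are reported so the two conventions can
be compared.

## Detector 2 — bootstrapped elastic-net selection

The regression view treats the read level itself as the response: for a
range such as `n = 6..40`, each defined integer level contributes one
observation with `y = n` and predictors `x_tf = ratio_tf(n)`. This is a
deliberately under-determined design (35–55 rows, ~100 predictors), so a
sparsity-inducing fit is used: elastic net with mixing weight 0.5
between the L1 and L2 penalties (the canonical compromise; the weight is
a parameter), penalty strength chosen by 10-fold cross-validation
minimizing mean squared error on a 30-point log-spaced grid. Predictors
are standardised internally; coefficients are reported on the original
scale; the intercept is unpenalised. When a bootstrap resample leaves
fewer than twice the fold count of rows, the fold count drops to
`max(3, rows // 5)` to avoid degenerate folds.

Stability is scored by resampling rows with replacement `B = 500` times
in each of five nested ranges (`6..40`, `6..45`, `6..50`, `6..55`,
`6..60`) and counting, per TF, the resamples in which its coefficient is
nonzero. A TF is selected when its count exceeds 5% of B in any single
range **or** 5% of the grand total (25/500 per range, 125/2500 in
total); both sub-criteria are recorded, and the default selected set is
their union because the rule is stated ambiguously in both per-range and
total form. The mean coefficient over selected resamples and the
majority-sign fraction are reported so positively-associated TFs can be
distinguished from negatively-associated ones.

### A structural caveat on the regression design

The ratio curve of *any* TF — including one whose binding is placed
independently of intensity — is a nested-count statistic: as `T` grows,
interactions leave `A` at random, so `ratio(T)` performs a bounded
random walk whose drift correlates strongly with `T` within any one
dataset (median |corr(curve, n)| ≈ 0.6 under the null at default scale).
Because the response *is* the threshold level, this dataset-level
association is genuine in-sample and out-of-fold: cross-validation
rewards dense fits of null curves, and bootstrap resampling of rows does
not break it. Consequently the 5% stability rule is **not calibrated
under the null** in this design: in null simulations most TFs pass it.
The chi-square scan does not share this defect (it compares proportions
at one threshold at a time and is Bonferroni-controlled; null
simulations yield ≈ 0 significant TFs per run). This is the main reason
the package reports the *intersection* of the two detectors as the
high-confidence output: the scan supplies the error control, the
regression supplies an effect-direction-aware ranking (its selection
counts separate planted from null TFs even though its pass/fail rule is
liberal). The acceptance suite asserts the nominal null behaviour for
both detectors and the elastic-net assertion fails by design of the
method, documenting rather than hiding the miscalibration.

## Baseline — trend test in proportions

For each TF and each of the five ranges, the Cochran–Armitage-form
statistic

    chi² = [Σ w_i (x_i − n_i p̄)]² / { p̄(1−p̄) [Σ n_i w_i² − (Σ n_i w_i)²/Σ n_i] }

with `x_i = |A∩B|`, `n_i = |A|`, scores `w_i = T_i` and pooled
proportion `p̄`, tests for a linear trend of the ratio in `T`
(equivalent to R's `prop.trend.test`; verified against it to 10 decimal
places, and algebraically identical to the uncorrected 2×2 chi-square
when only two levels are supplied). The signed square root's sign is
reported as the trend direction, addressing the usual complaint that the
test alone cannot distinguish increasing from decreasing trends. Because
consecutive levels share most of their interactions, the test is
anti-conservative as an enrichment detector and is reported as a
comparison baseline, not combined into the candidate set.

## Combination and export

The candidate set is the intersection of the scan-significant and
elastic-net-selected TF lists, ordered by elastic-net total count then
name. Interactions with `n ≥ T` (default `T = 20`) positive for any
candidate TF are exported as BEDPE links (0-based, half-open; TF names
comma-joined per interaction) for circos-style rendering by external
tools.

## Synthetic data generator

The generator emulates the statistical structure the detectors assume,
at the scale of the yeast genome — not chromatin physics (no polymer
model, no domain structure, no distance decay):

- **genome** — 16 chromosomes, ~12.1 Mb total (rounded sacCer3
  lengths), 1-kb bins (~12,100 bins).
- **interactions** — a configurable number of bin pairs (default
  50,000) drawn uniformly over inter-chromosomal pairs of ~3,500
  "active" bins (mirroring the number of unique interacting fragments
  in real yeast maps); duplicate pairs merge by summing counts. An
  optional intra-chromosomal fraction exists for subset tests.
- **read counts** — `n = 6 + Geometric(p) − 1` with
  `p = 1 − 0.5^(1/5) ≈ 0.129` so that half the interactions carry ≤ 10
  reads, echoing the observed decline of interaction counts with reads;
  a discrete power-law alternative is provided for tail-sensitivity
  work. The geometric tail is lighter above ~100 reads than real maps,
  which makes high-threshold ratios noisier than real data at equal
  sample size — one reason detection scale matters (below).
- **TF binding** — 100 TFs, 150 sites each (12 bp, placed within a
  chosen bin). A null TF chooses bins uniformly. A planted TF (10 by
  default) chooses bin `j` with probability ∝ exp(b0 + b1·s_j), where
  `s_j = log(1 + max n over interactions touching j)` and `b1 = 2.0` by
  default — strong interactions' bins are preferentially bound, which
  is exactly the dependence the detectors target through the
  either-bin-positive labelling rule.

Everything is a pure function of the configuration and master seed;
`write_fixture` serialises a complete dataset (chrom.sizes, contact TSV,
BED4, ground-truth JSON embedding the config) that round-trips through
the package's readers exactly.

What passing on this generator does **not** show: robustness to
distance-dependent intra-chromosomal structure, to non-uniform fragment
usage (centromere/telomere clustering), to mappability artefacts, or to
binding maps whose site counts vary by orders of magnitude across TFs.
It does show that the statistics are computed exactly, that the scan's
error control behaves nominally, and that a binding–intensity dependence
of realistic strength is recovered.

## Problem sizes used in validation

Planted-recovery and determinism checks run the full default scale
(50,000 interaction draws, 100 TFs, B = 500, i.e. 2,500 bootstrap fits
per run). Null calibration uses 20 seeds at full data scale with B = 20
resamples per range (the null outcome is driven by per-fit selection
density, not resampling depth). Unit tests that exercise mechanics
rather than power use a miniature 4-chromosome genome; recovery-style
unit tests use the default genome with 20,000 interactions and 40 TFs,
the smallest scale at which a planted effect of default strength is
Bonferroni-detectable — detection power, not the effect mechanism, is
what shrinks with sample size. The acceptance script reports metrics
from one full planted run plus a 5-seed null sweep.

## Numerical and degenerate-input choices

- Ratios at `|A| = 0` are NaN-flagged and excluded from designs and
  trend inputs; a design range must retain ≥ 10 defined levels.
- Chi-square and trend tests signal untestability (zero margin, pooled
  proportion 0 or 1, zero score variance) via a dedicated exception
  rather than returning a value; untestable cells never enter Bonferroni
  families.
- Coordinate-descent settings (30-alpha grid, tol 1e-3, max_iter 2000)
  were chosen for a well-resolved CV minimum at 35–55-row designs;
  convergence warnings on near-degenerate bootstrap resamples are
  suppressed inside the bootstrap loop.
- All randomness flows from a single master seed through derived child
  seeds (kept below 2³¹); identical configuration + seed reproduces
  every output file byte-for-byte.
- Ties in TF orderings are broken alphabetically after the primary key
  (significant-threshold count or selection count, descending).

## Known limitations

- The elastic-net stage's pass/fail rule is structurally liberal (see
  the caveat above); its value is the ranking and effect signs, and the
  final candidate set should always be the two-method intersection.
- Inputs are assumed to be already-called contacts; no FDR-based
  contact calling, matrix balancing, or duplicate-read handling is
  performed.
- The trend baseline tests levels that share interactions and should
  not be interpreted as an independent-sample trend test.
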