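# Methods

`methclock` re-implements, as a tested library, the analysis stack used to
build species-specific DNA-methylation clocks and disease biomarkers from
mammalian methylation-array beta values: outlier screening, elastic-net
clocks for age and sex with leave-one-out evaluation, per-CpG association
screens (EWAS), moderated differential methylation, and gene-level
over-representation analysis. This note records the models, the defaults
and why, and what the synthetic cohorts do and do not establish.

## Age transform

Methylation drifts rapidly before sexual maturity and roughly linearly in
adulthood, so clocks regress on a transformed age anchored at the age of
sexual maturity (ASM) `m` with offset `k` (both in years):

    F(a) = log(a + k) − log(m + k)   a < m
    F(a) = (a − m) / (m + k)         a ≥ m

`F` is continuous at the knot, strictly increasing, zero at `a = m`, and has
the explicit inverse `F⁻¹(y) = exp(y)(m+k) − k` (y < 0) / `y(m+k) + m`
(y ≥ 0). Natural logarithms throughout. Defaults `m = 2`, `k = 1` years —
cheetahs mature at about two years, and one year is the conventional
offset; both are configurable, and a sensitivity grid of `m ∈ {1.5, 2, 3}`
is the usual robustness check. Extreme negative scores invert to negative
ages and are returned as-is (flagged in logs) rather than clamped, so
miscalibration stays visible.

## Elastic-net clocks

The age clock minimizes the glmnet-style objective
`1/(2n)‖F(age) − b0 − Xw‖² + λ(α‖w‖₁ + (1−α)/2 ‖w‖₂²)` on (by default)
standardized betas, with mixing `α = 0.5` and `λ` chosen at the inner
K-fold CV minimum of mean squared error over a descending log-spaced grid
(25 points; grid top at the smallest λ that zeroes every coefficient; grid
floor at 10⁻² of the top when p > n, 10⁻⁴ otherwise, following glmnet's
rule). If the inner CV picks the grid floor *and* the CV error is in free
fall there (a ≥10× drop across the bottom decade of λ — the signature of
near-noiseless data, where held-out error is pure shrinkage bias and falls
as λ²), the grid is extended downward, at most twice; a curve that has
merely flattened at the floor is left alone, since chasing a shallow CV
minimum into tiny λ just overfits CV noise. Reported coefficients are destandardized to the
raw beta scale, so a stored clock is applied as a bare dot product plus
inverse transform. The published model is always the refit on all training
samples; LOOCV repeats the entire procedure (probe filtering, imputation,
standardization, λ search) without the held-out sample and is evaluation
only, so per-fold CpG sets may differ from the final model's.

Probes missing in more than 20% of training samples are dropped, the rest
mean-imputed from training samples. At prediction time, probes absent from
the input are an error by default or imputed at 0.5 on request. Samples are
internally sorted by id before fitting so results do not depend on input
order. Fits use scikit-learn's coordinate descent with a duality-gap
tolerance of 10⁻³ — on cohorts of this size the selected λ and the fit are
indistinguishable from much tighter tolerances at a fraction of the cost —
and the test suite separately verifies single-λ solutions against an
independent brute-force coordinate-descent solver at tolerance 10⁻¹².

The sex clock is the penalized logistic analogue (saga solver), with the
regularization strength chosen by stratified inner CV on log-loss over a
C grid capped at 10: on separable data, larger C only inflates
coefficients without changing a label and the solver stops converging. The
label mapped to positive scores is fixed lexicographically (so "male" for
female/male data) and recorded on the model; a 0.5 probability resolves to
the positive label.

Accuracy reporting follows clock conventions: Pearson r between
inverse-transformed predictions and chronological age, MAE as the *median*
absolute error in years, and a per-sample accuracy rule
`|pred − true| ≤ max(0.2·true, 1 year)` combining the relative-20% and
1-year phrasings; both knobs are configurable.

Evaluation configuration: LOOCV-heavy runs (tests, the acceptance script)
use 5 inner folds rather than the 10-fold default of single fits — with
n ≈ 60 the selected λ is the same and the evaluation is ~2× cheaper.

## Outlier screening

Per tissue, agglomerative clustering (Euclidean distance on betas, average
linkage by default; 1−Pearson and complete linkage available) with an
explicit cut rule replacing the visual dendrogram inspection such screens
traditionally use: cut at `cut_fraction` (default 0.5) of the maximum
merge height and flag clusters of at most `max_outlier_cluster` (default
2) samples. `max_outlier_cluster = 0` disables flagging; tissues with
fewer than two samples are skipped with a warning. Probes with missing
values are dropped before distances.

## EWAS

Per-probe marginal screening: Pearson correlation against a numeric trait,
with `z = r√(n−2)/√(1−r²)` referred to t(n−2) (|r| capped at 1−10⁻¹² so a
perfect correlation yields a large finite statistic); or a two-sample
t-test (pooled Student by default, Welch optional, variances floored at
machine epsilon) for binary traits, with the mean difference in the `r`
slot so its sign matches `z`. `z > 0` is hypermethylation with the trait.
Missing betas are handled pairwise-complete with per-probe counts
recorded; constant probes get missing statistics. Significance is a raw
p-value threshold (10⁻³ by convention for adequately sized tissues, 10⁻²
for very small ones); no multiplicity adjustment, matching how such
screens are conventionally reported. Region summaries count hyper/hypo
probes per TSS-relative category against the array-wide background
distribution; Venn overlaps between tissue-level significant sets report
all 2^k − 1 exclusive regions and direction concordance in the full
intersection.

## Differential methylation

Per-probe OLS of beta on intercept + case indicator (optional transformed
age and sex covariates), restricted to samples above `min_age` (default 3
years — cases in the motivating cohort only occur above that age, and the
floor avoids conflating juvenile methylation drift with disease). Cases
are samples with an explicit positive diagnosis; suspect and
other-finding samples stay in the control group for fitting but carry
their labels into heatmap annotation tracks. Despite the column name
`logFC`, the effect is the case-minus-control difference of mean beta on
the beta scale (the OLS coefficient), the customary effect measure for
array betas.

Residual variances are moderated by the standard empirical-Bayes scheme
for gene-wise linear models: `s²_post = (d0·s0² + d·s²)/(d0 + d)`, with the
prior `(d0, s0²)` estimated by moment matching on `log s²` via
digamma/trigamma identities and a Newton trigamma inverse; the moderated t
has `d0 + d` degrees of freedom. `prior_df = 0` recovers the ordinary
t-test; the implementation agrees with the Bioconductor reference to
machine precision on shared fixtures (see the test suite). p-values are
BH-adjusted (step-up, missing values passed through and excluded from m)
and `significant` means `p_adj` below the threshold (default 0.05).

The heatmap takes the top k (default 100) significant probes ranked by
(p_adj, p, probe id), z-scores each probe across the *reference* samples,
projects any extra samples (e.g. blood profiles laid alongside a liver
reference) with the reference mean/SD, clusters rows and columns
hierarchically (Euclidean/complete by default) and reports the 2-cluster
column cut.

## Enrichment

Probes map to adjacent-gene symbols (deduplicated, empty symbols dropped).
The universe is gene-level and array-restricted: query and gene sets are
intersected with the deduplicated genes represented on the array before
counting, since a pathway can only be enriched relative to what the chip
could detect. One-sided hypergeometric upper-tail p per set; sets with
overlap below `min_overlap` (default 2) are excluded before BH, so
multiplicity is paid only over tested sets. Hyper-only, hypo-only and
combined queries can be run separately.

## Synthetic cohorts

The generator emulates a small zoo-cohort array study: ~35k probes over
50–70 samples (liver-dominated tissue mix 75/15/10), uniform ages 0–16
years, disease restricted to samples above 3 years at 25% prevalence.
Probe classes are disjoint by default (age, sex, disease, null) so
recovery is identifiable. The mean surface is
`μ = clip(b0 + s·F(age) + Δ·1[female] + δ·1[case] + tissue offset, 0.01, 0.99)`
and observed betas are `expit(logit(μ) + ε)`, `ε ~ N(0, noise_sd²)` —
logit-normal noise keeps betas inside (0,1) without truncation artifacts.
Null baselines are drawn from a 0.1/0.5/0.9 mixture mimicking the bimodal
array landscape; informative baselines are intermediate (0.25–0.75), where
trait-responsive probes concentrate and planted effects stay clear of the
clip. Effect sizes are not published for cohorts like this, so defaults
are chosen to be realistic for array betas and are all configurable: age
slopes 0.02–0.12 beta per transformed-age unit (signs mixed), sex shift
0.15, disease shift 0.2 with an 83% hypomethylated share, logit noise SD
0.15, tissue offsets SD 0.02.

Documented desk-scale study conditions used by the tests and the
acceptance script:

* clock recovery — n = 60, 2000 probes, 200 age CpGs, noise 0.15;
* EWAS null calibration — n = 40, 10,000 null probes, single tissue;
* differential-methylation recovery — n = 30 (10 cases), 2000 probes,
  100 disease CpGs of |δ| = 0.2, noise 0.1, single tissue.

What the generator does *not* emulate: detection p-values, dye bias,
chip/batch effects, probe-probe correlation, relatedness, and cell-type
composition. Passing recovery tests therefore show the algorithms are
implemented correctly and well calibrated under the stated model, not that
the same power holds on real arrays. One generator property worth knowing:
with a mixed-tissue cohort, the per-probe tissue offsets interact with the
single realized age–tissue correlation of the draw, so a naive pooled
age screen is (correctly) miscalibrated — association screens should be
run within tissue, which is how the calibration studies are configured.

## Numerical choices and degenerate inputs

Beta-matrix orientation is auto-detected via the `^cg|^ch` probe-id
pattern; missing values are stored as NaN, never 0 (a legal beta value);
coordinates are 1-based. All-constant design → intercept-only clock
predicting the inverse-transformed mean response. Constant probes or
traits → missing statistics, never crashes. Zero variances → machine
epsilon floors with logged counts. BH inputs outside [0,1] → error. Venn
and region summaries are order-independent; heatmap tie-breaks are
deterministic. All randomness flows from explicit integer seeds; identical
config + seed reproduces byte-identical artifacts.

## Known limitations

LOOCV refits the λ search per fold but, like the clock literature it
mirrors, does not nest a second CV layer for the mixing parameter α.
The sex clock's C grid cap (10) is a convergence guard, not a tuned
value. The moderation fit assumes a common residual df across probes
(true here, where probes share one design) and implements no
robust/trended variants. Enrichment is bag-of-genes; probe density per
gene is not modeled, so genes covered by many probes are easier to hit.
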