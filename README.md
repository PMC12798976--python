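# methclock

Analysis toolkit for DNA-methylation array studies of wildlife cohorts:
elastic-net **epigenetic clocks** for age and sex, per-CpG **association
screens** (EWAS), empirical-Bayes **differential methylation**,
clustering-based **outlier screening**, and background-restricted
**pathway over-representation** — plus a synthetic-cohort generator with a
truth record, so the full pipeline runs and is testable without any
external download.

It is written for the common wildlife-epigenetics setting: a few dozen
biobanked samples (liver, blood, skin) with known chronological age, sex
and clinical annotations, profiled on a conserved-CpG mammalian array and
normalized to beta values in [0, 1].

## The models in brief

**Age clock.** Chronological age is transformed through the piecewise
log-linear map anchored at the age of sexual maturity *m* (offset *k*):

    F(a) = log(a + k) − log(m + k)   for a < m
    F(a) = (a − m) / (m + k)         for a ≥ m

and F(age) is regressed on beta values with the elastic net
(`1/(2n)‖y − b0 − Xw‖² + λ(α‖w‖₁ + (1−α)/2‖w‖₂²)`), λ chosen by inner
K-fold CV. Predictions return through F⁻¹. Evaluation is leave-one-out
cross-validation (the entire procedure refit per fold), summarized by
Pearson r, the **median** absolute error in years, and the fraction of
predictions within max(20% of true age, 1 year). The sex clock is the
penalized logistic analogue.

**EWAS.** Per probe: Pearson correlation against age
(z = r√(n−2)/√(1−r²), t-distributed with n−2 df) or Student's t between
sexes; z > 0 means hypermethylation with the trait. Region summaries and
Venn overlaps of significant CpG sets across tissues are included.

**Differential methylation.** Per-probe OLS of beta on a case indicator
(disease-positive vs the rest, samples above an age floor), with the
classic empirical-Bayes variance moderation
`s²_post = (d0·s0² + d·s²)/(d0+d)` (prior fit by digamma/trigamma moment
matching; agrees with the Bioconductor reference to machine precision in
the tests), Benjamini–Hochberg adjustment, and a top-k row-z-scored
heatmap with 2-cluster column cut and projection of extra samples.

**Enrichment.** One-sided hypergeometric over-representation of
differentially methylated genes against GMT gene sets, with the universe
restricted to genes actually represented on the array.

See `docs/methods.md` for assumptions, defaults, numerical choices and
limitations.

## Worked example

```python
from methclock import (SimConfig, generate_dataset, PenaltyConfig,
                       TransformParams, loocv_age, fit_dma)

# a liver cohort with 60 age-linked CpGs planted among 600 probes
cfg = SimConfig(n_samples=40, n_probes=600, n_age_cpgs=60, n_sex_cpgs=0,
                n_disease_cpgs=60, noise_sd=0.12, tissue_weights=(1, 0, 0),
                age_distribution=(4.0, 16.0), disease_prevalence=1/3, seed=7)
beta, sheet, annot, truth = generate_dataset(cfg)

ev = loocv_age(beta, sheet, TransformParams(asm=2.0, offset=1.0),
               PenaltyConfig(inner_folds=5, seed=7))
print(f"LOOCV r={ev.r:.3f}  MAE={ev.mae:.2f}y  within-20%={ev.accuracy20:.2f}")

res = fit_dma(beta, sheet, min_age=3.0, tissue="liver")
sig = res.significant_probes
hits = len(set(sig) & set(truth.probes_of("disease")))
print(f"DMA: {len(sig)} significant CpGs at q<0.05, {hits} of 60 planted")
```

prints

```
LOOCV r=0.999  MAE=0.08y  within-20%=1.00
DMA: 64 significant CpGs at q<0.05, 60 of 60 planted
```

i.e. the held-out age predictions track truth with a median error under a
tenth of a year and all samples inside the accuracy band, and the disease
contrast recovers every planted CpG (64 calls at q < 0.05, a realized
false-discovery proportion of 4/64 ≈ 0.06, consistent with the nominal
0.05).

The same stages are available from the shell:

```bash
methclock simulate --seed 7 --out run/
methclock outliers --beta run/beta.csv --sheet run/sample_sheet.csv --out run/
methclock loocv    --beta run/beta.csv --sheet run/sample_sheet.csv --out run/loocv
methclock dma      --beta run/beta.csv --sheet run/sample_sheet.csv \
                   --annotation run/annotation.csv --out run/
methclock enrich   --dma-table run/dma.csv --annotation run/annotation.csv \
                   --gmt run/gene_sets.gmt --out run/enrichment.csv
methclock run      --config run.yaml        # multi-stage with manifest.json
```

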