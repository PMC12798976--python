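"""Synthetic methylation cohorts with known truth.

The generator emits the four artifacts the pipeline consumes -- a beta
matrix, a sample sheet, a probe annotation table and (optionally) gene
sets -- together with a truth record, so every downstream stage can be
exercised and scored without any external download.

The statistical structure mirrors a small zoo-cohort methylation-array
study: a few dozen samples across liver/blood/skin, ages spanning birth to
mid-teens, a minority of probes tracking transformed age with slopes of
either sign, a block of sex-dimorphic probes, and a block of disease-shifted
probes that are mostly hypomethylated in cases.  Noise is logit-normal:

    beta_ij = expit( logit(mu_ij) + eps_ij ),  eps_ij ~ N(0, noise_sd^2)

with the mean surface

    mu_ij = clip( b0_j + s_j * F(age_i)
                  + delta_sex_j * 1[female_i]
                  + delta_dis_j * 1[case_i]
                  + tissue_offset[tissue_i, j],  0.01, 0.99 )

where ``F`` is the log-linear age transform.  Working on the logit scale
keeps betas inside (0, 1) without truncation artifacts; the clip on ``mu``
avoids infinite logits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import BetaMatrix, ProbeAnnotation, SampleSheet, REGIONS
from .transform import TransformParams, transform_age

__all__ = ["SimConfig", "TruthRecord", "generate_dataset", "generate_gene_sets"]

_CHROMS = [f"chr{c}" for c in ("A1", "A2", "A3", "B1", "B2", "B3", "B4",
                               "C1", "C2", "D1", "D2", "D3", "D4",
                               "E1", "E2", "E3", "F1", "F2", "X")]


@dataclass(frozen=True)
class SimConfig:
    """Cohort and effect-size settings for :func:`generate_dataset`.

    Effect sizes for age and disease probes are not published for this kind
    of cohort, so the defaults below are chosen to be realistic for array
    betas (age slopes of a few percent beta per transformed-age unit; case
    shifts comparable to reported top differential effects of ~0.15-0.25
    beta) and are all configurable.
    """

    n_samples: int = 60
    n_probes: int = 35000
    n_age_cpgs: int = 2000
    n_sex_cpgs: int = 300
    n_disease_cpgs: int = 1000
    age_slope_range: tuple = (0.02, 0.12)   # |beta| per transformed-age unit
    sex_delta: float = 0.15                 # beta shift in females
    disease_delta: float = 0.2              # |beta| shift in cases
    disease_hypo_fraction: float = 0.83     # share of disease CpGs shifted down
    noise_sd: float = 0.15                  # logit-scale noise SD
    asm: float = 2.0                        # transform knot, years
    offset: float = 1.0                     # transform offset, years
    tissue_shift_sd: float = 0.02           # per-(tissue, probe) offset SD, beta
    age_distribution: tuple = (0.0, 16.0)   # uniform age range, years
    disease_age_min: float = 3.0            # cases only above this age
    disease_prevalence: float = 0.25        # case share among eligible samples
    tissue_weights: tuple = (0.75, 0.15, 0.10)  # liver, blood, skin
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_info = self.n_age_cpgs + self.n_sex_cpgs + self.n_disease_cpgs
        if n_info > self.n_probes:
            raise ValueError(
                f"informative probe counts ({n_info}) exceed n_probes ({self.n_probes})"
            )
        for name in ("disease_hypo_fraction", "disease_prevalence", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort.

    ``probe_class`` assigns each probe to one of {age, sex, disease, null};
    ``effect`` holds the true slope (age probes, per transformed-age unit)
    or shift (sex/disease probes, beta units; sign included), 0 for nulls.
    ``samples`` is a copy of the emitted sample sheet data.
    """

    probe_class: pd.Series
    effect: pd.Series
    samples: pd.DataFrame
    config: SimConfig

    def probes_of(self, cls: str) -> list:
        return self.probe_class.index[self.probe_class == cls].tolist()


def _draw_baselines(rng, n_null: int, n_info: int) -> tuple:
    """Bimodal baseline for null probes, intermediate for informative ones.

    Array betas are strongly bimodal (mostly near 0.1 or 0.9, some
    intermediate); trait-responsive probes sit mostly at intermediate
    methylation, which also keeps planted effects away from the clip.
    """
    centers = rng.choice([0.1, 0.5, 0.9], size=n_null, p=[0.4, 0.2, 0.4])
    b0_null = np.clip(centers + rng.normal(0.0, 0.05, size=n_null), 0.02, 0.98)
    b0_info = rng.uniform(0.25, 0.75, size=n_info)
    return b0_null, b0_info


def generate_dataset(config: SimConfig):
    """Simulate one cohort; fully reproducible from ``config.seed``.

    Returns ``(BetaMatrix, SampleSheet, ProbeAnnotation, TruthRecord)``.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_probes
    tparams = TransformParams(asm=config.asm, offset=config.offset)

    # --- samples -----------------------------------------------------------
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    tissue = rng.choice(TISSUE_ORDER, size=n, p=np.asarray(config.tissue_weights))
    sex = rng.choice(["female", "male"], size=n)
    lo, hi = config.age_distribution
    age = rng.uniform(lo, hi, size=n)

    status = np.array(["none"] * n, dtype=object)
    eligible = np.flatnonzero(age > config.disease_age_min)
    n_cases = int(round(config.disease_prevalence * len(eligible)))
    case_idx = rng.choice(eligible, size=n_cases, replace=False) if n_cases else np.array([], int)
    status[case_idx] = "sos_positive"
    remaining = np.setdiff1d(eligible, case_idx)
    # a sprinkling of suspect / other-finding annotations among non-cases
    n_susp = int(round(0.1 * len(remaining)))
    n_other = int(round(0.1 * len(remaining)))
    side = rng.choice(remaining, size=min(n_susp + n_other, len(remaining)), replace=False)
    status[side[:n_susp]] = "sos_suspect"
    status[side[n_susp:]] = "liver_other"

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "individual_id": [f"I{i + 1:03d}" for i in range(n)],
        "tissue": tissue,
        "species": "cheetah",
        "sex": sex,
        "age_years": age,
        "disease_status": status,
        "source": "synthetic",
    }))

    # --- probes ------------------------------------------------------------
    probe_ids = [f"cg{i:08d}" for i in range(1, p + 1)]
    n_info = config.n_age_cpgs + config.n_sex_cpgs + config.n_disease_cpgs
    info_idx = rng.choice(p, size=n_info, replace=False)
    age_idx = info_idx[: config.n_age_cpgs]
    sex_idx = info_idx[config.n_age_cpgs: config.n_age_cpgs + config.n_sex_cpgs]
    dis_idx = info_idx[config.n_age_cpgs + config.n_sex_cpgs:]

    probe_class = np.array(["null"] * p, dtype=object)
    probe_class[age_idx] = "age"
    probe_class[sex_idx] = "sex"
    probe_class[dis_idx] = "disease"

    b0 = np.empty(p)
    null_mask = probe_class == "null"
    b0[null_mask], b0[~null_mask] = _draw_baselines(rng, int(null_mask.sum()), n_info)

    slo, shi = config.age_slope_range
    slopes = np.zeros(p)
    slopes[age_idx] = rng.uniform(slo, shi, size=len(age_idx)) * rng.choice(
        [-1.0, 1.0], size=len(age_idx)
    )
    sex_shift = np.zeros(p)
    sex_shift[sex_idx] = config.sex_delta * rng.choice([-1.0, 1.0], size=len(sex_idx))
    dis_shift = np.zeros(p)
    n_hypo = int(round(config.disease_hypo_fraction * len(dis_idx)))
    signs = np.ones(len(dis_idx))
    hypo_pick = rng.choice(len(dis_idx), size=n_hypo, replace=False)
    signs[hypo_pick] = -1.0
    dis_shift[dis_idx] = config.disease_delta * signs

    effect = slopes + sex_shift + dis_shift  # disjoint classes, so additive

    # --- mean surface and noise -------------------------------------------
    f_age = transform_age(age, tparams)
    is_female = (sex == "female").astype(float)
    is_case = (status == "sos_positive").astype(float)
    tissue_offsets = rng.normal(0.0, config.tissue_shift_sd, size=(len(TISSUE_ORDER), p))
    t_index = np.array([TISSUE_ORDER.index(t) for t in tissue])

    mu = (
        b0[None, :]
        + np.outer(f_age, slopes)
        + np.outer(is_female, sex_shift)
        + np.outer(is_case, dis_shift)
        + tissue_offsets[t_index]
    )
    np.clip(mu, 0.01, 0.99, out=mu)
    if config.noise_sd > 0:
        values = expit(logit(mu) + rng.normal(0.0, config.noise_sd, size=mu.shape))
    else:
        values = mu
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.copy()
        values[mask] = np.nan

    beta = BetaMatrix(sample_ids, probe_ids, values)

    # --- annotation --------------------------------------------------------
    n_genes = max(1, p // 3)
    gene_pool = np.array([f"GENE{i + 1:05d}" for i in range(n_genes)])
    annot = ProbeAnnotation(pd.DataFrame({
        "probe_id": probe_ids,
        "chrom": rng.choice(_CHROMS, size=p),
        "pos": rng.integers(1, 200_000_000, size=p),
        "gene": gene_pool[rng.integers(0, n_genes, size=p)],
        "region": rng.choice(REGIONS[:-1], size=p),
    }))

    truth = TruthRecord(
        probe_class=pd.Series(probe_class, index=probe_ids, name="class"),
        effect=pd.Series(effect, index=probe_ids, name="effect"),
        samples=sheet.data.copy(),
        config=config,
    )
    return beta, sheet, annot, truth


TISSUE_ORDER = ["liver", "blood", "skin"]


def generate_gene_sets(
    annot: ProbeAnnotation,
    n_sets: int = 20,
    set_size_range: tuple = (20, 200),
    enriched_genes=None,
    n_enriched_sets: int = 2,
    seed: int = 0,
) -> dict:
    """Random GMT-style gene sets drawn from the annotation's gene universe.

    When ``enriched_genes`` is given, the first ``n_enriched_sets`` sets are
    seeded with a majority of those genes so that over-representation
    analysis has true positives to find.
    """
    rng = np.random.default_rng(seed)
    universe = sorted({g for g in annot.data["gene"] if g})
    if not universe:
        raise ValueError("annotation has no gene symbols")
    universe = np.array(universe)
    sets = {}
    lo, hi = set_size_range
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(universe, size=min(size, len(universe)), replace=False))
        if enriched_genes and i < n_enriched_sets:
            pool = [g for g in enriched_genes if g in set(universe)]
            take = min(len(pool), max(1, size // 2))
            seeded = list(rng.choice(np.array(pool), size=take, replace=False))
            members = sorted(set(seeded + members[: size - take]))
        sets[f"SET{i + 1:03d}"] = (f"synthetic gene set {i + 1}", sorted(set(members)))
    return sets
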