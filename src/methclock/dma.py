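"""Differential methylation analysis with empirical-Bayes variance moderation.

Case-versus-control differences are estimated probe-by-probe with ordinary
least squares (intercept + case indicator, optionally age/sex covariates),
then the per-probe residual variances are shrunk toward a common prior by
the standard empirical-Bayes scheme for gene-wise linear models: the
residual variances s_g^2 (d residual df each) are modeled as scaled-F
draws around a prior variance s0^2 with d0 prior df, and the posterior
variance

    s_post^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

replaces s_g^2 in the t-statistic, which then has d0 + d degrees of
freedom.  (d0, s0^2) are estimated by moment matching on log s_g^2 via the
digamma/trigamma identities, with the trigamma inverse found by Newton
iteration.  With few samples per group this borrowing of strength across
probes is what makes the test stable.

Despite the conventional column name ``logFC``, the reported effect here is
the case-minus-control difference of mean beta *on the beta scale* (the
case-indicator OLS coefficient) -- methylation differences are customarily
reported this way for array betas, so values live in [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .io import BetaMatrix, SampleSheet
from .transform import TransformParams, transform_age

logger = logging.getLogger(__name__)

__all__ = ["DmaResult", "HeatmapBundle", "fit_dma", "bh_adjust", "build_heatmap",
           "trigamma_inverse", "fit_f_dist"]


@dataclass
class DmaResult:
    """Per-probe moderated-t table plus the moderation hyperparameters.

    ``table`` columns: logFC (case - control mean beta), t_mod, p, p_adj
    (Benjamini-Hochberg), significant.  ``d0``/``s0_sq`` are the prior df
    and prior variance; ``df_residual`` the per-probe residual df.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    df_residual: float
    s2: pd.Series
    case_sample_ids: list
    control_sample_ids: list
    p_adj_threshold: float

    @property
    def significant_probes(self) -> list:
        t = self.table
        return t.index[t["significant"]].tolist()


def trigamma_inverse(y: float, max_iter: int = 50, tol: float = 1e-10) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple:
    """Method-of-moments fit of the scaled-F prior to residual variances.

    Matches mean and variance of log(s^2) using digamma/trigamma; returns
    ``(d0, s0_sq)`` with ``d0 = inf`` when the observed spread of log
    variances does not exceed its sampling variability.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Missing entries pass through as NaN and do not count toward ``m``.
    Values outside [0, 1] raise.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def fit_dma(
    beta: BetaMatrix,
    sheet: SampleSheet,
    case_label: str = "sos_positive",
    control_labels=None,
    min_age: float = 3.0,
    covariates=None,
    p_adj_threshold: float = 0.05,
    tissue: str | None = None,
    prior_df: float | None = None,
) -> DmaResult:
    """Moderated-t differential methylation between case and control samples.

    Samples are restricted to ``age_years > min_age`` (and to ``tissue``
    when given); cases are the samples whose ``disease_status`` equals
    ``case_label`` and controls are all other retained samples unless
    ``control_labels`` narrows them.  ``covariates`` may list ``"age"``
    (transformed age) and/or ``"sex"``.  ``prior_df`` overrides the
    estimated d0 (0 recovers the ordinary unmoderated t-test).
    """
    meta = sheet.aligned_to(beta)
    keep = meta["age_years"] > min_age
    if tissue is not None:
        keep &= meta["tissue"] == tissue
    meta = meta[keep]
    is_case = meta["disease_status"] == case_label
    if control_labels is None:
        is_control = ~is_case
    else:
        is_control = meta["disease_status"].isin(list(control_labels))
    used = meta[is_case | is_control]
    case_ids = used.loc[used["disease_status"] == case_label, "sample_id"].tolist()
    control_ids = [s for s in used["sample_id"] if s not in set(case_ids)]
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(case_ids)} cases / "
            f"{len(control_ids)} controls"
        )

    sample_ids = used["sample_id"].tolist()
    idx = [beta.sample_ids.index(s) for s in sample_ids]
    Y = beta.values[idx]
    complete = ~np.isnan(Y).any(axis=0)
    if not complete.all():
        logger.warning("dropping %d probes with missing values", int((~complete).sum()))
    probe_ids = np.array(beta.probe_ids)[complete]
    Y = Y[:, complete]

    cols = [np.ones(len(used)), used["disease_status"].eq(case_label).to_numpy(float)]
    names = ["intercept", "case"]
    for cov in covariates or []:
        if cov == "age":
            cols.append(transform_age(used["age_years"].to_numpy(), TransformParams()))
        elif cov == "sex":
            cols.append(used["sex"].eq("male").to_numpy(float))
        else:
            raise ValueError(f"unknown covariate {cov!r}")
        names.append(cov)
    X = np.column_stack(cols)
    n, q = X.shape
    df_resid = n - np.linalg.matrix_rank(X)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    pinv = np.linalg.pinv(X)
    B = pinv @ Y
    resid = Y - X @ B
    s2 = (resid ** 2).sum(axis=0) / df_resid
    eps = np.finfo(float).eps
    n_floor = int((s2 < eps).sum())
    if n_floor:
        logger.warning("floored %d zero-variance probes at machine epsilon", n_floor)
    s2 = np.maximum(s2, eps)
    c_case = np.linalg.inv(X.T @ X)[1, 1]
    logfc = B[1]

    if prior_df is None:
        d0, s0_sq = fit_f_dist(s2, df_resid)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    elif np.isinf(prior_df):
        _, s0_sq = fit_f_dist(s2, df_resid)
        d0 = np.inf
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_f_dist(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se_post = np.sqrt(c_case * s2_post)
    t_mod = logfc / se_post
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p_adj = bh_adjust(p)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t_mod": t_mod,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < p_adj_threshold,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return DmaResult(
        table=table,
        d0=float(d0),
        s0_sq=float(s0_sq),
        df_residual=float(df_resid),
        s2=pd.Series(s2, index=probe_ids, name="s2"),
        case_sample_ids=case_ids,
        control_sample_ids=control_ids,
        p_adj_threshold=p_adj_threshold,
    )


@dataclass
class HeatmapBundle:
    """Row-z-scored top-k matrix with hierarchical clusterings.

    ``matrix`` is probes x samples; rows were centered/scaled using the
    *reference* samples only, and any extra (projected) samples reuse the
    reference mean/SD, so reference rows have mean 0 / SD 1 exactly.
    ``col_clusters`` holds the 2-cluster column cut labels.
    """

    matrix: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    col_clusters: pd.Series
    reference_sample_ids: list
    extra_sample_ids: list
    annotations: pd.DataFrame | None


def build_heatmap(
    dma: DmaResult,
    beta_ref: BetaMatrix,
    beta_extra: BetaMatrix | None = None,
    k: int = 100,
    linkage: str = "complete",
    distance: str = "euclidean",
    sheet: SampleSheet | None = None,
    n_col_clusters: int = 2,
) -> HeatmapBundle:
    """Top-k significant probes, z-scored over reference samples, clustered.

    Probes are ranked by (p_adj, p, probe_id); ``k`` caps at the number of
    significant probes.  Extra samples (e.g. blood profiles laid alongside a
    liver reference) are projected with the reference row statistics, not
    re-scaled.
    """
    from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
    from scipy.spatial.distance import pdist

    if k <= 0:
        raise ValueError("k must be positive")
    sig = dma.table[dma.table["significant"]].copy()
    if sig.empty:
        raise ValueError("no significant probes to plot")
    sig = sig.assign(_probe=sig.index).sort_values(
        ["p_adj", "p", "_probe"], kind="mergesort"
    )
    top = sig.index[: min(k, len(sig))].tolist()

    ref = beta_ref.to_frame()[top].T  # probes x samples
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=0).replace(0.0, np.nan)
    Z = ref.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    extra_ids: list = []
    if beta_extra is not None:
        extra = beta_extra.to_frame().reindex(columns=top).T
        Zx = extra.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
        extra_ids = list(beta_extra.sample_ids)
        Z = pd.concat([Z, Zx], axis=1)

    metric = "euclidean" if distance == "euclidean" else "correlation"
    row_link = scipy_linkage(pdist(Z.to_numpy(), metric=metric), method=linkage)
    col_link = scipy_linkage(pdist(Z.to_numpy().T, metric=metric), method=linkage)
    labels = fcluster(col_link, t=n_col_clusters, criterion="maxclust")
    col_clusters = pd.Series(labels, index=Z.columns, name="cluster")

    annotations = None
    if sheet is not None:
        meta = sheet.data.set_index("sample_id")
        annotations = meta.reindex(Z.columns)[["disease_status", "age_years", "sex", "tissue"]]

    return HeatmapBundle(
        matrix=Z,
        row_linkage=row_link,
        col_linkage=col_link,
        col_clusters=col_clusters,
        reference_sample_ids=list(beta_ref.sample_ids),
        extra_sample_ids=extra_ids,
        annotations=annotations,
    )
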