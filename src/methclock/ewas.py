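"""Epigenome-wide association screening of methylation against a trait.

Each probe is tested marginally: Pearson correlation against a numeric
trait (age), or a two-sample t-test against a binary trait (sex).  The
signed statistic ``z`` carries the direction of association -- ``z > 0``
means hypermethylation with an increasing trait (or in the second group),
``z < 0`` hypomethylation.  Downstream consumers use only the sign of ``z``
and the raw p-value threshold, so ``z`` is defined as the t-statistic
itself.  Missing betas are handled pairwise-complete per probe and the
per-probe sample count is recorded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "EwasResult",
    "screen_numeric",
    "screen_binary",
    "region_proportions",
    "overlap_sets",
    "OverlapSummary",
]

_R_CAP = 1.0 - 1e-12  # guard before the t formula at perfect correlation


@dataclass
class EwasResult:
    """Per-probe association table.

    ``table`` columns: r (correlation or group mean difference), z (signed
    t-statistic), p (two-sided), significant, n_used.  Statistics are NaN
    for probes that are constant or have too few complete pairs.
    """

    table: pd.DataFrame
    trait_kind: str  # "numeric" | "binary"
    p_threshold: float

    @property
    def significant_probes(self) -> list:
        t = self.table
        return t.index[t["significant"]].tolist()

    def direction(self) -> pd.Series:
        """Sign of association (+1 hyper, -1 hypo) for significant probes."""
        t = self.table
        return np.sign(t.loc[t["significant"], "z"])


def _nan_moments(values: np.ndarray, x: np.ndarray):
    """Pairwise-complete sums needed for per-probe Pearson r against x."""
    ok = np.isfinite(values)
    V = np.where(ok, values, 0.0)
    n = ok.sum(axis=0).astype(float)
    sx = x @ ok
    sv = V.sum(axis=0)
    sxx = (x ** 2) @ ok
    svv = (V ** 2).sum(axis=0)
    sxv = x @ V
    return n, sx, sv, sxx, svv, sxv


def screen_numeric(beta: BetaMatrix, trait, p_threshold: float = 1e-3) -> EwasResult:
    """Per-probe Pearson correlation screen against a numeric trait.

    ``trait`` is aligned to ``beta.sample_ids`` (array-like of the same
    length); samples with missing trait are dropped up front.  For each
    probe, r is the pairwise-complete Pearson correlation,
    ``z = r * sqrt(n - 2) / sqrt(1 - r^2)`` and p is two-sided from the t
    distribution with ``n - 2`` degrees of freedom.
    """
    x = np.asarray(trait, dtype=float)
    if x.shape[0] != beta.n_samples:
        raise ValueError("trait length must match the number of samples")
    keep = np.isfinite(x)
    if keep.sum() < 3:
        raise ValueError("need at least 3 samples with a non-missing trait")
    x = x[keep]
    values = beta.values[keep]
    if np.ptp(x) == 0:
        logger.warning("trait is constant; all statistics are undefined")
        nan = np.full(beta.n_probes, np.nan)
        table = pd.DataFrame(
            {"r": nan, "z": nan, "p": nan, "significant": False,
             "n_used": int(keep.sum())},
            index=pd.Index(beta.probe_ids, name="probe_id"),
        )
        return EwasResult(table, "numeric", p_threshold)

    n, sx, sv, sxx, svv, sxv = _nan_moments(values, x)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxv - sx * sv
        var_x = n * sxx - sx ** 2
        var_v = n * svv - sv ** 2
        r = cov / np.sqrt(var_x * var_v)
        r = np.where(n >= 3, r, np.nan)
        r = np.clip(r, -1.0, 1.0)
        r_c = np.clip(r, -_R_CAP, _R_CAP)
        z = r_c * np.sqrt(n - 2) / np.sqrt(1.0 - r_c ** 2)
        p = 2.0 * stats.t.sf(np.abs(z), df=n - 2)
    table = pd.DataFrame(
        {
            "r": r,
            "z": z,
            "p": p,
            "significant": (p < p_threshold) & np.isfinite(p),
            "n_used": n.astype(int),
        },
        index=pd.Index(beta.probe_ids, name="probe_id"),
    )
    return EwasResult(table, "numeric", p_threshold)


def screen_binary(
    beta: BetaMatrix,
    labels,
    p_threshold: float = 1e-3,
    variance: str = "pooled",
) -> EwasResult:
    """Per-probe two-sample t-test screen against a binary trait.

    Groups are the two sorted unique labels; the ``r`` slot holds
    ``mean(group2) - mean(group1)`` so its sign matches ``z``.  ``variance``
    selects the classic pooled (Student) or Welch statistic; zero variances
    are floored at machine epsilon.
    """
    if variance not in ("pooled", "welch"):
        raise ValueError("variance must be 'pooled' or 'welch'")
    labels = pd.Series(list(labels))
    if len(labels) != beta.n_samples:
        raise ValueError("labels length must match the number of samples")
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    eps = np.finfo(float).eps

    def moments(mask):
        ok = np.isfinite(beta.values[mask])
        V = np.where(ok, beta.values[mask], 0.0)
        n = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = V.sum(axis=0) / n
            ss = (V ** 2).sum(axis=0) - n * mean ** 2
            var = np.where(n > 1, ss / (n - 1), np.nan)
        return n, mean, np.maximum(var, eps)

    n1, m1, v1 = moments((labels == groups[0]).to_numpy())
    n2, m2, v2 = moments((labels == groups[1]).to_numpy())
    if (n1 < 2).all() or (n2 < 2).all():
        raise ValueError("each group needs at least 2 samples")
    diff = m2 - m1
    with np.errstate(invalid="ignore", divide="ignore"):
        if variance == "pooled":
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
    bad = (n1 < 2) | (n2 < 2)
    for arr in (diff, t, p):
        arr[bad] = np.nan
    table = pd.DataFrame(
        {
            "r": diff,
            "z": t,
            "p": p,
            "significant": (p < p_threshold) & np.isfinite(p),
            "n_used": (n1 + n2).astype(int),
        },
        index=pd.Index(beta.probe_ids, name="probe_id"),
    )
    return EwasResult(table, "binary", p_threshold)


def region_proportions(result: EwasResult, annot: ProbeAnnotation) -> pd.DataFrame:
    """Hyper/hypomethylation counts of significant probes per genomic region.

    Returns one row per region with ``n_hyper`` (z > 0), ``n_hypo`` (z < 0),
    ``hyper_fraction`` (NaN when the region has no significant probes) and
    ``n_background`` (all annotated probes in the region, the array-wide
    reference distribution).
    """
    ann = annot.indexed()["region"]
    sig = result.table[result.table["significant"]]
    region = ann.reindex(sig.index).fillna("unannotated")
    hyper = sig["z"] > 0
    regions = sorted(set(ann.unique()) | set(region.unique()))
    rows = []
    for reg in regions:
        in_reg = region == reg
        n_hyper = int((hyper & in_reg).sum())
        n_hypo = int(((~hyper) & in_reg & (sig["z"] < 0)).sum())
        total = n_hyper + n_hypo
        rows.append({
            "region": reg,
            "n_hyper": n_hyper,
            "n_hypo": n_hypo,
            "hyper_fraction": n_hyper / total if total else np.nan,
            "n_background": int((ann == reg).sum()),
        })
    return pd.DataFrame(rows).set_index("region")


@dataclass
class OverlapSummary:
    """Venn-style breakdown of named significant-probe sets.

    ``region_counts`` maps each non-empty membership pattern (a tuple of set
    names) to the number of probes found in exactly those sets.
    ``intersection`` lists the probes common to all sets with their per-set
    direction signs and whether the sign is concordant everywhere.
    """

    region_counts: dict
    intersection: pd.DataFrame


def overlap_sets(named_sets: dict) -> OverlapSummary:
    """Exact Venn region counts for >= 2 named probe sets.

    ``named_sets`` maps a name to either a set of probe ids or a pandas
    Series of signed statistics indexed by probe id (signs are then carried
    into the full-intersection table).
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(named_sets)
    members = {}
    signs = {}
    for name, obj in named_sets.items():
        if isinstance(obj, pd.Series):
            members[name] = set(obj.index)
            signs[name] = np.sign(obj)
        else:
            members[name] = set(obj)
            signs[name] = None

    counts = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(members[c] for c in combo))
            outside = set.union(set(), *(members[n] for n in names if n not in combo))
            counts[combo] = len(inside - outside)

    full = sorted(set.intersection(*members.values()))
    rows = []
    for probe in full:
        row = {"probe_id": probe}
        probe_signs = []
        for name in names:
            s = signs[name]
            val = float(s.loc[probe]) if s is not None else np.nan
            row[f"sign_{name}"] = val
            if np.isfinite(val):
                probe_signs.append(val)
        row["concordant"] = (
            bool(len({np.sign(v) for v in probe_signs}) == 1) if probe_signs else True
        )
        rows.append(row)
    intersection = pd.DataFrame(rows, columns=["probe_id", *(f"sign_{n}" for n in names),
                                               "concordant"])
    return OverlapSummary(region_counts=counts, intersection=intersection)
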