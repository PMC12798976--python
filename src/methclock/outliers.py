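"""Clustering-based detection of sample outliers.

Methylation cohorts are screened per tissue with unsupervised hierarchical
clustering before any modeling; samples that split off from the main group
(technical artifacts, degraded DNA, genuinely divergent biology) are
flagged and excluded.  Visual dendrogram-cut choices are replaced here by
an explicit, reproducible rule: cut the tree at ``cut_fraction`` times the
maximum merge height and flag every cluster of size at most
``max_outlier_cluster``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .io import BetaMatrix, SampleSheet

logger = logging.getLogger(__name__)

__all__ = ["OutlierReport", "TissueClustering", "detect_outliers"]

_DISTANCES = {"euclidean": "euclidean", "one_minus_pearson": "correlation"}
_LINKAGES = ("average", "complete")


@dataclass
class TissueClustering:
    tissue: str
    sample_ids: list
    linkage_matrix: np.ndarray  # scipy (n-1, 4) merge table
    cut_height: float
    flagged_sample_ids: list


@dataclass
class OutlierReport:
    """Per-tissue clustering results and flagged samples."""

    by_tissue: dict

    @property
    def flagged_sample_ids(self) -> list:
        out = []
        for tc in self.by_tissue.values():
            out.extend(tc.flagged_sample_ids)
        return sorted(out)


def detect_outliers(
    beta: BetaMatrix,
    sheet: SampleSheet,
    distance: str = "euclidean",
    linkage: str = "average",
    cut_fraction: float = 0.5,
    max_outlier_cluster: int = 2,
) -> OutlierReport:
    """Flag outlier samples by agglomerative clustering, separately per tissue.

    Probes with any missing value (within the tissue's samples) are dropped
    before distances are computed.  Tissues with fewer than two samples are
    skipped with a warning.  ``max_outlier_cluster = 0`` disables flagging.
    """
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {sorted(_DISTANCES)}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if not 0 < cut_fraction <= 1:
        raise ValueError("cut_fraction must lie in (0, 1]")

    meta = sheet.aligned_to(beta)
    report = {}
    for tissue in sorted(meta["tissue"].unique()):
        ids = meta.loc[meta["tissue"] == tissue, "sample_id"].tolist()
        if len(ids) < 2:
            logger.warning("tissue %r has <2 samples; skipping outlier check", tissue)
            continue
        idx = [beta.sample_ids.index(s) for s in ids]
        X = beta.values[idx]
        X = X[:, ~np.isnan(X).any(axis=0)]
        dists = pdist(X, metric=_DISTANCES[distance])
        Z = scipy_linkage(dists, method=linkage)
        max_h = float(Z[:, 2].max()) if len(Z) else 0.0
        cut = cut_fraction * max_h
        flagged: list = []
        if max_h > 0 and max_outlier_cluster >= 1:
            labels = fcluster(Z, t=cut, criterion="distance")
            sizes = np.bincount(labels)
            small = {c for c in np.unique(labels) if sizes[c] <= max_outlier_cluster}
            flagged = sorted(s for s, lab in zip(ids, labels) if lab in small)
        report[tissue] = TissueClustering(
            tissue=tissue,
            sample_ids=ids,
            linkage_matrix=Z,
            cut_height=cut,
            flagged_sample_ids=flagged,
        )
    return OutlierReport(by_tissue=report)


def format_dendrogram(tc: TissueClustering) -> str:
    """Plain-text merge listing of a tissue's dendrogram (for run artifacts)."""
    lines = [f"# tissue={tc.tissue} cut_height={tc.cut_height:.6g}"]
    n = len(tc.sample_ids)

    def name(i: int) -> str:
        return tc.sample_ids[i] if i < n else f"node{i - n}"

    for row_i, (a, b, h, size) in enumerate(tc.linkage_matrix):
        lines.append(
            f"node{row_i}: merge({name(int(a))}, {name(int(b))}) "
            f"height={h:.6g} size={int(size)}"
        )
    return "\n".join(lines)
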