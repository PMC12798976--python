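"""Gene-level over-representation analysis against pathway gene sets.

Differentially methylated probes are mapped to their adjacent genes and
tested against each gene set with the one-sided hypergeometric (Fisher
upper-tail) test.  The universe is deliberately *gene-level and
array-restricted*: many probes map to one gene, and a pathway can only be
"enriched" relative to what the chip could have detected, so both the
query and every gene set are intersected with the deduplicated background
of genes represented on the array before counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .dma import bh_adjust
from .io import ProbeAnnotation

__all__ = ["EnrichmentResult", "map_probes_to_genes", "hypergeom_ora"]


@dataclass
class EnrichmentResult:
    """Per-set over-representation table, sorted by p.

    ``table`` columns: set_id, description, set_size_in_background, overlap,
    gene_ratio (overlap / query size), p (hypergeometric upper tail), p_adj
    (BH across tested sets), genes (semicolon-joined overlap symbols).
    """

    table: pd.DataFrame
    n_background: int
    n_query: int


def map_probes_to_genes(probes, annot: ProbeAnnotation) -> list:
    """Deduplicated, sorted gene symbols of the given probes.

    Probes absent from the annotation or with an empty symbol contribute
    nothing; the output does not depend on input order.
    """
    ann = annot.indexed()["gene"]
    genes = ann.reindex([str(p) for p in probes]).dropna()
    return sorted({g for g in genes if g})


def hypergeom_ora(
    query_genes,
    gene_sets: dict,
    background_genes,
    min_overlap: int = 2,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation over GMT gene sets.

    With N background genes, K of them in the set, n in the query and x in
    both, ``p = P[X >= x]`` for ``X ~ Hypergeom(N, K, n)``.  Sets with
    ``x < min_overlap`` are dropped before BH adjustment, so multiplicity is
    paid only over the sets actually tested.
    """
    background = {str(g) for g in background_genes}
    if not background:
        raise ValueError("background gene universe is empty")
    query = {str(g) for g in query_genes} & background
    if not query:
        raise ValueError("query is empty after intersection with the background")
    N, n = len(background), len(query)
    rows = []
    for set_id, value in gene_sets.items():
        desc, genes = value if isinstance(value, tuple) else ("", value)
        in_bg = set(genes) & background
        hit = sorted(in_bg & query)
        K, x = len(in_bg), len(hit)
        if x < min_overlap:
            continue
        p = float(hypergeom.sf(x - 1, N, K, n))
        rows.append({
            "set_id": set_id,
            "description": desc,
            "set_size_in_background": K,
            "overlap": x,
            "gene_ratio": x / n,
            "p": p,
            "genes": ";".join(hit),
        })
    table = pd.DataFrame(
        rows,
        columns=["set_id", "description", "set_size_in_background", "overlap",
                 "gene_ratio", "p", "genes"],
    )
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return EnrichmentResult(table=table, n_background=N, n_query=n)
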