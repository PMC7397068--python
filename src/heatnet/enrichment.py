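"""Gene-set enrichment of subnetwork genes by hypergeometric overlap.

Given a subnetwork gene list and a GMT collection, each set is scored by
the upper-tail hypergeometric test against a background universe (by
default the pruned PPI gene set), reusing the single tested tail
implementation from the similarity module.  Raw p-values decide
significance (threshold 0.05); Benjamini-Hochberg adjusted values are
reported alongside.  This is the plain overlap test, not DAVID's
EASE-adjusted variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .similarity import hypergeometric_upper_tail

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentRecord", "enrich", "adjust_bh"]

SIGNIFICANCE_THRESHOLD = 0.05


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentRecord:
    set_id: str
    overlap: int
    set_size: int       # |S ∩ universe|
    query_size: int     # |query ∩ universe|
    universe_size: int
    p_value: float
    p_adjusted: float
    significant: bool


def adjust_bh(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(query_genes, collection, universe) -> list[EnrichmentRecord]:
    """Score every set in ``collection`` against ``query_genes``.

    ``collection`` is a GeneSetCollection (or any iterable of objects
    with ``set_id`` and ``members``).  Query genes outside the universe
    are dropped with a logged count.  Records are sorted ascending by
    raw p, ties by set id.
    """
    universe = set(universe)
    if not universe:
        raise EnrichmentError("empty universe")
    query = set(query_genes) & universe
    n_outside = len(set(query_genes)) - len(query)
    if n_outside:
        logger.info("dropping %d query gene(s) outside the universe", n_outside)
    if not query:
        raise EnrichmentError("no query genes inside the universe")
    M, N = len(universe), len(query)
    sets = getattr(collection, "sets", collection)
    records = []
    for gene_set in sets:
        members = set(gene_set.members) & universe
        K = len(members)
        x = len(query & members)
        p = hypergeometric_upper_tail(x, K, N, M)
        records.append(EnrichmentRecord(
            set_id=gene_set.set_id, overlap=x, set_size=K, query_size=N,
            universe_size=M, p_value=p, p_adjusted=np.nan,
            significant=p <= SIGNIFICANCE_THRESHOLD,
        ))
    records.sort(key=lambda r: (r.p_value, r.set_id))
    adjusted = adjust_bh([r.p_value for r in records])
    for rec, adj in zip(records, adjusted):
        rec.p_adjusted = float(adj)
    return records
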