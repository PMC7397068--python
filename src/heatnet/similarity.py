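"""Hypergeometric similarity between agent subnetwork gene sets.

Two gene regulatory subnetworks are called similar when their overlap is
improbably large under random sampling: with ``K`` genes in the query
network, ``N`` in the other, a population of ``M`` genes and observed
intersection ``x``, the score is the upper tail

    p = P(X >= x),   X ~ Hypergeometric(M, K, N)

Two population conventions are supported.  ``union`` takes M as the size
of the union of the two networks, which makes the test maximally
conservative (the overlap then never exceeds its null expectation);
``universe`` (default) takes M as the number of genes in the pruned PPI
network, the standard overlap-test background that can yield very small
p-values for strongly overlapping networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "SimilarityRecord",
    "hypergeometric_upper_tail",
    "compare_networks",
    "screen_library",
    "aggregate_disease_classes",
]

SIGNIFICANCE_THRESHOLD = 0.05


class SimilarityError(ValueError):
    pass


@dataclass
class SimilarityRecord:
    agent_a: str
    agent_b: str
    x: int       # intersection size
    K: int       # query network gene count
    N: int       # other network gene count
    M: int       # population size (mode dependent)
    p_value: float
    significant: bool
    rank: int | None = None
    top_k: bool = False


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_upper_tail(x: int, K: int, N: int, M: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(M, K, N), in log space.

    M: population size; K: marked items; N: draws; x: observed marked
    draws.  Summation runs over the attainable support and is carried in
    log space (gammaln + logsumexp), so deep tails far below float
    underflow of individual binomials remain accurate.
    """
    for name, v in (("x", x), ("K", K), ("N", N), ("M", M)):
        if int(v) != v:
            raise SimilarityError(f"{name} must be an integer, got {v}")
    x, K, N, M = int(x), int(K), int(N), int(M)
    if M < 0 or K < 0 or N < 0 or x < 0:
        raise SimilarityError("negative parameter")
    if K > M or N > M:
        raise SimilarityError(f"K={K} and N={N} must not exceed M={M}")
    if x > min(K, N):
        raise SimilarityError(f"x={x} exceeds min(K, N)={min(K, N)}")
    if x == 0:
        return 1.0
    i = np.arange(x, min(K, N) + 1)
    i = i[N - i <= M - K]  # attainable support only
    if i.size == 0:
        return 0.0
    log_pmf = _log_binom(K, i) + _log_binom(M - K, N - i) - _log_binom(M, N)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def compare_networks(
    genes_a: set[str],
    genes_b: set[str],
    population: str = "universe",
    universe_size: int | None = None,
    agent_a: str = "a",
    agent_b: str = "b",
) -> SimilarityRecord:
    """Overlap test between two subnetwork gene sets."""
    if not genes_a or not genes_b:
        raise SimilarityError("gene sets must be nonempty")
    x = len(genes_a & genes_b)
    K, N = len(genes_a), len(genes_b)
    union = len(genes_a | genes_b)
    if population == "union":
        M = union
    elif population == "universe":
        if universe_size is None:
            raise SimilarityError("universe mode requires universe_size")
        if universe_size < union:
            raise SimilarityError(
                f"universe_size={universe_size} smaller than union size {union}")
        M = int(universe_size)
    else:
        raise SimilarityError(f"unknown population mode {population!r}")
    p = hypergeometric_upper_tail(x, K, N, M)
    return SimilarityRecord(
        agent_a=agent_a, agent_b=agent_b, x=x, K=K, N=N, M=M,
        p_value=p, significant=p <= SIGNIFICANCE_THRESHOLD,
    )


def screen_library(
    query_agent: str,
    library: dict[str, set[str]],
    population: str = "universe",
    k: int = 20,
    universe_size: int | None = None,
    query_genes: set[str] | None = None,
) -> list[SimilarityRecord]:
    """Rank every library agent by similarity to the query.

    The query itself is excluded from the ranking.  Records are sorted
    ascending by p-value with ties broken by agent id; the first ``k``
    are flagged ``top_k``.
    """
    if k < 1:
        raise SimilarityError("k must be >= 1")
    if query_genes is None:
        if query_agent not in library:
            raise SimilarityError(f"query agent {query_agent!r} not in library")
        query_genes = library[query_agent]
    others = {a: g for a, g in library.items() if a != query_agent}
    if not others:
        raise SimilarityError("library holds no agents besides the query")
    records = [
        compare_networks(query_genes, genes, population, universe_size,
                         agent_a=query_agent, agent_b=agent)
        for agent, genes in others.items()
    ]
    records.sort(key=lambda r: (r.p_value, r.agent_b))
    for rank, rec in enumerate(records, start=1):
        rec.rank = rank
        rec.top_k = rank <= k
    return records


def aggregate_disease_classes(
    ranked: list[SimilarityRecord],
    indications: dict[str, set[str]],
    k: int,
) -> list[tuple[str, int]]:
    """Count distinct top-k agents per disease class.

    Each agent contributes once to every class it is annotated to;
    agents absent from the indication table fall into 'unannotated'.
    Sorted by count descending, then class name.
    """
    if k > len(ranked):
        raise SimilarityError(f"k={k} exceeds ranked list length {len(ranked)}")
    counts: dict[str, int] = {}
    for rec in ranked[:k]:
        classes = indications.get(rec.agent_b) or {"unannotated"}
        for cls in classes:
            counts[cls] = counts.get(cls, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
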