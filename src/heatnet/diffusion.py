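"""Insulated heat diffusion on a protein–protein interaction network.

The model is the random-walk-with-restart kernel popularised by HotNet2:
heat injected at a node diffuses along PPI edges, and at every step a
fraction ``beta`` (the insulation parameter) of the moving heat returns to
its source.  The stationary kernel is

    F = beta * (I - (1 - beta) * W)^{-1}

with ``W`` the column-normalised adjacency matrix.  The exchanged-heat
matrix ``E[i, j] = F[i, j] * h[j]`` records how much of source ``j``'s
initial heat ``h[j]`` ends up at node ``i``.  Thresholding ``E`` at
``delta`` defines a directed graph whose strongly connected components
are the reported subnetworks; ``delta`` itself is chosen so that no large
component arises from the same heat distribution placed at random on
degree-matched random networks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "DiffusionConfig",
    "DiffusionResult",
    "SubnetworkSet",
    "build_transition_matrix",
    "compute_diffusion_kernel",
    "exchanged_heat",
    "threshold_components",
    "permute_network",
    "select_delta",
    "DeltaSelector",
    "diffuse",
]


class DiffusionError(ValueError):
    """Raised for invalid diffusion inputs (isolated nodes, bad beta, ...)."""


@dataclass(frozen=True)
class PPINetwork:
    """Undirected simple PPI graph with a stable gene <-> index mapping.

    Nodes are gene symbols treated as opaque case-sensitive strings; the
    dense index order is the sorted node order, which makes every matrix
    built from the network reproducible.
    """

    graph: nx.Graph
    nodes: tuple[str, ...]
    index: dict[str, int]

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "PPINetwork":
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        g.add_edges_from((u, v) for u, v in graph.edges if u != v)
        nodes = tuple(sorted(g.nodes))
        return cls(graph=g, nodes=nodes, index={n: i for i, n in enumerate(nodes)})

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PPINetwork":
        g = nx.Graph()
        n_loops = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v)
        if n_loops:
            logger.info("dropped %d self-loop(s) from edge list", n_loops)
        return cls.from_graph(g)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> np.ndarray:
        return np.array([self.graph.degree(n) for n in self.nodes], dtype=float)

    def edge_set(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset((u, v)) for u, v in self.graph.edges)

    def prune(self, keep: set[str] | None = None) -> "PPINetwork":
        """Restrict to ``keep`` (if given) and drop isolated nodes.

        The diffusion transition matrix requires every node to have at
        least one neighbour, so isolated nodes must be removed first.
        """
        g = self.graph
        if keep is not None:
            dropped = set(g.nodes) - set(keep)
            if dropped:
                logger.info("pruning %d gene(s) absent from expression data", len(dropped))
            g = g.subgraph(set(g.nodes) & set(keep)).copy()
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        if isolated:
            logger.info("pruning %d isolated node(s)", len(isolated))
            g = g.copy()
            g.remove_nodes_from(isolated)
        return PPINetwork.from_graph(g)


@dataclass
class DiffusionConfig:
    """Parameters of one diffusion run.

    beta : restart (insulation) probability in (0, 1]; 0.4 is the
        conventional setting for PPI networks of this scale.
    delta_mode : 'fixed' (use ``delta_value``) or 'auto' (choose the
        smallest threshold keeping components small on degree-matched
        random networks).
    l_max : largest component size tolerated on random networks during
        auto delta selection.
    n_networks : number of permuted networks for auto selection.
    s_min : smallest component size reported as a subnetwork.
    n_swaps_factor : double-edge swaps per edge when permuting.
    """

    beta: float = 0.4
    delta_mode: str = "auto"
    delta_value: float | None = None
    l_max: int = 15
    n_networks: int = 20
    seed: int = 0
    s_min: int = 3
    n_swaps_factor: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise DiffusionError(f"beta must be in (0, 1], got {self.beta}")
        if self.delta_mode not in ("fixed", "auto"):
            raise DiffusionError(f"unknown delta mode {self.delta_mode!r}")
        if self.delta_mode == "fixed" and self.delta_value is None:
            raise DiffusionError("fixed delta mode requires delta_value")
        if self.l_max < 2:
            raise DiffusionError("l_max must be >= 2")
        if self.n_networks < 1:
            raise DiffusionError("n_networks must be >= 1")


@dataclass
class SubnetworkSet:
    """Strongly connected components of the delta-thresholded graph."""

    components: list[list[str]]
    delta: float

    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    def genes(self) -> set[str]:
        return {g for comp in self.components for g in comp}


@dataclass
class DiffusionResult:
    network: PPINetwork
    W: np.ndarray
    F: np.ndarray
    E: np.ndarray
    heat: np.ndarray
    beta: float
    delta: float
    subnetworks: SubnetworkSet


def build_transition_matrix(network: PPINetwork) -> np.ndarray:
    """Column-stochastic random-walk matrix W[i, j] = 1/deg(j) on edges."""
    deg = network.degrees()
    if network.n_nodes == 0:
        raise DiffusionError("empty network")
    if np.any(deg == 0):
        bad = [network.nodes[i] for i in np.nonzero(deg == 0)[0][:5]]
        raise DiffusionError(f"isolated node(s) present, prune first: {bad}")
    A = nx.to_numpy_array(network.graph, nodelist=list(network.nodes), dtype=float)
    return A / deg[np.newaxis, :]


def compute_diffusion_kernel(W: np.ndarray, beta: float) -> np.ndarray:
    """F = beta * (I - (1 - beta) W)^{-1}; columns sum to one.

    beta = 1 short-circuits to the exact identity (no diffusion).
    """
    if not 0.0 < beta <= 1.0:
        raise DiffusionError(f"beta must be in (0, 1], got {beta}")
    n = W.shape[0]
    if beta == 1.0:
        return np.eye(n)
    F = beta * np.linalg.solve(np.eye(n) - (1.0 - beta) * W, np.eye(n))
    return F


def exchanged_heat(F: np.ndarray, h: np.ndarray) -> np.ndarray:
    """E[i, j] = F[i, j] * h[j]: heat node i receives from source j."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise DiffusionError("heat vector must be nonnegative")
    if h.shape[0] != F.shape[1]:
        raise DiffusionError("heat vector length does not match kernel")
    return F * h[np.newaxis, :]


def _strong_component_labels(E: np.ndarray, delta: float) -> tuple[int, np.ndarray]:
    """Labels of strongly connected components of the graph j -> i iff E[i,j] >= delta."""
    mask = E >= delta
    np.fill_diagonal(mask, False)
    # adjacency[u, v] = edge u -> v; source j = column of E
    adj = csr_matrix(mask.T)
    return connected_components(adj, directed=True, connection="strong")


def _max_scc_size(E: np.ndarray, delta: float) -> int:
    n_comp, labels = _strong_component_labels(E, delta)
    return int(np.bincount(labels, minlength=n_comp).max())


def threshold_components(
    E: np.ndarray, delta: float, s_min: int, nodes: Sequence[str]
) -> SubnetworkSet:
    """Strongly connected components (size >= s_min) of the thresholded graph.

    The edge rule is inclusive (E >= delta), applied identically during
    delta selection and extraction.  Components are gene-sorted and
    ordered by (size desc, first gene id).
    """
    if delta < 0:
        raise DiffusionError("delta must be >= 0")
    n_comp, labels = _strong_component_labels(E, delta)
    counts = np.bincount(labels, minlength=n_comp)
    comps: list[list[str]] = []
    for lab in np.nonzero(counts >= s_min)[0]:
        members = sorted(nodes[i] for i in np.nonzero(labels == lab)[0])
        comps.append(members)
    comps.sort(key=lambda c: (-len(c), c[0]))
    return SubnetworkSet(components=comps, delta=float(delta))


def permute_network(
    network: PPINetwork, n_swaps: int, seed: int | np.random.Generator
) -> PPINetwork:
    """Degree-preserving randomisation by double-edge swaps.

    Each attempt picks two edges (a, b), (c, d) and rewires them to
    (a, d), (c, b); swaps that would create a self-loop or a duplicate
    edge are rejected.  Attempts are capped, so swap-free graphs (e.g. a
    triangle) are returned unchanged.
    """
    if n_swaps < 1:
        raise DiffusionError("n_swaps must be >= 1")
    if network.n_edges < 2:
        warnings.warn("fewer than 2 edges; returning network unchanged", stacklevel=2)
        return PPINetwork.from_graph(network.graph)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = [tuple(e) for e in network.graph.edges]
    edge_set = {frozenset(e) for e in edges}
    n_edges = len(edges)
    successes = 0
    attempts = 0
    max_attempts = max(100, 20 * n_swaps)
    while successes < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):
            c, d = d, c
        # proposed rewiring: (a, b), (c, d) -> (a, d), (c, b)
        if a == d or c == b:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = (a, d)
        edges[j] = (c, b)
        successes += 1
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(edges)
    return PPINetwork.from_graph(g)


class DeltaSelector:
    """Chooses delta from degree-matched random networks.

    The permuted networks and their diffusion kernels depend only on the
    PPI graph and beta, so they are computed once and reused across
    agents; only the (cheap) heat assignment and threshold search are
    per-agent.
    """

    def __init__(self, network: PPINetwork, config: DiffusionConfig):
        self.network = network
        self.config = config
        self._kernels: list[np.ndarray] | None = None

    def _ensure_kernels(self) -> list[np.ndarray]:
        if self._kernels is None:
            cfg = self.config
            n_swaps = max(1, cfg.n_swaps_factor * self.network.n_edges)
            rng = np.random.default_rng(cfg.seed)
            kernels = []
            for _ in range(cfg.n_networks):
                perm = permute_network(self.network, n_swaps, rng)
                W = build_transition_matrix(perm)
                kernels.append(compute_diffusion_kernel(W, cfg.beta))
            self._kernels = kernels
        return self._kernels

    @staticmethod
    def _min_delta(E: np.ndarray, l_max: int) -> float:
        """Smallest candidate delta with max SCC size <= l_max.

        Candidates are the sorted unique off-diagonal entries of E; the
        max SCC size is nonincreasing in delta, so a binary search over
        candidates finds the leftmost feasible one.
        """
        off = E[~np.eye(E.shape[0], dtype=bool)]
        cand = np.unique(off)
        lo, hi = 0, len(cand) - 1
        if _max_scc_size(E, cand[hi]) > l_max:
            # even the sparsest nontrivial graph is too connected
            return float(np.nextafter(cand[hi], np.inf))
        while lo < hi:
            mid = (lo + hi) // 2
            if _max_scc_size(E, cand[mid]) <= l_max:
                hi = mid
            else:
                lo = mid + 1
        return float(cand[lo])

    def select(self, heat_pool: np.ndarray, seed: int) -> float:
        cfg = self.config
        heat_pool = np.asarray(heat_pool, dtype=float)
        if cfg.l_max >= self.network.n_nodes:
            warnings.warn("l_max >= node count; delta constraint vacuous, using 0",
                          stacklevel=2)
            return 0.0
        rng = np.random.default_rng(seed)
        minima = []
        for F in self._ensure_kernels():
            h = rng.permutation(heat_pool)
            E = exchanged_heat(F, h)
            minima.append(self._min_delta(E, cfg.l_max))
        return float(median(minima))


def select_delta(
    network: PPINetwork, heat_pool: np.ndarray, config: DiffusionConfig
) -> float:
    """Median over permuted networks of the smallest component-limiting delta."""
    return DeltaSelector(network, config).select(heat_pool, config.seed)


def diffuse(
    network: PPINetwork,
    heat: dict[str, float] | np.ndarray,
    config: DiffusionConfig,
    selector: DeltaSelector | None = None,
    delta_seed: int | None = None,
) -> DiffusionResult:
    """Full single-agent diffusion: W, F, E, delta, subnetworks."""
    if isinstance(heat, dict):
        h = np.array([heat.get(g, 0.0) for g in network.nodes], dtype=float)
    else:
        h = np.asarray(heat, dtype=float)
    W = build_transition_matrix(network)
    F = compute_diffusion_kernel(W, config.beta)
    if config.delta_mode == "fixed":
        delta = float(config.delta_value)  # type: ignore[arg-type]
    else:
        sel = selector if selector is not None else DeltaSelector(network, config)
        delta = sel.select(h, config.seed if delta_seed is None else delta_seed)
    E = exchanged_heat(F, h)
    subnets = threshold_components(E, delta, config.s_min, network.nodes)
    return DiffusionResult(
        network=network, W=W, F=F, E=E, heat=h, beta=config.beta,
        delta=delta, subnetworks=subnets,
    )
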