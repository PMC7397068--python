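"""Synthetic inputs: PPI graph, planted modules, expression, GMT, indications.

The generator emulates the structure of agent-vs-control microarray
screens on a protein interaction network so that every pipeline stage
can be exercised, and recovery benchmarked, without external downloads:

* a preferential-attachment (scale-free) PPI graph;
* a connected "hot" module of genes whose treated-sample mean is a
  multiple ``phi`` of the control mean (all other genes unaffected);
* log-normal control expression with multiplicative replicate noise and
  1-3 probes per gene carrying fixed probe-specific factors, so the
  max-per-gene probe collapse is exercised nontrivially;
* an agent library whose modules share a controlled number of genes
  with a designated query agent, plus matching GMT sets with random
  decoys, and an indication table whose class labels track module
  identity.

At zero replicate noise a module gene's merged score has the closed
form a = 2(phi - 1)/(phi + 1): probe factors multiply test and control
alike and cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffusion import PPINetwork
from .io import (
    GeneSet,
    GeneSetCollection,
    IndicationTable,
    SampleMeta,
    write_edge_list,
    write_expression_tsv,
    write_gmt,
    write_indications,
    write_probe_map,
)

__all__ = [
    "SimulationScenario", "SyntheticLibrary",
    "generate_ppi", "plant_module", "generate_profiles",
    "generate_agent_library", "write_library",
]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic experiment.

    Defaults mirror a desk-scale version of a connectivity-map style
    screen: 500 network genes, a planted module of 20, a five-fold
    expression effect, 10% replicate noise (CV), three replicates per
    group, and 1-3 probes per gene.
    """

    n_genes: int = 500
    m_attach: int = 2                 # edges per new node (preferential attachment)
    k_module: int = 20
    phi: float = 5.0                  # test mean = phi x control mean on module genes
    mu_log: float = math.log(100.0)   # log-normal control-mean location
    sigma_log: float = 0.5            # log-normal control-mean scale
    cv: float = 0.1                   # replicate noise coefficient of variation
    n_replicates: int = 3             # per role (test and control)
    probes_per_gene: tuple[int, int] = (1, 3)
    n_conditions: int = 1
    n_agents: int = 1
    # overlap of each non-query agent's module with the query module,
    # length n_agents - 1; None -> all disjoint from the query
    overlaps: list[int] | None = None
    n_decoy_sets: int = 49
    decoy_size_range: tuple[int, int] = (10, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_module >= self.n_genes:
            raise SimulationError("k_module must be < n_genes")
        if self.phi <= 1:
            raise SimulationError("phi must be > 1")
        if min(self.n_genes, self.m_attach, self.k_module,
               self.n_replicates, self.n_agents, self.n_conditions) < 1:
            raise SimulationError("all counts must be >= 1")
        if self.overlaps is not None:
            if len(self.overlaps) != self.n_agents - 1:
                raise SimulationError("overlaps must have length n_agents - 1")
            if any(o < 0 or o > self.k_module for o in self.overlaps):
                raise SimulationError("overlap counts must lie in [0, k_module]")


@dataclass
class SyntheticLibrary:
    """A fully realised synthetic screen."""

    scenario: SimulationScenario
    network: PPINetwork
    modules: dict[str, frozenset[str]]       # agent -> planted module
    query_agent: str
    expression: pd.DataFrame                 # probes x all samples
    samples: list[SampleMeta]
    probe_map: pd.DataFrame
    gene_sets: GeneSetCollection
    indications: IndicationTable

    def bundle(self, agent_id: str):
        """ExpressionBundle view of one agent's samples."""
        from .io import ExpressionBundle

        metas = [m for m in self.samples if m.agent_id == agent_id]
        if not metas:
            raise KeyError(agent_id)
        cols = [m.sample_id for m in metas]
        return ExpressionBundle(agent_id=agent_id,
                                values=self.expression[cols], samples=metas)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_ppi(n: int, m: int, seed: int) -> PPINetwork:
    """Connected simple preferential-attachment graph with named genes."""
    if not n > m >= 1:
        raise SimulationError("need n > m >= 1")
    g = nx.barabasi_albert_graph(n, m, seed=int(seed))
    relabeled = nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})
    return PPINetwork.from_graph(relabeled)


def plant_module(
    network: PPINetwork, k: int, seed: int | np.random.Generator,
    allowed: set[str] | None = None, start: str | None = None,
) -> frozenset[str]:
    """Connected induced subgraph of size k grown by randomised BFS.

    ``allowed`` restricts growth (and the random start) to a node
    subset; raises if no connected module of size k fits.
    """
    if k > network.n_nodes:
        raise SimulationError("module size exceeds node count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = set(network.nodes) if allowed is None else set(allowed) & set(network.nodes)
    if start is None:
        candidates = sorted(pool)
        if not candidates:
            raise SimulationError("no allowed start node")
        start = candidates[rng.integers(0, len(candidates))]
    module = {start}
    frontier = sorted(set(network.graph.neighbors(start)) & pool - module)
    while len(module) < k:
        if not frontier:
            raise SimulationError(
                f"cannot grow a connected module of size {k} from {start!r}")
        nxt = frontier.pop(rng.integers(0, len(frontier)))
        module.add(nxt)
        frontier = sorted(
            (set(frontier) | set(network.graph.neighbors(nxt)) & pool) - module)
    return frozenset(module)


def _build_probe_map(genes: list[str], scenario: SimulationScenario,
                     rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = scenario.probes_per_gene
    rows = []
    for g in genes:
        n_probes = int(rng.integers(lo, hi + 1))
        for p in range(1, n_probes + 1):
            rows.append((f"{g}_p{p}", g))
    return pd.DataFrame(rows, columns=["probe_id", "gene_id"])


def generate_profiles(
    scenario: SimulationScenario,
    module: frozenset[str],
    rng: np.random.Generator,
    agent_id: str = "agent",
    genes: list[str] | None = None,
    probe_map: pd.DataFrame | None = None,
    control_means: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list[SampleMeta], pd.DataFrame]:
    """Replicate expression matrices for one agent.

    Control replicate values are log-normal gene means times a fixed
    probe factor (uniform 0.8-1.2) times multiplicative noise
    (normal(1, cv), truncated at 0); test values additionally carry the
    phi-fold effect on module genes.  Returns (values, metadata,
    probe_map); pass ``genes``/``probe_map``/``control_means`` to share
    them across a library.
    """
    if genes is None:
        genes = [_gene_name(i) for i in range(scenario.n_genes)]
    if probe_map is None:
        probe_map = _build_probe_map(genes, scenario, rng)
    if control_means is None:
        control_means = rng.lognormal(scenario.mu_log, scenario.sigma_log,
                                      size=len(genes))
    mean_of = dict(zip(genes, control_means))
    probe_factor = rng.uniform(0.8, 1.2, size=len(probe_map))

    probe_gene = probe_map["gene_id"].to_numpy()
    base = np.array([mean_of[g] for g in probe_gene]) * probe_factor
    effect = np.where(np.isin(probe_gene, list(module)), scenario.phi, 1.0)

    cols: dict[str, np.ndarray] = {}
    samples: list[SampleMeta] = []
    for cond in range(1, scenario.n_conditions + 1):
        cond_id = f"cond{cond}"
        for role, mult in (("control", np.ones_like(effect)), ("test", effect)):
            for rep in range(1, scenario.n_replicates + 1):
                sid = f"{agent_id}.{cond_id}.{role}{rep}"
                noise = (rng.normal(1.0, scenario.cv, size=len(base))
                         if scenario.cv > 0 else np.ones(len(base)))
                cols[sid] = np.maximum(base * mult * noise, 0.0)
                samples.append(SampleMeta(sid, agent_id, cond_id, role))
    values = pd.DataFrame(cols, index=pd.Index(probe_map["probe_id"], name="probe_id"))
    return values, samples, probe_map


def _module_with_overlap(
    network: PPINetwork, query_module: frozenset[str], overlap: int, k: int,
    rng: np.random.Generator, forbidden: set[str],
) -> frozenset[str]:
    """Connected module of size k sharing exactly ``overlap`` genes with the query.

    Grown from a connected seed inside the query module (when overlap > 0),
    then extended only through genes outside the query module and outside
    ``forbidden``.  Retries with fresh seeds before giving up.
    """
    outside = set(network.nodes) - set(query_module) - forbidden
    for _ in range(50):
        try:
            if overlap == 0:
                return plant_module(network, k, rng, allowed=outside)
            seed_set = plant_module(network, overlap, rng,
                                    allowed=set(query_module))
            module = set(seed_set)
            frontier = sorted(
                {nb for g in module for nb in network.graph.neighbors(g)}
                & outside - module)
            while len(module) < k:
                if not frontier:
                    raise SimulationError("stuck")
                nxt = frontier.pop(rng.integers(0, len(frontier)))
                module.add(nxt)
                frontier = sorted(
                    (set(frontier) | set(network.graph.neighbors(nxt)) & outside)
                    - module)
            return frozenset(module)
        except SimulationError:
            continue
    raise SimulationError(
        f"infeasible overlap design: overlap={overlap}, k={k}")


def generate_agent_library(scenario: SimulationScenario) -> SyntheticLibrary:
    """Multi-agent screen with controlled module overlap versus the query.

    Agent 0 (id ``A000``) is the query; agent i > 0 shares
    ``scenario.overlaps[i-1]`` genes with the query module (0 by
    default).  Zero-overlap modules are also grown disjoint from the
    query module.  One GMT set is emitted per module plus
    ``n_decoy_sets`` random decoys; the indication table labels
    query-overlapping agents with class ``shared_mechanism`` and the
    rest with rotating decoy classes.
    """
    rng = np.random.default_rng(scenario.seed)
    network = generate_ppi(scenario.n_genes, scenario.m_attach, scenario.seed)
    genes = list(network.nodes)
    overlaps = scenario.overlaps or [0] * (scenario.n_agents - 1)

    agent_ids = [f"A{i:03d}" for i in range(scenario.n_agents)]
    query = agent_ids[0]
    modules: dict[str, frozenset[str]] = {
        query: plant_module(network, scenario.k_module, rng)}
    for aid, ov in zip(agent_ids[1:], overlaps):
        modules[aid] = _module_with_overlap(
            network, modules[query], ov, scenario.k_module, rng, forbidden=set())

    probe_map = _build_probe_map(genes, scenario, rng)
    control_means = rng.lognormal(scenario.mu_log, scenario.sigma_log,
                                  size=len(genes))
    frames, samples = [], []
    for aid in agent_ids:
        vals, metas, _ = generate_profiles(
            scenario, modules[aid], rng, agent_id=aid, genes=genes,
            probe_map=probe_map, control_means=control_means)
        frames.append(vals)
        samples.extend(metas)
    expression = pd.concat(frames, axis=1)

    sets = [GeneSet(set_id=f"MOD_{aid}", description=f"planted module of {aid}",
                    members=modules[aid]) for aid in agent_ids]
    lo, hi = scenario.decoy_size_range
    for d in range(scenario.n_decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        sets.append(GeneSet(set_id=f"DECOY_{d:03d}",
                            description="random decoy set", members=members))
    gene_sets = GeneSetCollection(sets=sets)

    decoy_classes = ["metabolic", "neurologic", "dermatologic"]
    rows = [(query, "shared_mechanism")]
    for i, (aid, ov) in enumerate(zip(agent_ids[1:], overlaps)):
        cls = "shared_mechanism" if ov > 0 else decoy_classes[i % len(decoy_classes)]
        rows.append((aid, cls))
    indications = IndicationTable(rows=rows)

    return SyntheticLibrary(
        scenario=scenario, network=network, modules=modules, query_agent=query,
        expression=expression, samples=samples, probe_map=probe_map,
        gene_sets=gene_sets, indications=indications)


def write_library(library: SyntheticLibrary, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input format for a library; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "samples.tsv",
        "probe_map": out / "probe_map.tsv",
        "ppi": out / "ppi_edges.tsv",
        "gmt": out / "gene_sets.gmt",
        "indications": out / "indications.tsv",
        "modules": out / "true_modules.json",
    }
    write_expression_tsv(library.expression, library.samples,
                         paths["expression"], paths["metadata"])
    write_probe_map(library.probe_map, paths["probe_map"])
    write_edge_list(library.network, paths["ppi"])
    write_gmt(library.gene_sets, paths["gmt"])
    write_indications(library.indications, paths["indications"])
    import json
    with open(paths["modules"], "w", encoding="utf-8") as fh:
        json.dump({a: sorted(m) for a, m in library.modules.items()}, fh, indent=1)
    return paths
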