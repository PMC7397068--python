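"""End-to-end orchestration: files in, result tables out.

A run is fully described by a configuration mapping (usually a YAML
file) naming the input paths and all numeric parameters, plus one seed.
The run manifest written next to the results records everything needed
to reproduce them; two runs with equal manifests produce byte-identical
result tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .diffusion import DeltaSelector, DiffusionConfig, diffuse
from .enrichment import enrich
from .io import (
    read_edge_list,
    read_expression_tsv,
    read_gmt,
    read_indications,
    read_probe_map,
    write_enrichment_tsv,
    write_class_counts_tsv,
    write_similarity_tsv,
    write_subnetworks_json,
)
from .preprocess import (
    build_heat_vector,
    collapse_conditions,
    merge_replicates,
    probes_to_genes,
)
from .reporting import write_report
from .significance import significance_test
from .similarity import aggregate_disease_classes, screen_library

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "PipelineError", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


def preprocess_bundle(bundle, probe_map, n_top: int, mode: str = "both"):
    """One agent's preprocessing chain: merge, collapse, map, select.

    Returns (HeatVector, GeneScores).
    """
    per_condition = [
        merge_replicates(bundle.test_matrix(c), bundle.control_matrix(c))
        for c in bundle.conditions()
    ]
    collapsed = collapse_conditions(per_condition)
    gene_scores = probes_to_genes(collapsed, probe_map)
    return build_heat_vector(gene_scores, n_top, mode=mode), gene_scores


DEFAULT_PARAMS = {
    "n_top": 25,
    "heat_mode": "both",
    "beta": 0.4,
    "delta_mode": "auto",
    "delta_value": None,
    "l_max": 15,
    "n_networks": 20,
    "n_swaps_factor": 10,
    "s_min": 3,
    "s_values": None,       # default: adaptive (largest observed component size)
    "n_perm": 99,
    "population": "universe",
    "top_k": 20,
    "query_agent": None,    # default: first agent in sorted order
    "seed": 0,
}


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _validate_config(config: dict) -> tuple[dict, dict]:
    if "inputs" not in config:
        raise ConfigError("config missing 'inputs' section")
    inputs = config["inputs"]
    for key in ("expression", "metadata", "probe_map", "ppi"):
        if key not in inputs:
            raise ConfigError(f"config missing required input path {key!r}")
        if not Path(inputs[key]).exists():
            raise ConfigError(f"input file not found: {inputs[key]}")
    for key in ("gmt", "indications"):
        if inputs.get(key) and not Path(inputs[key]).exists():
            raise ConfigError(f"input file not found: {inputs[key]}")
    params = dict(DEFAULT_PARAMS)
    unknown = set(config.get("params", {})) - set(DEFAULT_PARAMS)
    if unknown:
        raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
    params.update(config.get("params", {}))
    if "output_dir" not in config:
        raise ConfigError("config missing 'output_dir'")
    return inputs, params


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: dict) -> Path:
    """Execute every stage and write the results directory.

    Outputs: ``subnetworks.json``, ``similarity.tsv``, ``enrichment.tsv``
    (when a GMT is configured), ``class_counts.tsv`` (when indications
    are configured), ``report.json`` and ``manifest.json``.
    """
    inputs, params = _validate_config(config)
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read-inputs"):
        network = read_edge_list(inputs["ppi"])
        bundles = read_expression_tsv(inputs["expression"], inputs["metadata"])
        probe_map = read_probe_map(inputs["probe_map"])
        gene_sets = read_gmt(inputs["gmt"]) if inputs.get("gmt") else None
        indications = (read_indications(inputs["indications"])
                       if inputs.get("indications") else None)

    agents = sorted(bundles)
    # independent integer seeds per stochastic stage, all derived from one seed
    state = np.random.SeedSequence(int(params["seed"])).generate_state(
        2 + 2 * len(agents), dtype=np.uint32)
    seeds = [int(s) % (2**31) for s in state]

    with _stage("preprocess"):
        heats = {}
        scores = {}
        for agent in agents:
            heats[agent], scores[agent] = preprocess_bundle(
                bundles[agent], probe_map, int(params["n_top"]),
                mode=params["heat_mode"])

    with _stage("prune-network"):
        expressed = set(scores[agents[0]].scores.index)
        network = network.prune(expressed)
        logger.info("pruned network: %d nodes, %d edges",
                    network.n_nodes, network.n_edges)

    diff_cfg = DiffusionConfig(
        beta=float(params["beta"]),
        delta_mode=params["delta_mode"],
        delta_value=params["delta_value"],
        l_max=int(params["l_max"]),
        n_networks=int(params["n_networks"]),
        seed=seeds[0],
        s_min=int(params["s_min"]),
        n_swaps_factor=int(params["n_swaps_factor"]),
    )
    selector = DeltaSelector(network, diff_cfg) if params["delta_mode"] == "auto" else None

    s_values = params["s_values"]
    entries = []
    results = {}
    with _stage("diffuse-and-test"):
        for i, agent in enumerate(agents):
            res = diffuse(network, heats[agent].as_dict(), diff_cfg,
                          selector=selector, delta_seed=seeds[1 + 2 * i])
            report = significance_test(
                network, res.heat, res.delta, s_values,
                int(params["n_perm"]), seeds[2 + 2 * i],
                s_min=diff_cfg.s_min, F=res.F)
            results[agent] = (res, report)
            entries.append({
                "agent_id": agent,
                "beta": res.beta,
                "delta": res.delta,
                "components": [
                    {"genes": comp, "p_value": p}
                    for comp, p in zip(res.subnetworks.components,
                                       report.component_p)
                ],
                "significance": report.as_dict(),
            })
        write_subnetworks_json(entries, out / "subnetworks.json")

    with _stage("similarity"):
        library = {a: results[a][0].subnetworks.genes() for a in agents}
        library = {a: g for a, g in library.items() if g}
        query = params["query_agent"] or agents[0]
        ranked = []
        class_counts = None
        if query in library and len(library) > 1:
            ranked = screen_library(
                query, library, population=params["population"],
                k=int(params["top_k"]), universe_size=network.n_nodes)
            write_similarity_tsv(ranked, out / "similarity.tsv")
            if indications is not None:
                class_counts = aggregate_disease_classes(
                    ranked, indications.classes_of(),
                    min(int(params["top_k"]), len(ranked)))
                write_class_counts_tsv(class_counts, out / "class_counts.tsv")
        else:
            logger.warning("similarity skipped: query %r empty or library too small",
                           query)
            write_similarity_tsv([], out / "similarity.tsv")

    with _stage("enrichment"):
        if gene_sets is not None:
            query = params["query_agent"] or agents[0]
            query_genes = results[query][0].subnetworks.genes()
            if query_genes:
                records = enrich(query_genes, gene_sets, set(network.nodes))
                write_enrichment_tsv(records, out / "enrichment.tsv")
            else:
                logger.warning("enrichment skipped: query subnetwork empty")
                write_enrichment_tsv([], out / "enrichment.tsv")

    with _stage("report"):
        largest = {a: (max(res.subnetworks.sizes()) if res.subnetworks.sizes() else 0)
                   for a, (res, rep) in results.items() if rep.significant}
        write_report(out, largest, ranked or None, class_counts)

    with _stage("manifest"):
        manifest = {
            "version": __version__,
            "inputs": {k: str(v) for k, v in inputs.items()},
            "params": params,
            "derived_seeds": seeds,
            "agents": agents,
            "network": {"nodes": network.n_nodes, "edges": network.n_edges},
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    return out
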