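"""Readers and writers for the on-disk formats of the pipeline.

All files are UTF-8 and tab-delimited.  Gene and probe identifiers are
opaque, case-sensitive strings; no symbol normalisation happens here.

Formats
-------
expression matrix   header ``probe_id`` + one column per sample id
sample metadata     columns sample_id, agent_id, condition_id, role
probe map           columns probe_id, gene_id
PPI edge list       two whitespace-delimited gene symbols per line,
                    ``#`` comments allowed
GMT                 one gene set per line: id, description, members
indications         columns agent_id, disease_class
heat vector         columns gene_id, score, heat, direction
subnetworks JSON    {agent_id, beta, delta, components, significance}
similarity TSV      agent_a, agent_b, x, K, N, M, p_value, significant
enrichment TSV      set_id, overlap, set_size, query_size,
                    universe_size, p_value, p_adjusted
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import PPINetwork
from .preprocess import HeatVector

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError", "SampleMeta", "ExpressionBundle", "GeneSet",
    "GeneSetCollection", "IndicationTable",
    "read_expression_tsv", "write_expression_tsv",
    "read_probe_map", "write_probe_map",
    "read_edge_list", "write_edge_list",
    "read_gmt", "write_gmt",
    "read_indications", "write_indications",
    "read_heat_tsv", "write_heat_tsv",
    "write_subnetworks_json", "read_subnetworks_json",
    "write_similarity_tsv", "write_enrichment_tsv", "write_class_counts_tsv",
]

FLOAT_FORMAT = "%.10g"


class ParseError(ValueError):
    """A named, located failure while parsing an input file."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    agent_id: str
    condition_id: str
    role: str  # 'test' | 'control'


@dataclass
class ExpressionBundle:
    """Probe-level test/control replicate matrices for one agent."""

    agent_id: str
    values: pd.DataFrame          # probes x samples, row order preserved
    samples: list[SampleMeta]

    def conditions(self) -> list[str]:
        return sorted({s.condition_id for s in self.samples})

    def _cols(self, condition_id: str, role: str) -> list[str]:
        return [s.sample_id for s in self.samples
                if s.condition_id == condition_id and s.role == role]

    def test_matrix(self, condition_id: str) -> pd.DataFrame:
        return self.values[self._cols(condition_id, "test")]

    def control_matrix(self, condition_id: str) -> pd.DataFrame:
        return self.values[self._cols(condition_id, "control")]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ParseError("duplicate set id in gene set collection")
        for s in self.sets:
            if not s.members:
                raise ParseError(f"gene set {s.set_id!r} has no members")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def by_id(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


@dataclass
class IndicationTable:
    """Unique (agent_id, disease_class) pairs; agents may map to many classes."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) != len(set(self.rows)):
            raise ParseError("duplicate (agent, class) pair in indication table")

    def classes_of(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for agent, cls in self.rows:
            out.setdefault(agent, set()).add(cls)
        return out


# --------------------------------------------------------------------------
# expression matrices + metadata


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "agent_id", "condition_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"metadata file missing column(s): {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ParseError("duplicate sample_id in metadata")
    bad = set(df["role"]) - {"test", "control"}
    if bad:
        raise ParseError(f"unknown role value(s): {sorted(bad)}")
    metas = [SampleMeta(r.sample_id, r.agent_id, r.condition_id, r.role)
             for r in df.itertuples()]
    # every condition with a test sample needs at least one control sample
    for agent in {m.agent_id for m in metas}:
        per = [m for m in metas if m.agent_id == agent]
        for cond in {m.condition_id for m in per if m.role == "test"}:
            if not any(m.condition_id == cond and m.role == "control" for m in per):
                raise ParseError(
                    f"agent {agent!r} condition {cond!r} has test but no control samples")
    return metas


def read_expression_tsv(
    path: str | Path, meta_path: str | Path
) -> dict[str, ExpressionBundle]:
    """Partition one probe x sample matrix into per-agent bundles."""
    metas = read_sample_meta(meta_path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[0] == 0:
        raise ParseError(f"no probes in expression matrix {path}")
    if df.columns[0] != "probe_id":
        raise ParseError("first column of expression matrix must be 'probe_id'")
    df = df.set_index("probe_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate probe id {dup!r}")
    for m in metas:
        if m.sample_id not in df.columns:
            raise ParseError(f"sample column {m.sample_id!r} missing from matrix")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        raise ParseError(f"non-numeric value(s) in column {non_numeric[0]!r}")
    logger.info("read %d probes x %d samples", df.shape[0], df.shape[1])
    bundles: dict[str, ExpressionBundle] = {}
    for agent in sorted({m.agent_id for m in metas}):
        per = [m for m in metas if m.agent_id == agent]
        cols = [m.sample_id for m in per]
        bundles[agent] = ExpressionBundle(
            agent_id=agent, values=df[cols].astype(float), samples=per)
    return bundles


def write_expression_tsv(
    values: pd.DataFrame, samples: list[SampleMeta],
    path: str | Path, meta_path: str | Path,
) -> None:
    out = values.copy()
    out.insert(0, "probe_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    meta = pd.DataFrame(
        [(m.sample_id, m.agent_id, m.condition_id, m.role) for m in samples],
        columns=["sample_id", "agent_id", "condition_id", "role"])
    meta.to_csv(meta_path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ParseError("probe map needs columns probe_id, gene_id")
    return df[["probe_id", "gene_id"]]


def write_probe_map(probe_map: pd.DataFrame, path: str | Path) -> None:
    probe_map.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# PPI edge list


def read_edge_list(path: str | Path) -> PPINetwork:
    """Undirected simple graph from a two-column edge list.

    Self-loops are dropped (count logged); duplicate edges collapse.
    """
    edges: list[tuple[str, str]] = []
    n_loops = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tokens, got {len(tokens)}")
            u, v = tokens
            if u == v:
                n_loops += 1
                continue
            edges.append((u, v))
    if n_loops:
        logger.info("dropped %d self-loop(s) in %s", n_loops, path)
    net = PPINetwork.from_edges(edges)
    logger.info("read PPI network: %d nodes, %d edges", net.n_nodes, net.n_edges)
    return net


def write_edge_list(network: PPINetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{u}\t{v}\n")


# --------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has < 3 fields")
            set_id, desc = fields[0], fields[1]
            if set_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            seen.add(set_id)
            members = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(set_id=set_id, description=desc, members=members))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


# --------------------------------------------------------------------------
# indications


def read_indications(path: str | Path) -> IndicationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"agent_id", "disease_class"} <= set(df.columns):
        raise ParseError("indication table needs columns agent_id, disease_class")
    return IndicationTable(rows=[(r.agent_id, r.disease_class) for r in df.itertuples()])


def write_indications(table: IndicationTable, path: str | Path) -> None:
    pd.DataFrame(table.rows, columns=["agent_id", "disease_class"]).to_csv(
        path, sep="\t", index=False)


# --------------------------------------------------------------------------
# heat vectors and result tables


def write_heat_tsv(heat: HeatVector, scores: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({
        "gene_id": heat.heat.index,
        "score": scores.reindex(heat.heat.index).to_numpy(),
        "heat": heat.heat.to_numpy(),
        "direction": [heat.direction.get(g, "none") for g in heat.heat.index],
    })
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_heat_tsv(path: str | Path) -> HeatVector:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    heat = pd.Series(df["heat"].to_numpy(float), index=df["gene_id"])
    direction = {g: d for g, d in zip(df["gene_id"], df["direction"]) if d != "none"}
    return HeatVector(heat=heat, selected=set(direction), direction=direction)


def write_subnetworks_json(entries: list[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(entries, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_subnetworks_json(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_similarity_tsv(records, path: str | Path) -> None:
    df = pd.DataFrame([
        {"agent_a": r.agent_a, "agent_b": r.agent_b, "x": r.x, "K": r.K,
         "N": r.N, "M": r.M, "p_value": r.p_value,
         "significant": str(r.significant)}
        for r in records
    ], columns=["agent_a", "agent_b", "x", "K", "N", "M", "p_value", "significant"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6e")


def write_enrichment_tsv(records, path: str | Path) -> None:
    df = pd.DataFrame([
        {"set_id": r.set_id, "overlap": r.overlap, "set_size": r.set_size,
         "query_size": r.query_size, "universe_size": r.universe_size,
         "p_value": r.p_value, "p_adjusted": r.p_adjusted}
        for r in records
    ], columns=["set_id", "overlap", "set_size", "query_size",
                "universe_size", "p_value", "p_adjusted"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6e")


def write_class_counts_tsv(counts: list[tuple[str, int]], path: str | Path) -> None:
    pd.DataFrame(counts, columns=["disease_class", "agent_count"]).to_csv(
        path, sep="\t", index=False)
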