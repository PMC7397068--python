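"""Result summaries: subnetwork size distribution, top-k similarity, classes.

Reports are pure views over stored results; regenerating a report from
the same results is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .similarity import SimilarityRecord

__all__ = ["size_histogram", "top_k_table", "write_report"]


def size_histogram(sizes: Sequence[int], bin_edges: Sequence[float]) -> dict:
    """Left-closed right-open histogram with a single overflow bucket.

    ``bin_edges`` must be strictly increasing; sizes outside every
    [edge_i, edge_{i+1}) bin land in the overflow count, so the total is
    conserved.
    """
    edges = list(bin_edges)
    if any(b >= a for b, a in zip(edges, edges[1:])) or len(edges) < 2:
        raise ValueError("bin edges must be strictly increasing (>= 2 edges)")
    counts = [0] * (len(edges) - 1)
    overflow = 0
    for s in sizes:
        for i in range(len(edges) - 1):
            if edges[i] <= s < edges[i + 1]:
                counts[i] += 1
                break
        else:
            overflow += 1
    return {
        "bins": [[edges[i], edges[i + 1]] for i in range(len(edges) - 1)],
        "counts": counts,
        "overflow": overflow,
        "total": len(sizes),
    }


def top_k_table(ranked: list[SimilarityRecord], k: int) -> list[dict]:
    """First k rows of a ranked similarity list, p in scientific notation."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranked):
        warnings.warn(f"k={k} exceeds list length {len(ranked)}; returning all",
                      stacklevel=2)
        k = len(ranked)
    return [{"rank": r.rank, "agent": r.agent_b, "p_value": f"{r.p_value:.6e}"}
            for r in ranked[:k]]


def write_report(
    out_dir: str | Path,
    largest_sizes: dict[str, int],
    ranked: list[SimilarityRecord] | None,
    class_counts: list[tuple[str, int]] | None,
    bin_edges: Sequence[float] = (3, 10, 25, 50, 150, 500),
    k: int = 20,
) -> Path:
    """report.json plus TSV views in the results directory."""
    out = Path(out_dir)
    report: dict = {
        "size_histogram": size_histogram(list(largest_sizes.values()), bin_edges),
        "largest_component_size": dict(sorted(largest_sizes.items())),
    }
    if ranked:
        table = top_k_table(ranked, min(k, len(ranked)))
        report["top_similar_agents"] = table
        pd.DataFrame(table).to_csv(out / "top_similar.tsv", sep="\t", index=False)
    if class_counts is not None:
        report["disease_class_counts"] = [
            {"disease_class": c, "agent_count": n} for c, n in class_counts]
    path = out / "report.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path
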