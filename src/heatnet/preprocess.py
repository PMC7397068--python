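"""Expression signatures: replicate merge, condition collapse, gene heat.

A treated-vs-control contrast per probe is the symmetrised relative
change ``a = (t - c) / ((t + c) / 2)`` with ``t`` and ``c`` the replicate
means of the test and control groups.  For nonnegative expression values
``a`` is bounded in [-2, 2], antisymmetric in (t, c), and zero when the
groups agree.  Probe scores are collapsed across experimental conditions
by the per-probe median, then to genes by keeping the probe with the
largest absolute score (sign retained), and finally the strongest up-
and downregulated genes receive nonnegative heat ``|a|`` for diffusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneScores",
    "HeatVector",
    "merge_replicates",
    "collapse_conditions",
    "probes_to_genes",
    "build_heat_vector",
]


class PreprocessError(ValueError):
    pass


@dataclass
class GeneScores:
    """Per-gene signed score plus the probe that supplied it."""

    scores: pd.Series  # index: gene_id, values: signed score
    winning_probe: dict[str, str]


@dataclass
class HeatVector:
    """Nonnegative per-gene heat with up/down provenance.

    ``heat`` covers every gene seen upstream; unselected genes carry 0
    so they can relay diffused heat without emitting any.
    """

    heat: pd.Series  # index: gene_id, values: h >= 0
    selected: set[str] = field(default_factory=set)
    direction: dict[str, str] = field(default_factory=dict)  # gene -> 'up'|'down'

    def as_dict(self) -> dict[str, float]:
        return self.heat.to_dict()


def merge_replicates(test_reps: pd.DataFrame, control_reps: pd.DataFrame) -> pd.Series:
    """Symmetrised relative change per probe between replicate groups.

    Returns ``a = (t - c) / ((t + c) / 2)``; the 0/0 case (probe silent
    in both groups) is defined as 0: an unexpressed probe carries no
    signal.
    """
    if test_reps.shape[1] < 1 or control_reps.shape[1] < 1:
        raise PreprocessError("need at least one replicate per group")
    if not test_reps.index.equals(control_reps.index):
        raise PreprocessError("probe rows differ between test and control matrices")
    tv, cv = test_reps.to_numpy(float), control_reps.to_numpy(float)
    if np.any(tv < 0) or np.any(cv < 0):
        raise PreprocessError("negative expression value in replicate matrix")
    t = tv.mean(axis=1)
    c = cv.mean(axis=1)
    denom = (t + c) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom > 0, (t - c) / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.Series(a, index=test_reps.index, name="a")


def collapse_conditions(scores_by_condition: list[pd.Series]) -> pd.Series:
    """Per-probe median across conditions (even count: mean of middle two)."""
    if not scores_by_condition:
        raise PreprocessError("no conditions to collapse")
    first = scores_by_condition[0].index
    for s in scores_by_condition[1:]:
        if set(s.index) != set(first):
            raise PreprocessError("probe sets differ across conditions")
    stacked = pd.concat([s.reindex(first) for s in scores_by_condition], axis=1)
    return stacked.median(axis=1)


def probes_to_genes(scores: pd.Series, probe_map: pd.DataFrame) -> GeneScores:
    """Collapse probe scores to genes by maximum absolute value.

    ``probe_map`` needs columns ``probe_id`` and ``gene_id``.  The score
    with the largest |a| among a gene's probes wins, keeping its sign;
    ties go to the lexicographically smallest probe id.  Probes without
    a mapping are dropped (count logged).
    """
    if probe_map.empty:
        raise PreprocessError("empty probe-to-gene mapping")
    mapped = probe_map[probe_map["probe_id"].isin(scores.index)]
    n_unmapped = scores.index.difference(pd.Index(probe_map["probe_id"])).size
    if n_unmapped:
        logger.info("dropping %d probe(s) without gene mapping", n_unmapped)
    df = pd.DataFrame({
        "probe_id": mapped["probe_id"].to_numpy(),
        "gene_id": mapped["gene_id"].to_numpy(),
        "score": scores.reindex(mapped["probe_id"]).to_numpy(),
    })
    df["abs"] = df["score"].abs()
    df = df.sort_values(["gene_id", "abs", "probe_id"],
                        ascending=[True, False, True],
                        kind="mergesort")
    best = df.groupby("gene_id", sort=True).first()
    return GeneScores(
        scores=best["score"].rename("score"),
        winning_probe=best["probe_id"].to_dict(),
    )


def build_heat_vector(
    gene_scores: GeneScores, n_top: int, mode: str = "both"
) -> HeatVector:
    """Select the strongest up/down genes and assign nonnegative heat.

    The ``n_top`` most-positive and ``n_top`` most-negative scores are
    selected ("most up/downregulated" requires strictly positive or
    negative scores; zeros never qualify).  Selected genes get
    ``h = |score|``; everything else 0.  ``mode`` restricts selection to
    'up' or 'down' for separate single-direction runs; the default pools
    both directions into one heat vector.
    """
    if n_top < 1:
        raise PreprocessError("n_top must be >= 1")
    if mode not in ("both", "up", "down"):
        raise PreprocessError(f"unknown mode {mode!r}")
    s = gene_scores.scores
    up = s[s > 0].sort_values(ascending=False, kind="mergesort")
    up = up.loc[sorted(up.index, key=lambda g: (-up[g], g))][:n_top]
    down = s[s < 0].sort_values(kind="mergesort")
    down = down.loc[sorted(down.index, key=lambda g: (down[g], g))][:n_top]
    direction: dict[str, str] = {}
    if mode in ("both", "up"):
        direction.update({g: "up" for g in up.index})
    if mode in ("both", "down"):
        direction.update({g: "down" for g in down.index})
    heat = pd.Series(0.0, index=s.index.sort_values())
    for g in direction:
        heat[g] = abs(s[g])
    return HeatVector(heat=heat, selected=set(direction), direction=direction)
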