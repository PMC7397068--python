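"""Permutation significance of extracted subnetworks.

The test statistic is, for a size class ``s``, the number of strongly
connected components of size >= s found at the chosen delta.  Null
draws permute the assignment of the observed heat multiset to network
genes (zero-heat genes included, so the multiset is preserved exactly),
keeping the network, kernel and delta fixed.  Empirical p-values use
the add-one convention, so they are never zero and their floor is
1/(n_perm + 1).

Two views are derived from one set of permutations:

* per size class ``s`` in ``s_values``: observed count, null mean and
  p-value.  When ``s_values`` is not given it defaults to the single
  adaptive class s = size of the largest observed component, i.e. the
  test "does a component this large arise from randomly placed heat?" —
  the question the delta calibration is designed around.
* per observed component: the p-value of the count statistic at
  s = that component's size, annotating each component with how
  unusual a component of its size is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusion import (
    PPINetwork,
    SubnetworkSet,
    build_transition_matrix,
    compute_diffusion_kernel,
    exchanged_heat,
    threshold_components,
)

__all__ = ["SignificanceReport", "component_count_statistic", "significance_test"]

SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class SizeClassResult:
    s: int
    observed: int
    null_mean: float
    p_value: float


@dataclass
class SignificanceReport:
    results: list[SizeClassResult]
    component_p: list[float]       # aligned with observed components
    observed_sizes: list[int]
    n_perm: int
    seed: int

    @property
    def significant(self) -> bool:
        """Significant when p <= 0.05 at the smallest tested size class."""
        smallest = min(self.results, key=lambda r: r.s)
        return smallest.p_value <= SIGNIFICANCE_THRESHOLD

    def as_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "significant": self.significant,
            "size_classes": [
                {"s": r.s, "observed": r.observed,
                 "null_mean": r.null_mean, "p_value": r.p_value}
                for r in self.results
            ],
        }


def component_count_statistic(subnetworks: SubnetworkSet, s: int) -> int:
    """Number of components with size >= s."""
    return sum(1 for size in subnetworks.sizes() if size >= s)


def _count_ge(sizes: np.ndarray, s: int) -> int:
    return int(np.sum(sizes >= s))


def significance_test(
    network: PPINetwork,
    heat: np.ndarray,
    delta: float,
    s_values: list[int] | None,
    n_perm: int,
    seed: int,
    s_min: int = 3,
    beta: float = 0.4,
    F: np.ndarray | None = None,
) -> SignificanceReport:
    """Empirical p-values for the component-count statistic.

    ``F`` may be passed to reuse an already-computed kernel; delta stays
    fixed at the observed-data choice so the permutation tests the heat
    placement, not the threshold.  ``s_values=None`` selects the
    adaptive single class s = largest observed component size (s_min
    when no component was observed).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    heat = np.asarray(heat, dtype=float)
    if F is None:
        F = compute_diffusion_kernel(build_transition_matrix(network), beta)
    observed_subnets = threshold_components(
        exchanged_heat(F, heat), delta, s_min, network.nodes)
    obs_sizes = np.array(observed_subnets.sizes(), dtype=int)

    if s_values is None:
        s_values = [int(obs_sizes.max())] if obs_sizes.size else [s_min]
    s_values = sorted(set(int(s) for s in s_values))
    if not s_values:
        raise ValueError("s_values must be nonempty")

    rng = np.random.default_rng(seed)
    null_sizes: list[np.ndarray] = []
    for _ in range(n_perm):
        h_perm = rng.permutation(heat)
        subnets = threshold_components(
            exchanged_heat(F, h_perm), delta, s_min, network.nodes)
        null_sizes.append(np.array(subnets.sizes(), dtype=int))

    def p_at(s: int) -> tuple[int, float, float]:
        obs = _count_ge(obs_sizes, s)
        nulls = np.array([_count_ge(ns, s) for ns in null_sizes])
        p = (1 + int(np.sum(nulls >= obs))) / (1 + n_perm)
        return obs, float(nulls.mean()), p

    results = []
    for s in s_values:
        obs, null_mean, p = p_at(s)
        results.append(SizeClassResult(s=s, observed=obs, null_mean=null_mean,
                                       p_value=p))
    component_p = [p_at(int(z))[2] for z in obs_sizes]
    return SignificanceReport(
        results=results, component_p=component_p,
        observed_sizes=[int(z) for z in obs_sizes], n_perm=n_perm, seed=seed)
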