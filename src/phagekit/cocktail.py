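"""Cocktail enumeration, union-coverage prediction and marginal ranking.

A combination of phage agents is assumed to inhibit a strain if at least
one member does (the union / complementarity rule).  The *marginal host
range* of an agent is the coverage gained by adding it to a combination
lacking it; collecting these gains over all admissible base combinations
gives a distribution whose mode (located by a Gaussian KDE) serves as the
agent's utility for ranking.

Engineered agents derived from the same wild-type ancestor phage have
near-identical inhibitory profiles, which would bias marginal values; by
default no combination may contain two agents sharing an ancestor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .host_range import CoverageEstimate, SusceptibilityMatrix, union_covered
from .host_range import _coverage_from_covered

__all__ = [
    "Combination",
    "MarginalDistribution",
    "enumerate_combinations",
    "combination_coverage",
    "marginal_host_range",
    "marginal_mode",
    "rank_caps",
    "predict_combination_effect",
]


@dataclass(frozen=True)
class Combination:
    """An unordered set of agent labels considered as one cocktail."""

    agent_ids: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "agent_ids", frozenset(self.agent_ids))

    @property
    def size(self) -> int:
        return len(self.agent_ids)

    def sorted_ids(self) -> tuple:
        return tuple(sorted(self.agent_ids))


@dataclass(frozen=True)
class MarginalDistribution:
    """Marginal coverage gains of one agent over its admissible bases."""

    cap_id: str
    values: np.ndarray = field(repr=False)
    mode: float
    kde_bandwidth: float


def enumerate_combinations(
    ancestors: Mapping[str, str],
    sizes: Iterable[int],
    exclude_shared_ancestor: bool = True,
) -> list:
    """All size-k agent subsets for each k, in deterministic lexicographic order.

    With ``exclude_shared_ancestor`` (default) no combination may contain
    two agents derived from the same wild-type ancestor.  Sizes exceeding
    the agent count simply contribute nothing.
    """
    agents = sorted(ancestors)
    if not agents:
        raise ValueError("agents must be non-empty")
    combos = []
    for k in sorted(set(int(k) for k in sizes)):
        if k < 0:
            raise ValueError("combination size must be >= 0")
        for subset in itertools.combinations(agents, k):
            if exclude_shared_ancestor:
                anc = [ancestors[a] for a in subset]
                if len(set(anc)) != len(anc):
                    continue
            combos.append(Combination(frozenset(subset)))
    return combos


def combination_coverage(
    matrix: SusceptibilityMatrix, combo: "Combination | Iterable[str]"
) -> CoverageEstimate:
    """Union-rule coverage of a combination over the panel.

    Per replicate, a strain counts as covered iff at least one member has a
    susceptible call; mean and panel-normalized count s.d. follow the
    single-agent host-range convention.  The empty combination covers
    nothing.
    """
    agent_ids = (
        combo.sorted_ids() if isinstance(combo, Combination) else sorted(combo)
    )
    covered, considered = union_covered(matrix, agent_ids)
    panel = int(considered.any(axis=0).sum())
    return _coverage_from_covered(covered, considered, panel)


def _admissible_bases(
    matrix: SusceptibilityMatrix,
    cap_id: str,
    candidate_ids: Sequence[str],
    base_sizes: Iterable[int],
    exclude_shared_ancestor: bool,
) -> list:
    others = {
        a: matrix.ancestors.get(a, a) for a in candidate_ids if a != cap_id
    }
    cap_anc = matrix.ancestors.get(cap_id, cap_id)
    if not others:
        return [Combination(frozenset())] if 0 in set(base_sizes) else []
    bases = []
    for combo in enumerate_combinations(
        others, base_sizes, exclude_shared_ancestor
    ):
        if exclude_shared_ancestor and any(
            matrix.ancestors.get(a, a) == cap_anc for a in combo.agent_ids
        ):
            continue
        bases.append(combo)
    return bases


def marginal_host_range(
    matrix: SusceptibilityMatrix,
    cap_id: str,
    base_combinations: Optional[Sequence[Combination]] = None,
    base_sizes: Optional[Iterable[int]] = None,
    candidate_ids: Optional[Sequence[str]] = None,
    exclude_shared_ancestor: bool = True,
) -> MarginalDistribution:
    """Distribution of coverage gains from adding one agent to base combinations.

    For each admissible base B (excluding the agent, and — under the
    ancestor rule — any agent sharing its ancestor) the value is
    ``coverage(B + cap) - coverage(B)``.  When no explicit bases are given,
    all admissible combinations of sizes ``base_sizes`` (default
    1..n_candidates-1) over ``candidate_ids`` (default all matrix agents)
    are used.
    """
    if cap_id not in matrix.agents:
        raise KeyError(f"unknown agent {cap_id!r}")
    if base_combinations is None:
        if candidate_ids is None:
            candidate_ids = matrix.agents
        if base_sizes is None:
            base_sizes = range(1, len(candidate_ids))
        base_combinations = _admissible_bases(
            matrix, cap_id, candidate_ids, base_sizes, exclude_shared_ancestor
        )
    values = []
    for base in base_combinations:
        if cap_id in base.agent_ids:
            raise ValueError(f"base combination already contains {cap_id!r}")
        with_cap = Combination(base.agent_ids | {cap_id})
        gain = (
            combination_coverage(matrix, with_cap).mean_fraction
            - combination_coverage(matrix, base).mean_fraction
        )
        values.append(gain)
    if not values:
        raise ValueError("no admissible combinations")
    values = np.asarray(values, dtype=float)
    bw = _nrd0_bandwidth(values)
    return MarginalDistribution(
        cap_id=cap_id,
        values=values,
        mode=_kde_mode(values, bw),
        kde_bandwidth=bw,
    )


def _nrd0_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth (R density() default, bw.nrd0)."""
    n = len(values)
    if n < 2:
        return 0.0
    sd = float(np.std(values, ddof=1))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        # nrd0 fallback chain for degenerate spreads
        spread = abs(float(values[0])) if values[0] != 0 else 1.0
    return 0.9 * spread * n ** (-0.2)


def _kde_mode(values: np.ndarray, bandwidth: float, grid_points: int = 512) -> float:
    """Argmax of a Gaussian KDE on a 512-point grid spanning [min-3h, max+3h]."""
    if len(values) == 1 or np.ptp(values) == 0 or bandwidth <= 0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method=bandwidth / np.std(values, ddof=1))
    grid = np.linspace(
        values.min() - 3 * bandwidth, values.max() + 3 * bandwidth, grid_points
    )
    return float(grid[np.argmax(kde(grid))])


def marginal_mode(dist: "MarginalDistribution | np.ndarray") -> float:
    """Mode of a marginal host-range distribution via Gaussian KDE."""
    if isinstance(dist, MarginalDistribution):
        return dist.mode
    values = np.asarray(dist, dtype=float)
    if len(values) == 0:
        raise ValueError("empty distribution")
    return _kde_mode(values, _nrd0_bandwidth(values))


def rank_caps(
    matrix: SusceptibilityMatrix,
    candidate_ids: Optional[Sequence[str]] = None,
    base_sizes: Optional[Iterable[int]] = None,
    exclude_shared_ancestor: bool = True,
) -> list:
    """Rank candidate agents by the mode of their marginal host range.

    Returns (cap_id, MarginalDistribution) pairs sorted by mode descending;
    ties broken by mean marginal value, then by label.  Deterministic in
    the candidate input order.
    """
    if candidate_ids is None:
        candidate_ids = matrix.agents
    candidate_ids = sorted(candidate_ids)
    if not candidate_ids:
        raise ValueError("candidates must be non-empty")
    dists = [
        marginal_host_range(
            matrix,
            cap,
            base_sizes=base_sizes,
            candidate_ids=candidate_ids,
            exclude_shared_ancestor=exclude_shared_ancestor,
        )
        for cap in candidate_ids
    ]
    return sorted(
        zip(candidate_ids, dists),
        key=lambda item: (-item[1].mode, -float(item[1].values.mean()), item[0]),
    )


def predict_combination_effect(per_cap_reductions: Iterable[float]) -> float:
    """Additive in-vivo prediction: sum of per-agent log10 CFU/g reductions."""
    reductions = [float(r) for r in per_cap_reductions]
    if any(not np.isfinite(r) for r in reductions):
        raise ValueError("reductions must be finite")
    return float(sum(reductions))
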