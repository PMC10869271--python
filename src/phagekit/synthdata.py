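"""Seeded synthetic-data generators with planted ground truth.

Every input class the pipeline consumes can be simulated here: OmniLog-style
sigmoidal dye-accumulation growth curves with phage-dependent inhibition,
strain x agent susceptibility panels with ancestor-correlated agent profiles
and noisy duplicate plaquing runs, competition-assay calibration mixtures,
and left-censored in-vivo CFU counts.  All generators are deterministic
given their seed, so recovery tests can compare pipeline output against the
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .host_range import (
    LYSIS_ZONE,
    NO_EFFECT,
    PLAQUE,
    PanelStrain,
    PlaquingObservation,
    SusceptibilityMatrix,
)
from .kinetics import KineticSeries

__all__ = [
    "CurveSimConfig",
    "PanelSimConfig",
    "simulate_growth_curve",
    "simulate_panel",
    "simulate_planted_panel",
    "simulate_competition_series",
    "simulate_in_vivo_counts",
]


@dataclass(frozen=True)
class CurveSimConfig:
    """Parameters of one simulated growth-kinetics well.

    The dye signal is a cumulative logistic
    ``baseline + (1 - inhibition) * amplitude / (1 + exp(-rate (t - t_mid)))``
    plus Gaussian noise with s.d. ``noise_sd * amplitude``; ``inhibition``
    (lambda in [0, 1]) scales the agent effect, 1 being complete
    suppression.  Sampling is every 0.25 h over 24 h, matching a 15-min
    microplate read cycle.
    """

    amplitude: float = 200.0
    growth_rate: float = 0.8
    t_mid: float = 8.0
    baseline: float = 20.0
    noise_sd: float = 0.05
    inhibition: float = 0.0
    t_max: float = 24.0
    dt: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if not 0.0 <= self.inhibition <= 1.0:
            raise ValueError("inhibition must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_growth_curve(
    config: CurveSimConfig,
    well_id: str = "W1",
    strain_id: str = "s1",
    agent_id: Optional[str] = None,
    moi: float = 1.0,
    replicate: int = 1,
) -> KineticSeries:
    """Simulate one well's cumulative redox signal as a noisy logistic."""
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.t_max + config.dt / 2, config.dt)
    logistic = 1.0 / (1.0 + np.exp(-config.growth_rate * (times - config.t_mid)))
    mean = config.baseline + (1.0 - config.inhibition) * config.amplitude * logistic
    noise = rng.normal(0.0, config.noise_sd * config.amplitude, size=len(times))
    return KineticSeries(
        well_id=well_id,
        strain_id=strain_id,
        agent_id=agent_id,
        moi=moi,
        replicate=replicate,
        times=times,
        signal=mean + noise,
    )


@dataclass(frozen=True)
class PanelSimConfig:
    """Parameters of a simulated strain x agent susceptibility panel.

    ``agent_profiles`` maps each agent to per-phylogroup susceptibility
    probabilities; agents sharing an entry in ``ancestor_map`` are derived
    from a common wild-type phage and copy the first sibling's true profile
    with per-strain flip probability ``derived_flip_prob`` (ancestor
    correlation).  Observed plaquing replicates flip hits to misses with
    probability ``miss_rate``, misses to hits with ``false_hit_rate``, and
    report a hit as a countable plaque with probability
    ``p_plaque_given_hit`` (otherwise a lysis zone).
    """

    n_strains: int = 72
    phylogroup_weights: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.15, "B1": 0.12, "B2": 0.53, "D": 0.2}
    )
    agent_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            f"cap{j}": {"A": 0.6, "B1": 0.6, "B2": 0.7, "D": 0.6}
            for j in range(1, 5)
        }
    )
    ancestor_map: Mapping[str, str] = field(default_factory=dict)
    derived_flip_prob: float = 0.05
    miss_rate: float = 0.05
    false_hit_rate: float = 0.02
    p_plaque_given_hit: float = 0.6
    n_replicates: int = 2
    seed: int = 0


def simulate_panel(
    config: PanelSimConfig,
) -> tuple:
    """Simulate a panel: (true SusceptibilityMatrix, noisy PlaquingObservation list).

    True boolean profiles are drawn per strain from the per-phylogroup
    probabilities; agents sharing an ancestor are near-copies of each other.
    The observation list carries ``n_replicates`` runs per cell with the
    configured misclassification rates applied independently per run.
    """
    rng = np.random.default_rng(config.seed)
    phylogroups = sorted(config.phylogroup_weights)
    weights = np.array([config.phylogroup_weights[p] for p in phylogroups])
    weights = weights / weights.sum()
    agents = sorted(config.agent_profiles)
    n_s, n_a = config.n_strains, len(agents)

    strain_pg = rng.choice(phylogroups, size=n_s, p=weights)
    strains = [
        PanelStrain(strain_id=f"b{i + 1:03d}", phylogroup=str(strain_pg[i]))
        for i in range(n_s)
    ]

    ancestors = {a: config.ancestor_map.get(a, a) for a in agents}
    truth = np.zeros((n_s, n_a), dtype=bool)
    first_of_ancestor: dict = {}
    for j, agent in enumerate(agents):
        anc = ancestors[agent]
        if anc in first_of_ancestor:
            # sibling of an already-drawn agent: copy with small flips
            base = truth[:, first_of_ancestor[anc]]
            flips = rng.random(n_s) < config.derived_flip_prob
            truth[:, j] = base ^ flips
        else:
            probs = np.array(
                [config.agent_profiles[agent].get(str(pg), 0.0) for pg in strain_pg]
            )
            truth[:, j] = rng.random(n_s) < probs
            first_of_ancestor[anc] = j

    true_matrix = SusceptibilityMatrix(
        strains=strains,
        agents=agents,
        calls=truth[np.newaxis, :, :],
        present=np.ones((1, n_s, n_a), dtype=bool),
        ancestors=dict(ancestors),
    )

    observations = []
    for run in range(1, config.n_replicates + 1):
        for i in range(n_s):
            for j, agent in enumerate(agents):
                hit = truth[i, j]
                if hit and rng.random() < config.miss_rate:
                    hit = False
                elif not hit and rng.random() < config.false_hit_rate:
                    hit = True
                if hit:
                    outcome = (
                        PLAQUE
                        if rng.random() < config.p_plaque_given_hit
                        else LYSIS_ZONE
                    )
                else:
                    outcome = NO_EFFECT
                observations.append(
                    PlaquingObservation(
                        strain_id=strains[i].strain_id,
                        agent_id=agent,
                        run=run,
                        outcome=outcome,
                    )
                )
    return true_matrix, observations


def simulate_planted_panel(
    n_blocks: int = 4,
    block_size: int = 10,
    n_decoys: int = 7,
    dropout: float = 0.25,
    seed: int = 0,
) -> tuple:
    """Panel with planted orthogonal agents plus redundant degraded decoys.

    Each of ``n_blocks`` planted agents covers its own disjoint block of
    ``block_size`` strains (orthogonal, high-coverage profiles).  Each
    decoy is an engineered derivative of a random planted agent: it
    inherits the ancestor's host set and loses each host with probability
    ``dropout`` (at least one host is always lost — receptor specificity
    is inherited, so a derivative never gains hosts its ancestor lacks).
    Decoys share their source's ancestor label, engaging the
    same-ancestor exclusion during ranking.

    Returns (SusceptibilityMatrix, planted agent-id list); the planted
    agents are the ground-truth top choices for marginal ranking.
    """
    rng = np.random.default_rng(seed)
    n_s = n_blocks * block_size
    planted = [f"planted{j + 1}" for j in range(n_blocks)]
    decoys = [f"decoy{k + 1}" for k in range(n_decoys)]
    agents = planted + decoys
    truth = np.zeros((n_s, len(agents)), dtype=bool)
    ancestors = {}
    for j in range(n_blocks):
        truth[j * block_size : (j + 1) * block_size, j] = True
        ancestors[planted[j]] = f"wt{j + 1}"
    for k in range(n_decoys):
        src = int(rng.integers(0, n_blocks))
        col = truth[:, src].copy()
        hosts = np.flatnonzero(col)
        drops = hosts[rng.random(len(hosts)) < dropout]
        if len(drops) == 0:
            drops = hosts[[int(rng.integers(len(hosts)))]]
        col[drops] = False
        truth[:, n_blocks + k] = col
        ancestors[decoys[k]] = ancestors[planted[src]]
    strains = [PanelStrain(strain_id=f"b{i + 1:03d}") for i in range(n_s)]
    matrix = SusceptibilityMatrix(
        strains=strains,
        agents=agents,
        calls=truth[np.newaxis, :, :],
        present=np.ones((1, n_s, len(agents)), dtype=bool),
        ancestors=ancestors,
    )
    return matrix, planted


def simulate_competition_series(
    alpha: float,
    fractions: Sequence[float],
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple:
    """Calibration mixtures for the competition assay.

    Returns aligned arrays (f, r) with r = alpha (1-f)/f perturbed by
    multiplicative log-normal noise of the given log-scale s.d.
    """
    f = np.asarray(fractions, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("fractions must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    r = alpha * (1.0 - f) / f
    if noise_sd > 0:
        r = r * np.exp(rng.normal(0.0, noise_sd, size=len(f)))
    return f, r


def simulate_in_vivo_counts(
    group_means_log10: Mapping[str, float],
    sd_log10: float,
    n_animals: int,
    lod: float,
    seed: int = 0,
) -> dict:
    """Per-animal CFU/g counts, log-normal per group, left-censored at the LOD.

    Returns {group: array of counts} where values below the LOD are clamped
    to it (censored observations plot at the LOD line).
    """
    if n_animals < 1:
        raise ValueError("need at least one animal per group")
    rng = np.random.default_rng(seed)
    out = {}
    for group in sorted(group_means_log10):
        logs = rng.normal(group_means_log10[group], sd_log10, size=n_animals)
        counts = 10.0**logs
        out[group] = np.maximum(counts, lod)
    return out
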