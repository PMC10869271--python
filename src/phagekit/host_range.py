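"""Strain x agent susceptibility matrices and host-range statistics.

A :class:`SusceptibilityMatrix` holds per-replicate boolean susceptibility
calls (and optionally the categorical plaquing outcome behind each call)
for a panel of bacterial strains against a set of phage agents.  Matrices
are built either from kinetic iAUC scores or from spot-assay plaquing
observations, and feed host-range, category, stratified-coverage and
redundancy statistics.

Plaquing outcomes are ordered ``plaque > lysis_zone > no_effect``; both
plaques and lysis zones count a strain as susceptible.  The conservative
consensus of two plaquing runs is the outcome with the lower plaquing
efficiency under that ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .kinetics import IAUC_THRESHOLD, InhibitionScore, call_susceptible

__all__ = [
    "PLAQUE",
    "LYSIS_ZONE",
    "NO_EFFECT",
    "OUTCOMES",
    "PlaquingObservation",
    "PanelStrain",
    "SusceptibilityMatrix",
    "CoverageEstimate",
    "CategoryFractions",
    "StratifiedCoverage",
    "ResistanceRules",
    "consensus_call",
    "matrix_from_iauc",
    "matrix_from_plaquing",
    "host_range",
    "category_fractions",
    "classify_resistance",
    "stratified_coverage",
    "redundancy_distribution",
]

PLAQUE = "plaque"
LYSIS_ZONE = "lysis_zone"
NO_EFFECT = "no_effect"
OUTCOMES = (PLAQUE, LYSIS_ZONE, NO_EFFECT)

# Strict plaquing-efficiency ordering: plaque > lysis_zone > no_effect.
_OUTCOME_RANK = {PLAQUE: 2, LYSIS_ZONE: 1, NO_EFFECT: 0}
_RANK_OUTCOME = {v: k for k, v in _OUTCOME_RANK.items()}

# Compact matrix-CSV codes.
OUTCOME_CODES = {PLAQUE: "P", LYSIS_ZONE: "L", NO_EFFECT: "N"}
CODE_OUTCOMES = {v: k for k, v in OUTCOME_CODES.items()}


@dataclass(frozen=True)
class PlaquingObservation:
    """A single spot-assay reading for one strain x agent pair in one run."""

    strain_id: str
    agent_id: str
    run: int
    outcome: str
    titer: Optional[float] = None
    eop: Optional[float] = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown plaquing outcome {self.outcome!r}")
        if self.titer is not None and not self.titer > 0:
            raise ValueError("titer must be positive when present")

    @property
    def susceptible(self) -> bool:
        return self.outcome in (PLAQUE, LYSIS_ZONE)


@dataclass(frozen=True)
class PanelStrain:
    """Panel member with typing metadata and resistance phenotype.

    ``resistance_flags`` is a subset of {MDR, ESBL, CRE, FQR}; when a MIC
    table is supplied alongside explicit flags, the rule-defined flags
    (ESBL, CRE) must agree with :func:`classify_resistance`.
    """

    strain_id: str
    phylogroup: str = ""
    mlst: str = ""
    resistance_flags: frozenset = frozenset()
    mic_table: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "resistance_flags", frozenset(self.resistance_flags)
        )
        if self.mic_table is not None and self.resistance_flags:
            derived = classify_resistance(self.mic_table)
            for flag in ("ESBL", "CRE"):
                if (flag in derived) != (flag in self.resistance_flags):
                    raise ValueError(
                        f"strain {self.strain_id}: {flag} flag inconsistent "
                        "with MIC table"
                    )


@dataclass(frozen=True)
class CoverageEstimate:
    """Mean covered panel fraction with the panel-normalized s.d.

    The s.d. is computed on the per-replicate susceptible *counts* and then
    normalized by dividing with the size of the panel; a single replicate
    yields s.d. 0.
    """

    mean_fraction: float
    sd_fraction: float
    n_replicates: int
    n_strains: int


@dataclass(frozen=True)
class CategoryFractions:
    """Replicate-averaged per-strain best-outcome percentages (mutually exclusive)."""

    plaque_pct: float
    lysis_pct: float
    no_effect_pct: float
    coverage_pct: float
    plaque_sd: float = 0.0
    lysis_sd: float = 0.0
    coverage_sd: float = 0.0


@dataclass(frozen=True)
class StratifiedCoverage:
    stratum: str
    estimate: CoverageEstimate
    n_susceptible: int
    n_resistant: int


@dataclass
class SusceptibilityMatrix:
    """Per-replicate strain x agent susceptibility calls.

    ``calls`` and ``present`` have shape (n_replicates, n_strains, n_agents);
    cells with ``present`` False are excluded from all denominators.
    ``outcomes`` (same shape, codes P/L/N) is populated when the matrix was
    built from plaquing data.  ``ancestors`` maps each agent to its
    wild-type ancestor phage (defaults to the agent itself).
    """

    strains: list
    agents: list
    calls: np.ndarray
    present: np.ndarray
    outcomes: Optional[np.ndarray] = None
    ancestors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strains = [
            s if isinstance(s, PanelStrain) else PanelStrain(strain_id=str(s))
            for s in self.strains
        ]
        self.agents = [str(a) for a in self.agents]
        self.calls = np.asarray(self.calls, dtype=bool)
        self.present = np.asarray(self.present, dtype=bool)
        shape = (self.n_replicates, len(self.strains), len(self.agents))
        if self.calls.shape != shape or self.present.shape != shape:
            raise ValueError("calls/present shape mismatch")
        if self.calls.shape[0] < 1:
            raise ValueError("need at least one replicate")
        for agent in self.agents:
            self.ancestors.setdefault(agent, agent)

    @property
    def n_replicates(self) -> int:
        return self.calls.shape[0] if self.calls.ndim == 3 else 0

    @property
    def strain_ids(self) -> list:
        return [s.strain_id for s in self.strains]

    def agent_index(self, agent_id: str) -> int:
        try:
            return self.agents.index(agent_id)
        except ValueError:
            raise KeyError(f"unknown agent {agent_id!r}") from None

    def agent_indices(self, agent_ids: Iterable[str]) -> list:
        return [self.agent_index(a) for a in agent_ids]


def consensus_call(
    obs_run1: PlaquingObservation, obs_run2: PlaquingObservation
) -> str:
    """Conservative consensus of two plaquing runs.

    Returns the outcome with the *lower* plaquing efficiency under the
    ordering plaque > lysis_zone > no_effect.
    """
    if (obs_run1.strain_id, obs_run1.agent_id) != (
        obs_run2.strain_id,
        obs_run2.agent_id,
    ):
        raise ValueError("consensus requires observations of the same strain and agent")
    rank = min(_OUTCOME_RANK[obs_run1.outcome], _OUTCOME_RANK[obs_run2.outcome])
    return _RANK_OUTCOME[rank]


def _resolve_panel(
    strain_ids: Sequence[str], strains: Optional[Sequence[PanelStrain]]
) -> list:
    if strains is None:
        return [PanelStrain(strain_id=s) for s in strain_ids]
    by_id = {s.strain_id: s for s in strains}
    return [by_id.get(s, PanelStrain(strain_id=s)) for s in strain_ids]


def matrix_from_iauc(
    scores: Iterable[InhibitionScore],
    threshold: float = IAUC_THRESHOLD,
    strains: Optional[Sequence[PanelStrain]] = None,
    ancestors: Optional[Mapping[str, str]] = None,
) -> SusceptibilityMatrix:
    """Threshold kinetic iAUC scores into a per-replicate boolean matrix.

    Cells missing from the strain x agent x replicate design are marked
    absent and excluded from denominators; duplicate entries are an error.
    """
    scores = list(scores)
    strain_ids = sorted({s.strain_id for s in scores})
    agent_ids = sorted({s.agent_id for s in scores})
    replicates = sorted({s.replicate for s in scores})
    n_r, n_s, n_a = max(len(replicates), 1), len(strain_ids), len(agent_ids)
    calls = np.zeros((n_r, n_s, n_a), dtype=bool)
    present = np.zeros((n_r, n_s, n_a), dtype=bool)
    s_idx = {s: i for i, s in enumerate(strain_ids)}
    a_idx = {a: i for i, a in enumerate(agent_ids)}
    r_idx = {r: i for i, r in enumerate(replicates)}
    for sc in scores:
        r, i, j = r_idx[sc.replicate], s_idx[sc.strain_id], a_idx[sc.agent_id]
        if present[r, i, j]:
            raise ValueError(
                f"duplicate score for ({sc.strain_id}, {sc.agent_id}, "
                f"replicate {sc.replicate})"
            )
        present[r, i, j] = True
        calls[r, i, j] = call_susceptible(sc.iauc, threshold)
    return SusceptibilityMatrix(
        strains=_resolve_panel(strain_ids, strains),
        agents=agent_ids,
        calls=calls,
        present=present,
        ancestors=dict(ancestors) if ancestors else {},
    )


def matrix_from_plaquing(
    observations: Iterable[PlaquingObservation],
    consensus: bool = False,
    strains: Optional[Sequence[PanelStrain]] = None,
    ancestors: Optional[Mapping[str, str]] = None,
) -> SusceptibilityMatrix:
    """Build a categorical susceptibility matrix from spot-assay outcomes.

    A strain is susceptible to an agent when the outcome is a plaque or a
    lysis zone.  With ``consensus=True`` exactly two runs per cell are
    required and collapsed into one conservative-consensus replicate.
    """
    observations = list(observations)
    strain_ids = sorted({o.strain_id for o in observations})
    agent_ids = sorted({o.agent_id for o in observations})
    s_idx = {s: i for i, s in enumerate(strain_ids)}
    a_idx = {a: i for i, a in enumerate(agent_ids)}
    by_cell: dict = {}
    for o in observations:
        by_cell.setdefault((o.strain_id, o.agent_id), []).append(o)

    if consensus:
        n_r = 1
    else:
        runs = sorted({o.run for o in observations})
        run_idx = {r: i for i, r in enumerate(runs)}
        n_r = max(len(runs), 1)
    n_s, n_a = len(strain_ids), len(agent_ids)
    calls = np.zeros((n_r, n_s, n_a), dtype=bool)
    present = np.zeros((n_r, n_s, n_a), dtype=bool)
    outcomes = np.full((n_r, n_s, n_a), "", dtype="<U1")

    for (sid, aid), cell_obs in by_cell.items():
        i, j = s_idx[sid], a_idx[aid]
        if consensus:
            if len(cell_obs) != 2:
                raise ValueError(
                    f"consensus requires exactly 2 runs per cell; "
                    f"({sid}, {aid}) has {len(cell_obs)}"
                )
            out = consensus_call(cell_obs[0], cell_obs[1])
            present[0, i, j] = True
            calls[0, i, j] = out in (PLAQUE, LYSIS_ZONE)
            outcomes[0, i, j] = OUTCOME_CODES[out]
        else:
            seen = set()
            for o in cell_obs:
                if o.run in seen:
                    raise ValueError(
                        f"duplicate observation for ({sid}, {aid}, run {o.run})"
                    )
                seen.add(o.run)
                r = run_idx[o.run]
                present[r, i, j] = True
                calls[r, i, j] = o.susceptible
                outcomes[r, i, j] = OUTCOME_CODES[o.outcome]

    return SusceptibilityMatrix(
        strains=_resolve_panel(strain_ids, strains),
        agents=agent_ids,
        calls=calls,
        present=present,
        outcomes=outcomes,
        ancestors=dict(ancestors) if ancestors else {},
    )


def _count_sd(counts: np.ndarray) -> float:
    """Sample s.d. of per-replicate counts; 0 for a single replicate."""
    if len(counts) < 2:
        return 0.0
    return float(np.std(counts, ddof=1))


def _coverage_from_covered(
    covered: np.ndarray, denom_present: np.ndarray, panel_size: int
) -> CoverageEstimate:
    """Mean/s.d. coverage from a (n_replicates, n_strains) covered mask."""
    counts = covered.sum(axis=1).astype(float)
    denoms = denom_present.sum(axis=1).astype(float)
    fractions = np.divide(
        counts, denoms, out=np.zeros_like(counts), where=denoms > 0
    )
    return CoverageEstimate(
        mean_fraction=float(fractions.mean()),
        sd_fraction=_count_sd(counts) / panel_size if panel_size else 0.0,
        n_replicates=covered.shape[0],
        n_strains=panel_size,
    )


def host_range(matrix: SusceptibilityMatrix, agent_id: str) -> CoverageEstimate:
    """Fraction of the panel susceptible to one agent.

    Computed per replicate, averaged; the s.d. of the per-replicate
    susceptible counts is normalized by the panel size.
    """
    j = matrix.agent_index(agent_id)
    covered = matrix.calls[:, :, j] & matrix.present[:, :, j]
    denom = matrix.present[:, :, j]
    panel = int(denom.any(axis=0).sum())
    return _coverage_from_covered(covered, denom, panel)


def union_covered(
    matrix: SusceptibilityMatrix, agent_ids: Sequence[str]
) -> tuple:
    """(covered, considered) (n_replicates, n_strains) masks under the union rule.

    A strain is covered in a replicate iff at least one listed agent has a
    susceptible call there; strains with no present cell for any listed
    agent are excluded from denominators.
    """
    idx = matrix.agent_indices(agent_ids)
    if not idx:
        shape = (matrix.n_replicates, len(matrix.strains))
        return np.zeros(shape, dtype=bool), np.ones(shape, dtype=bool)
    sub_calls = matrix.calls[:, :, idx] & matrix.present[:, :, idx]
    covered = sub_calls.any(axis=2)
    considered = matrix.present[:, :, idx].any(axis=2)
    return covered, considered


def category_fractions(
    matrix: SusceptibilityMatrix, agent_ids: Optional[Sequence[str]] = None
) -> CategoryFractions:
    """Per-strain best-outcome category percentages over an agent subset.

    For each strain the best outcome across the subset is taken
    (plaque > lysis_zone > no_effect), making the plaque / lysis-zone /
    no-effect categories mutually exclusive; percentages are averaged over
    replicates and coverage% = plaque% + lysis%.
    """
    if matrix.outcomes is None:
        raise ValueError("matrix carries no categorical outcomes")
    if agent_ids is None:
        agent_ids = matrix.agents
    idx = matrix.agent_indices(agent_ids)
    rank = np.full(matrix.outcomes.shape, -1, dtype=int)
    for code, outcome in CODE_OUTCOMES.items():
        rank[matrix.outcomes == code] = _OUTCOME_RANK[outcome]
    rank[~matrix.present] = -1
    best = rank[:, :, idx].max(axis=2)  # (n_reps, n_strains); -1 = no data
    per_rep = []
    for r in range(matrix.n_replicates):
        n = int((best[r] >= 0).sum())
        if n == 0:
            per_rep.append((0.0, 0.0, 0.0))
            continue
        p = 100.0 * (best[r] == 2).sum() / n
        l = 100.0 * (best[r] == 1).sum() / n
        ne = 100.0 * (best[r] == 0).sum() / n
        per_rep.append((p, l, ne))
    arr = np.array(per_rep)
    sds = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(3)
    p, l, ne = arr.mean(axis=0)
    return CategoryFractions(
        plaque_pct=float(p),
        lysis_pct=float(l),
        no_effect_pct=float(ne),
        coverage_pct=float(p + l),
        plaque_sd=float(sds[0]),
        lysis_sd=float(sds[1]),
        coverage_sd=float((arr[:, 0] + arr[:, 1]).std(ddof=1))
        if len(arr) > 1
        else 0.0,
    )


@dataclass(frozen=True)
class ResistanceRules:
    """Configurable MIC breakpoints (mg/l) for phenotype flags.

    ESBL: MIC >= 2 for ceftriaxone, ceftazidime and/or aztreonam (inclusive).
    CRE: imipenem, doripenem and/or meropenem MIC > 2 (strict).
    FQR: ciprofloxacin MIC >= 1 or levofloxacin MIC >= 2 (CLSI-style).
    MDR: non-susceptible to >= 1 drug in >= ``mdr_min_classes`` classes.
    """

    esbl_drugs: tuple = ("ceftriaxone", "ceftazidime", "aztreonam")
    esbl_mic: float = 2.0
    cre_drugs: tuple = ("imipenem", "doripenem", "meropenem")
    cre_mic: float = 2.0
    fqr_breakpoints: tuple = (("ciprofloxacin", 1.0), ("levofloxacin", 2.0))
    mdr_min_classes: int = 3


# Drug -> antimicrobial class, for the MDR count.
DRUG_CLASSES = {
    "ampicillin": "penicillins",
    "piperacillin-tazobactam": "penicillins",
    "ceftriaxone": "cephalosporins",
    "ceftazidime": "cephalosporins",
    "cefepime": "cephalosporins",
    "aztreonam": "monobactams",
    "imipenem": "carbapenems",
    "doripenem": "carbapenems",
    "meropenem": "carbapenems",
    "ertapenem": "carbapenems",
    "ciprofloxacin": "fluoroquinolones",
    "levofloxacin": "fluoroquinolones",
    "gentamicin": "aminoglycosides",
    "tobramycin": "aminoglycosides",
    "amikacin": "aminoglycosides",
    "trimethoprim-sulfamethoxazole": "folate-pathway-inhibitors",
    "colistin": "polymyxins",
    "tigecycline": "tetracyclines",
}

# MIC strictly above this value counts the drug as non-susceptible (CLSI-style
# susceptible-range upper bounds), used only for the MDR class count.
_NONSUSCEPTIBLE_ABOVE = {
    "ampicillin": 8.0,
    "piperacillin-tazobactam": 8.0,
    "ceftriaxone": 1.0,
    "ceftazidime": 4.0,
    "cefepime": 2.0,
    "aztreonam": 4.0,
    "imipenem": 1.0,
    "doripenem": 1.0,
    "meropenem": 1.0,
    "ertapenem": 0.5,
    "ciprofloxacin": 0.25,
    "levofloxacin": 0.5,
    "gentamicin": 4.0,
    "tobramycin": 4.0,
    "amikacin": 16.0,
    "trimethoprim-sulfamethoxazole": 2.0,
    "colistin": 2.0,
    "tigecycline": 0.5,
}


def classify_resistance(
    mic_table: Mapping[str, float], rules: ResistanceRules = ResistanceRules()
) -> frozenset:
    """Derive {ESBL, CRE, FQR, MDR} flags from a MIC table (mg/l).

    Unknown drug names are ignored with a warning.  Raising any MIC never
    removes a flag.
    """
    mics = {}
    for drug, mic in mic_table.items():
        key = drug.strip().lower()
        if key not in DRUG_CLASSES:
            warnings.warn(f"unknown drug {drug!r} ignored", stacklevel=2)
            continue
        mics[key] = float(mic)
    flags = set()
    if any(mics.get(d, 0.0) >= rules.esbl_mic for d in rules.esbl_drugs):
        flags.add("ESBL")
    if any(mics.get(d, 0.0) > rules.cre_mic for d in rules.cre_drugs):
        flags.add("CRE")
    if any(mics.get(d, 0.0) >= bp for d, bp in rules.fqr_breakpoints):
        flags.add("FQR")
    classes_hit = {
        DRUG_CLASSES[d]
        for d, mic in mics.items()
        if mic > _NONSUSCEPTIBLE_ABOVE[d]
    }
    if len(classes_hit) >= rules.mdr_min_classes:
        flags.add("MDR")
    return frozenset(flags)


def _stratum_mask(matrix: SusceptibilityMatrix, stratum: str) -> np.ndarray:
    mask = np.array(
        [
            stratum in s.resistance_flags or s.phylogroup == stratum
            for s in matrix.strains
        ],
        dtype=bool,
    )
    return mask


def stratified_coverage(
    matrix: SusceptibilityMatrix,
    agent_ids: Sequence[str],
    stratum: str,
) -> StratifiedCoverage:
    """Union-rule coverage restricted to one resistance flag or phylogroup.

    Returns the coverage estimate plus integer susceptible / resistant
    counts; a strain counts as susceptible when it is covered in at least
    one replicate.
    """
    mask = _stratum_mask(matrix, stratum)
    if not mask.any():
        raise ValueError("empty stratum")
    covered, considered = union_covered(matrix, agent_ids)
    covered = covered[:, mask]
    considered = considered[:, mask]
    panel = int(considered.any(axis=0).sum())
    est = _coverage_from_covered(covered, considered, panel)
    n_susc = int(covered.any(axis=0).sum())
    return StratifiedCoverage(
        stratum=stratum,
        estimate=est,
        n_susceptible=n_susc,
        n_resistant=panel - n_susc,
    )


def redundancy_distribution(
    matrix: SusceptibilityMatrix, agent_ids: Sequence[str]
) -> np.ndarray:
    """Fraction of strains hit by >= k agents, for k = 0..len(agent_ids).

    Computed per replicate then averaged.  The value at k=0 is 1, the value
    at k=1 equals the union coverage, and the sequence is nonincreasing.
    """
    agent_ids = list(agent_ids)
    if not agent_ids:
        raise ValueError("agent subset must be non-empty")
    idx = matrix.agent_indices(agent_ids)
    hits = (matrix.calls[:, :, idx] & matrix.present[:, :, idx]).sum(axis=2)
    considered = matrix.present[:, :, idx].any(axis=2)
    ks = np.arange(len(agent_ids) + 1)
    per_rep = np.zeros((matrix.n_replicates, len(ks)))
    for r in range(matrix.n_replicates):
        n = int(considered[r].sum())
        if n == 0:
            per_rep[r, 0] = 1.0
            continue
        h = hits[r][considered[r]]
        per_rep[r] = [(h >= k).sum() / n for k in ks]
    return per_rep.mean(axis=0)
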