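"""Deterministic assay arithmetic.

Spot-assay titers with limit-of-detection handling, efficiency of plating
(EoP) and its sensitivity categories, generalized-transduction frequency,
relative metabolic activity, log-scale summaries, and the competition-assay
calibration that maps gel band-intensity ratios to phage fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SpotCount",
    "Censored",
    "CompetitionCalibration",
    "EopResult",
    "titer_from_spot",
    "eop",
    "transduction_frequency",
    "relative_metabolic_activity",
    "log_scale_summary",
    "fit_competition_calibration",
    "estimate_cap_fraction",
]


@dataclass(frozen=True)
class Censored:
    """A left-censored value: observed below ``bound`` (printed as "< bound")."""

    bound: float

    def __str__(self) -> str:
        return f"< {self.bound:g}"


@dataclass(frozen=True)
class SpotCount:
    """Plaque count from one spotted dilution.

    ``dilution_exponent`` d means the plated dilution was 10^-d;
    ``spot_volume`` is in millilitres.  ``lod`` is the configured limit of
    detection (PFU/ml or PFU/g depending on the assay).
    """

    count: int
    dilution_exponent: int
    spot_volume: float
    lod: Optional[float] = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be nonnegative")
        if self.dilution_exponent < 0:
            raise ValueError("dilution exponent must be >= 0")
        if not self.spot_volume > 0:
            raise ValueError("spot volume must be positive")


@dataclass(frozen=True)
class CompetitionCalibration:
    """Fitted intensity-efficiency factor for the band-ratio model r = alpha (1-f)/f."""

    alpha: float
    residual: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class EopResult:
    ratio: Optional[float]
    category: str  # sensitive | reduced | resistant


def titer_from_spot(spot: SpotCount) -> "float | Censored":
    """Titer from one spot: count / (spot_volume * 10^-d).

    A zero count (at the lowest plated dilution) is censored at the
    configured LOD.
    """
    if spot.count == 0:
        if spot.lod is None:
            raise ValueError("zero count requires a configured LOD")
        return Censored(spot.lod)
    return spot.count / (spot.spot_volume * 10.0 ** (-spot.dilution_exponent))


def eop(
    titer_test: "float | Censored | None", titer_reference: float
) -> EopResult:
    """Efficiency of plating and its sensitivity category.

    ratio = titer_test / titer_reference.  A test lawn with no plaque
    formation (None or censored titer) is *resistant*; plaques with a
    log10 drop > 1 are *reduced*; anything else is *sensitive* (EoP similar
    to the reference strain).
    """
    if not titer_reference > 0:
        raise ValueError("reference titer must be positive")
    if titer_test is None or isinstance(titer_test, Censored):
        return EopResult(ratio=None, category="resistant")
    ratio = titer_test / titer_reference
    if ratio <= 0:
        return EopResult(ratio=None, category="resistant")
    category = "reduced" if math.log10(ratio) < -1.0 else "sensitive"
    return EopResult(ratio=ratio, category=category)


def transduction_frequency(
    transductants: int, lysate_titer: float
) -> "float | Censored":
    """Transductants divided by the transducing-lysate titer (PFU).

    Zero transductants give the censored detection bound "< 1/titer".
    """
    if not lysate_titer > 0:
        raise ValueError("lysate titer must be positive")
    if transductants < 0:
        raise ValueError("transductant count must be nonnegative")
    if transductants == 0:
        return Censored(1.0 / lysate_titer)
    return transductants / lysate_titer


def relative_metabolic_activity(
    signal_treated: float, signal_no_promoter_control: float
) -> float:
    """Treated signal as a percentage of the no-promoter control signal."""
    if not signal_no_promoter_control > 0:
        raise ValueError("control signal must be positive")
    return 100.0 * signal_treated / signal_no_promoter_control


def log_scale_summary(
    values: Iterable["float | Censored"],
) -> dict:
    """Mean and s.d. on the log10 scale, with the back-transformed mean.

    Censored values are imputed at their detection bound and flagged in the
    returned ``n_censored``.  The back-transformed mean 10^mean is the
    geometric mean of the (imputed) values.
    """
    resolved = []
    n_censored = 0
    for v in values:
        if isinstance(v, Censored):
            resolved.append(v.bound)
            n_censored += 1
        else:
            resolved.append(float(v))
    arr = np.asarray(resolved, dtype=float)
    if len(arr) == 0:
        raise ValueError("no values to summarize")
    if np.any(arr <= 0):
        raise ValueError("log-scale summary requires positive values")
    logs = np.log10(arr)
    mean = float(logs.mean())
    sd = float(logs.std(ddof=1)) if len(logs) > 1 else 0.0
    return {
        "log10_mean": mean,
        "log10_sd": sd,
        "back_transformed_mean": 10.0**mean,
        "n": len(arr),
        "n_censored": n_censored,
    }


def fit_competition_calibration(
    known_fractions: Sequence[float], observed_ratios: Sequence[float]
) -> CompetitionCalibration:
    """Fit the band-intensity model r = alpha (1-f)/f to calibration mixtures.

    ``known_fractions`` are the mixed-in CAP fractions f in (0, 1) and
    ``observed_ratios`` the measured WT/CAP band-intensity ratios r.  The
    fit is least squares on log r (variance-stabilizing for multiplicative
    densitometry noise), which gives the closed form
    log alpha = mean(log r - log((1-f)/f)).
    """
    f = np.asarray(known_fractions, dtype=float)
    r = np.asarray(observed_ratios, dtype=float)
    if len(f) != len(r):
        raise ValueError("fractions and ratios must align")
    usable = (f > 0) & (f < 1) & (r > 0)
    f, r = f[usable], r[usable]
    if len(np.unique(f)) < 2:
        raise ValueError("need >= 2 mixtures with distinct fractions in (0, 1)")
    log_alpha = np.log(r) - np.log((1.0 - f) / f)
    alpha = float(np.exp(log_alpha.mean()))
    residual = float(np.sum((log_alpha - log_alpha.mean()) ** 2))
    return CompetitionCalibration(alpha=alpha, residual=residual)


def estimate_cap_fraction(
    ratio_wt_over_cap: float, cal: CompetitionCalibration
) -> float:
    """CAP fraction of total phage from a WT/CAP band ratio.

    Inverts the calibration model: f = alpha / (alpha + r); r = 0 (no WT
    band) gives f = 1.
    """
    if ratio_wt_over_cap < 0:
        raise ValueError("ratio must be >= 0")
    return cal.alpha / (cal.alpha + ratio_wt_over_cap)
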