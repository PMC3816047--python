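"""Dose-response fitting and fixed-ratio combination analysis.

IC50 values are extracted with a four-parameter logistic (Hill) model fitted
on the log-dose axis. Drug combinations follow a fixed-ratio (ray) design:
each drug is dosed at a fraction of its own IC50, with the two fractions
summing to one. Under Loewe additivity such a mixture is exactly one
IC50-equivalent of "total drug", so the null expectation is 50% inhibition
for every mixing ratio; observed inhibition above the null indicates
synergy, below it antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseData",
    "HillFit",
    "MixtureDesign",
    "SynergyResult",
    "FitError",
    "hill_curve",
    "fit_hill",
    "additive_null",
    "inhibition_percent",
    "evaluate_mixture",
]

# Deterministic multi-start factors applied to the IC50 initial guess.
_IC50_STARTS = (0.3, 1.0, 3.0)


class FitError(RuntimeError):
    """Raised when the sigmoidal fit cannot be performed or fails to converge."""


@dataclass(frozen=True)
class DoseResponseData:
    """Doses (strictly positive) with matched responses; replicates optional.

    Responses may be raw readouts (vascular area, wound closure) or percent
    of control; the model is agnostic to units as long as a sigmoidal
    transition is present.
    """

    doses: np.ndarray
    responses: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if d.shape != r.shape or d.ndim != 1:
            raise ValueError("doses and responses must be matching 1-D arrays")
        if not np.all(d > 0):
            raise ValueError("doses must be strictly positive")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "responses", r)

    @property
    def n_distinct_doses(self) -> int:
        return np.unique(self.doses).size


@dataclass(frozen=True)
class HillFit:
    """Fitted four-parameter logistic: ic50, slope, asymptotes, residual SS.

    Canonical form has ``bottom <= top``; the sign of ``hill_slope`` then
    encodes whether the response falls (positive) or rises (negative) with
    dose. ``ic50_in_range`` is False when the fitted IC50 lies outside the
    tested dose span, which flags an extrapolated and therefore unreliable
    estimate.
    """

    ic50: float
    hill_slope: float
    top: float
    bottom: float
    rss: float
    ic50_in_range: bool = True


def hill_curve(
    dose: np.ndarray | float, bottom: float, top: float, ic50: float, slope: float
) -> np.ndarray:
    """Four-parameter logistic r(d) = bottom + (top - bottom) / (1 + (d/ic50)^slope)."""
    d = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (d / ic50) ** slope)


def _model_logdose(logd: np.ndarray, bottom: float, top: float, log_ic50: float, slope: float):
    # (d/ic50)^slope == 10 ** (slope * (log10 d - log10 ic50))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logd - log_ic50)))


def fit_hill(data: DoseResponseData) -> HillFit:
    """Least-squares four-parameter logistic fit on the log-dose axis.

    Initialised from the data (top = max response, bottom = min, IC50 = the
    geometric-mean dose) with a deterministic three-point multi-start on the
    IC50 guess (x0.3, x1, x3) to escape local minima; the best residual sum
    of squares wins. Degenerate inputs with no dose-dependent transition
    raise :class:`FitError`.
    """
    if data.n_distinct_doses < 4:
        raise FitError("need at least 4 distinct doses to fit a sigmoid")
    logd = np.log10(data.doses)
    r = data.responses
    span = float(r.max() - r.min())
    if span <= 1e-12 * max(1.0, abs(float(r.max()))):
        raise FitError("no transition detected: responses are constant")

    log_gm = float(logd.mean())
    best: tuple[float, np.ndarray] | None = None
    for factor in _IC50_STARTS:
        p0 = (float(r.min()), float(r.max()), log_gm + np.log10(factor), 1.0)
        try:
            popt, _ = curve_fit(_model_logdose, logd, r, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((r - _model_logdose(logd, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise FitError("sigmoidal fit did not converge from any start")

    rss, (bottom, top, log_ic50, slope) = best
    if bottom > top:  # canonicalise: swapping asymptotes and negating the slope
        bottom, top, slope = top, bottom, -slope  # leaves the curve unchanged
    ic50 = float(10.0**log_ic50)
    in_range = bool(data.doses.min() <= ic50 <= data.doses.max())
    return HillFit(
        ic50=ic50,
        hill_slope=float(slope),
        top=float(top),
        bottom=float(bottom),
        rss=rss,
        ic50_in_range=in_range,
    )


def additive_null(ratio: tuple[float, float]) -> float:
    """Loewe-additive inhibition (%) for a fixed-ratio IC50 mixture.

    With drug A at ``f_A x IC50_A`` and drug B at ``f_B x IC50_B`` and
    ``f_A + f_B = 1``, the mixture totals exactly one IC50-equivalent, so a
    purely additive interaction yields half-maximal (50%) inhibition at
    every point of the ratio simplex.
    """
    f_a, f_b = ratio
    if not (0.0 <= f_a <= 1.0 and 0.0 <= f_b <= 1.0):
        raise ValueError("ratio fractions must lie in [0, 1]")
    if abs(f_a + f_b - 1.0) > 1e-9:
        raise ValueError(f"ratio fractions must sum to 1, got {f_a + f_b}")
    return 50.0


def inhibition_percent(
    treated: Sequence[float], control: Sequence[float]
) -> np.ndarray:
    """Inhibition = 100 * (1 - treated / mean(control)).

    Maps both assay polarities (remaining vascular area, wound closure) onto
    a single scale where 0% means no effect and 100% means full inhibition.
    """
    control_arr = np.asarray(control, dtype=float)
    if control_arr.size == 0 or control_arr.mean() == 0:
        raise ValueError("control group empty or has zero mean")
    return 100.0 * (1.0 - np.asarray(treated, dtype=float) / control_arr.mean())


@dataclass(frozen=True)
class MixtureDesign:
    """Fixed-ratio design: per-ratio IC50 fractions and observed inhibition (%)."""

    ratios: tuple[tuple[float, float], ...]
    observed_inhibition_pct: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ratios) != len(self.observed_inhibition_pct):
            raise ValueError("one observed inhibition per ratio required")
        for f_a, f_b in self.ratios:
            additive_null((f_a, f_b))  # validates the simplex constraint


@dataclass(frozen=True)
class RatioVerdict:
    ratio: tuple[float, float]
    expected_pct: float
    observed_pct: float
    delta_pct: float
    verdict: str  # "synergistic" | "additive" | "antagonistic"


@dataclass(frozen=True)
class SynergyResult:
    """Per-ratio verdicts plus the ratio of maximal deviation from the null."""

    verdicts: tuple[RatioVerdict, ...]
    max_delta_ratio: tuple[float, float]
    max_delta_pct: float


def evaluate_mixture(design: MixtureDesign, tolerance_pct: float = 5.0) -> SynergyResult:
    """Compare observed mixture inhibitions with the additive 50% null.

    ``delta = observed - 50``; synergistic when delta exceeds the tolerance,
    antagonistic below minus the tolerance, additive within the margin. The
    tolerance stands in for replicate-level significance testing when raw
    replicates are unavailable.
    """
    if tolerance_pct < 0:
        raise ValueError("tolerance_pct must be non-negative")
    verdicts = []
    for ratio, observed in zip(design.ratios, design.observed_inhibition_pct):
        expected = additive_null(ratio)
        delta = observed - expected
        if delta > tolerance_pct:
            verdict = "synergistic"
        elif delta < -tolerance_pct:
            verdict = "antagonistic"
        else:
            verdict = "additive"
        verdicts.append(
            RatioVerdict(
                ratio=ratio,
                expected_pct=expected,
                observed_pct=float(observed),
                delta_pct=float(delta),
                verdict=verdict,
            )
        )
    best = max(verdicts, key=lambda v: abs(v.delta_pct))
    return SynergyResult(
        verdicts=tuple(verdicts),
        max_delta_ratio=best.ratio,
        max_delta_pct=best.delta_pct,
    )
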