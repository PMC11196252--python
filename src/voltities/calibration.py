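"""Linear calibration statistics, LOD/LOQ, standard addition and
interference screening.

Conventions
-----------
Concentrations are in micromolar and currents in microamperes, so a slope
in uA/uM is numerically identical to A M^-1 — the unit Table-style reports
quote.  Detection limits follow the calibration-curve definition

    LOD = 3 * SE_b / a        LOQ = 10 * SE_b / a

where ``a`` is the slope (A M^-1) and ``SE_b`` the standard error of the
regression intercept (uA); the quotient is then in uM.  LOQ/LOD = 10/3 by
construction.

Calibrations built on backward (negative) currents are handled by fitting
|I|: the detection limit is a magnitude statement, while the sign of the
process is preserved in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationResult",
    "InterferenceRecord",
    "StandardAdditionResult",
    "linear_calibration",
    "lod_loq",
    "lod_loq_from_stats",
    "normalize_slope",
    "standard_addition",
    "interference_effect",
    "SELECTIVITY_THRESHOLD_PCT",
]

#: a method counts as selective when an interferent changes the analyte
#: signal by no more than +-10 %
SELECTIVITY_THRESHOLD_PCT: float = 10.0


@dataclass
class CalibrationResult:
    """Ordinary-least-squares calibration with validation statistics.

    ``slope``/``intercept`` keep the sign of the fitted currents;
    ``lod``/``loq`` are computed from magnitudes and satisfy
    ``loq = (10/3) * lod`` exactly.  ``ldr`` is the fitted concentration
    span (an annotation, not a detected linearity breakpoint).
    """

    slope: float  # A M^-1 (== uA/uM)
    intercept: float  # uA
    se_slope: float  # A M^-1
    se_intercept: float  # uA
    r2: float
    n_points: int
    ldr: tuple[float, float]  # uM
    lod: float  # uM
    loq: float  # uM
    normalized_slope: float | None = None  # A M^-1 cm^-2

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1.0 + 1e-9):
            raise ValueError(f"R^2 must lie in [0, 1], got {self.r2}")
        if self.lod > 0 and not math.isclose(
            self.loq / self.lod, 10.0 / 3.0, rel_tol=1e-12
        ):
            raise ValueError("LOQ/LOD must equal 10/3 exactly")

    def as_dict(self) -> dict:
        return {
            "slope_A_per_M": self.slope,
            "intercept_uA": self.intercept,
            "se_slope_A_per_M": self.se_slope,
            "se_intercept_uA": self.se_intercept,
            "r2": self.r2,
            "n_points": self.n_points,
            "ldr_uM": list(self.ldr),
            "lod_uM": self.lod,
            "loq_uM": self.loq,
            "normalized_slope_A_per_M_cm2": self.normalized_slope,
        }


def linear_calibration(
    concentrations, currents, area: float | None = None
) -> CalibrationResult:
    """Fit peak current against concentration by ordinary least squares.

    Standard errors of slope and intercept are the usual regression
    standard errors; LOD/LOQ use the magnitude of the slope so that
    negative-current (backward-transfer) calibrations are handled
    symmetrically.  If ``area`` (cm^2) is given the area-normalized slope
    is included.
    """
    x = np.asarray(list(concentrations), dtype=float)
    y = np.asarray(list(currents), dtype=float)
    if x.size != y.size:
        raise ValueError("concentration and current lengths differ")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero concentration variance: all levels equal")
    fit = stats.linregress(x, y)
    lod, loq = lod_loq_from_stats(abs(fit.slope), fit.intercept_stderr)
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        se_slope=float(fit.stderr),
        se_intercept=float(fit.intercept_stderr),
        r2=float(fit.rvalue**2),
        n_points=int(x.size),
        ldr=(float(x.min()), float(x.max())),
        lod=lod,
        loq=loq,
        normalized_slope=None if area is None else normalize_slope(fit.slope, area),
    )


def lod_loq_from_stats(slope: float, se_intercept: float) -> tuple[float, float]:
    """LOD and LOQ (uM) from a slope (A M^-1) and intercept error (uA).

    LOD = 3*SE_b/a, LOQ = 10*SE_b/a; with SE_b in uA and a in A M^-1 the
    ratio lands directly in 1e-6 M.
    """
    if slope <= 0:
        raise ValueError(f"slope must be > 0, got {slope}")
    if se_intercept < 0:
        raise ValueError("intercept standard error must be >= 0")
    lod = 3.0 * se_intercept / slope
    return lod, lod * (10.0 / 3.0)


def lod_loq(result: CalibrationResult) -> tuple[float, float]:
    """Detection and quantification limits of a fitted calibration, uM."""
    return lod_loq_from_stats(result.slope, result.se_intercept)


def normalize_slope(slope: float, area: float) -> float:
    """Sensitivity per unit electrode/interface area, A M^-1 cm^-2."""
    if area <= 0:
        raise ValueError(f"area must be > 0 cm^2, got {area}")
    return slope / area


@dataclass
class StandardAdditionResult:
    """Outcome of a standard-addition extrapolation."""

    concentration: float  # uM, |x-intercept| of the addition line
    se: float  # uM, propagated from the regression
    slope: float  # uA per uM in the matrix (suppressed sensitivity)
    intercept: float  # uA
    r2: float


def standard_addition(signals, added_concentrations) -> StandardAdditionResult:
    """Estimate the original analyte concentration by standard addition.

    Regresses signal on added concentration and extrapolates to zero
    signal: the estimate is intercept/slope (the x-intercept magnitude).
    Any multiplicative matrix effect scales slope and intercept alike and
    cancels, which is the whole point of the method.  The standard error
    follows the usual x-intercept propagation

        SE = (s_y/|a|) * sqrt(1/n + ybar^2 / (a^2 * Sxx)).
    """
    y = np.asarray(list(signals), dtype=float)
    x = np.asarray(list(added_concentrations), dtype=float)
    if x.size != y.size:
        raise ValueError("signals and additions lengths differ")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise ValueError(
            f"standard addition requires a positive slope, got {fit.slope:.3g}"
        )
    c0 = fit.intercept / fit.slope
    n = x.size
    resid = y - (fit.intercept + fit.slope * x)
    dof = max(n - 2, 1)
    s_y = float(np.sqrt(np.sum(resid**2) / dof))
    sxx = float(np.sum((x - x.mean()) ** 2))
    se = (s_y / fit.slope) * math.sqrt(1.0 / n + y.mean() ** 2 / (fit.slope**2 * sxx))
    return StandardAdditionResult(
        concentration=float(c0),
        se=float(se),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
    )


@dataclass
class InterferenceRecord:
    """Signal change caused by one interfering agent at one concentration."""

    interferent: str
    concentration: float  # uM
    signal_change: float  # percent, signed
    selective: bool

    def __post_init__(self) -> None:
        if self.selective != (abs(self.signal_change) <= SELECTIVITY_THRESHOLD_PCT):
            raise ValueError(
                "selective flag inconsistent with the +-10 % threshold"
            )


def interference_effect(
    reference_signal: float,
    signal_with_ia: float,
    interferent: str = "",
    concentration: float = float("nan"),
) -> InterferenceRecord:
    """Relative signal change caused by an interfering agent.

    ``signal_change = 100 * (signal_with_ia - reference) / reference``;
    the method is selective towards this interferent level when the
    change does not exceed +-10 %.
    """
    if reference_signal == 0:
        raise ValueError("reference signal must be nonzero")
    change = 100.0 * (signal_with_ia - reference_signal) / reference_signal
    return InterferenceRecord(
        interferent=interferent,
        concentration=concentration,
        signal_change=float(change),
        selective=bool(abs(change) <= SELECTIVITY_THRESHOLD_PCT),
    )
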