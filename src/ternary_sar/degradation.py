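"""Cellular degradation data reduction: POC, 4PL dose response, AUC, decay.

Measurements arrive as percent-of-control (POC): background-subtracted
assay signal divided by vehicle-control signal, times 100.  Dose-response
curves (1:3 titrations) are fitted with the variable-slope four-parameter
logistic on log10 concentration to obtain DC50 (dose at 50 POC) and Dmax;
the area under the POC-vs-dose-index curve (unit-spacing trapezoids) is a
fit-free potency/efficacy summary — a 10-point non-degrader pinned at 100
POC scores 900, and deeper degradation lowers the score.  Time courses are
fitted with a one-phase exponential decay; the half-life is the time the
fitted curve crosses 50 POC, and the initial degradation rate is
100 * (0.693 / t_half) in %/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = [
    "DoseResponseCurve",
    "DoseResponseFit",
    "TimeCourseFit",
    "normalize_poc",
    "auc_trapezoid",
    "fit_dose_response",
    "fit_time_course",
]

#: ln 2 rounded to the three digits conventionally used in the rate
#: definition tau = 0.693 / t_half; kept literal so
#: initial_rate * t_half == 69.3 holds exactly.
LN2_CONVENTION = 0.693


class DegradationError(ValueError):
    """Invalid degradation-assay input."""


def normalize_poc(signal: float, background: float, vehicle: float) -> float:
    """Percent of control: 100 * (signal - background) / (vehicle - background)."""
    if not vehicle > background:
        raise DegradationError(
            f"vehicle signal ({vehicle}) must exceed background ({background})"
        )
    return 100.0 * (signal - background) / (vehicle - background)


def auc_trapezoid(poc) -> float:
    """Area under the POC curve with unit spacing between dose indices.

    Sum over adjacent points of (b1 + b2)/2 with h = 1; invariant to
    reversing the dose order.
    """
    y = np.asarray(poc, float)
    if y.ndim != 1 or y.size < 2:
        raise DegradationError("need >= 2 POC points")
    if not np.all(np.isfinite(y)):
        raise DegradationError("POC values must be finite")
    return float(np.sum((y[:-1] + y[1:]) / 2.0))


@dataclass(frozen=True)
class DoseResponseCurve:
    """One compound's POC titration (replicate-averaged)."""

    conc_nM: np.ndarray
    poc: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.conc_nM, float)
        y = np.asarray(self.poc, float)
        if c.shape != y.shape or c.ndim != 1:
            raise DegradationError("conc and poc must be matching 1-D arrays")
        d = np.diff(c)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise DegradationError("concentrations must be strictly monotone")
        if np.any(c <= 0):
            raise DegradationError("concentrations must be positive")
        if not np.all(np.isfinite(y)):
            raise DegradationError("POC must be finite")
        # store ascending
        if d[0] < 0:
            c, y = c[::-1], y[::-1]
        object.__setattr__(self, "conc_nM", c)
        object.__setattr__(self, "poc", y)

    @property
    def n_points(self) -> int:
        return int(self.conc_nM.size)


@dataclass(frozen=True)
class DoseResponseFit:
    """4PL fit summary.

    ``dc50_nM`` is None when the fitted curve never reaches 50 POC inside
    the tested range (render as "> top-tested").  ``dmax`` follows the
    convention 100 - min(fitted bottom, observed minimum); the two inputs
    to that min are also reported separately.
    """

    dc50_nM: float | None
    dmax: float
    hill: float
    top: float
    bottom: float
    auc: float
    dmax_fitted: float
    dmax_observed: float
    censored_above_nM: float | None = None
    message: str = ""

    @property
    def dc50_label(self) -> str:
        if self.dc50_nM is not None:
            return f"{self.dc50_nM:g}"
        return f">{self.censored_above_nM:g}" if self.censored_above_nM else "NA"


def _four_pl(logc, top, bottom, log_dc50, hill):
    # GraphPad "log(inhibitor) vs response - variable slope" convention
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_dc50)))


def fit_dose_response(
    curve: DoseResponseCurve, *, mask_top_doses: int = 0
) -> DoseResponseFit:
    """Variable-slope 4PL fit on log10 concentration.

    ``mask_top_doses`` drops the m highest doses from the fit (hook-effect
    distortion) while the AUC is always computed on the full observed
    curve.  Non-convergence returns a censored fit with diagnostics rather
    than raising.
    """
    if curve.n_points < 5:
        raise DegradationError("need >= 5 dose points for a 4PL fit")
    if mask_top_doses < 0 or curve.n_points - mask_top_doses < 5:
        raise DegradationError("mask leaves fewer than 5 points")
    auc = auc_trapezoid(curve.poc)
    c = curve.conc_nM[: curve.n_points - mask_top_doses or None]
    y = curve.poc[: curve.n_points - mask_top_doses or None]
    logc = np.log10(c)
    top_conc = float(curve.conc_nM[-1])
    observed_min = float(np.min(curve.poc))

    params = lmfit.Parameters()
    params.add("top", value=float(np.max(y)), min=-50, max=250)
    params.add("bottom", value=float(np.min(y)), min=-50, max=250)
    params.add("log_dc50", value=float(np.median(logc)),
               min=float(logc[0]) - 3, max=float(logc[-1]) + 3)
    # sign convention: positive hill drives the curve down toward `bottom`
    # at high dose; start on the side the data indicate to avoid the
    # flat hill=0 saddle
    hill0 = 1.0 if y[0] >= y[-1] else -1.0
    params.add("hill", value=hill0, min=-10, max=10)

    def residual(p):
        return _four_pl(logc, p["top"].value, p["bottom"].value,
                        p["log_dc50"].value, p["hill"].value) - y

    result = lmfit.minimize(residual, params, method="least_squares")
    top = result.params["top"].value
    bottom = result.params["bottom"].value
    hill = result.params["hill"].value
    log_ec50 = result.params["log_dc50"].value

    def build(dc50, censored, msg=""):
        dmax_fit = float(np.clip(100.0 - min(bottom, top), 0.0, 100.0))
        dmax_obs = float(np.clip(100.0 - observed_min, 0.0, 100.0))
        dmax = float(np.clip(100.0 - min(bottom, observed_min), 0.0, 100.0))
        return DoseResponseFit(
            dc50_nM=dc50, dmax=dmax,
            hill=hill, top=top, bottom=bottom, auc=auc,
            dmax_fitted=dmax_fit, dmax_observed=dmax_obs,
            censored_above_nM=censored, message=msg,
        )

    if not result.success:
        return build(None, top_conc, f"fit did not converge: {result.message}")

    # dose at which the fitted curve crosses 50 POC, solved on the 4PL
    lo, hi = (bottom, top) if bottom < top else (top, bottom)
    if not (lo < 50.0 < hi):
        return build(None, top_conc, "fitted curve never crosses 50 POC")
    frac = (top - bottom) / (50.0 - bottom) - 1.0
    if frac <= 0 or hill == 0:
        return build(None, top_conc, "degenerate 4PL geometry at 50 POC")
    log_dc50 = log_ec50 + math.log10(frac) / hill
    if log_dc50 > math.log10(top_conc):
        return build(None, top_conc, "50 POC crossing above tested range")
    return build(10.0 ** log_dc50, None)


@dataclass(frozen=True)
class TimeCourseFit:
    """One-phase decay fit summary.

    ``t_half_min`` is the time the fitted curve crosses 50 POC (None when
    the fitted plateau sits at or above 50 POC); ``tau`` and
    ``initial_rate`` follow the conventions tau = 0.693/t_half and
    initial_rate = 100 * tau.
    """

    k: float
    plateau: float
    span: float
    t_half_min: float | None
    message: str = ""

    @property
    def tau(self) -> float | None:
        return None if self.t_half_min is None else LN2_CONVENTION / self.t_half_min

    @property
    def initial_rate(self) -> float | None:
        """Initial degradation rate, %/min."""
        return None if self.tau is None else 100.0 * self.tau


def fit_time_course(times_min, poc) -> TimeCourseFit:
    """One-phase decay fit POC(t) = span * exp(-k t) + plateau.

    The 50-POC crossing is interpolated on the fitted curve in closed
    form: t_half = ln(span / (50 - plateau)) / k.
    """
    t = np.asarray(times_min, float)
    y = np.asarray(poc, float)
    if t.shape != y.shape or t.ndim != 1 or t.size < 4:
        raise DegradationError("need >= 4 matched (time, POC) points")
    if np.any(np.diff(t) <= 0):
        raise DegradationError("times must be strictly increasing")

    params = lmfit.Parameters()
    params.add("plateau", value=float(np.min(y)), min=-50, max=150)
    params.add("span", value=float(y[0] - np.min(y)), min=0.0)
    k0 = 1.0 / max(float(t[-1] - t[0]) / 3.0, 1e-6)
    params.add("k", value=k0, min=1e-8, max=1e4)

    def residual(p):
        return p["span"].value * np.exp(-p["k"].value * t) + p["plateau"].value - y

    result = lmfit.minimize(residual, params, method="least_squares")
    k = result.params["k"].value
    plateau = result.params["plateau"].value
    span = result.params["span"].value
    if not result.success:
        return TimeCourseFit(k, plateau, span, None,
                             f"fit did not converge: {result.message}")
    start = span + plateau
    if plateau >= 50.0 or start <= 50.0:
        return TimeCourseFit(
            k, plateau, span, None,
            f"fitted curve never crosses 50 POC (plateau={plateau:.1f})",
        )
    t_half = math.log(span / (50.0 - plateau)) / k
    return TimeCourseFit(k, plateau, span, t_half)
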