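"""Fits for initiation/decoding kinetics and toeprint binding isotherms.

Three quantitative models:

* dipeptide-formation time courses, fit with the single-exponential burst
  ``y = A*(1 - exp(-k t))`` whose rate constant is the apparent rate
  ``k_app`` (min^-1);
* Arrhenius series, fit by ordinary least squares of ``ln k`` on ``1/T``
  with activation energy ``E_a = -slope * R`` (kcal/mol,
  R = 1.987e-3 kcal mol^-1 K^-1);
* 70S/30S toeprint titrations, fit to ``F = Fmax*bc/(bc + 1/KA)`` where
  ``b`` is the input tRNA concentration, ``c`` the ribosome or subunit
  concentration (both μM) and ``K_A`` an overall association constant in
  μM^-2.  When every point sits on the plateau (``bc*KA > 10``
  throughout) the curve carries almost no information about ``K_A`` and
  the fit is flagged saturated.

Nonlinear fits use Levenberg-Marquardt least squares from three
deterministic data-derived starts; standard errors come from the fit
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "R_KCAL",
    "TimeCourse",
    "BindingCurve",
    "ArrheniusSeries",
    "FitResult",
    "FitError",
    "fit_time_course",
    "fit_arrhenius",
    "fit_binding",
]

R_KCAL = 1.987e-3  # gas constant, kcal mol^-1 K^-1


class FitError(RuntimeError):
    """Degenerate input or non-convergent fit."""


@dataclass(frozen=True)
class TimeCourse:
    t: np.ndarray  # minutes
    y: np.ndarray  # product fraction

    def __post_init__(self) -> None:
        t, y = np.asarray(self.t, float), np.asarray(self.y, float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.shape != y.shape:
            raise ValueError("t and y must have the same length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(y < 0):
            raise ValueError("signal must be non-negative")


@dataclass(frozen=True)
class BindingCurve:
    b: np.ndarray  # input tRNA concentrations, μM
    c: float  # input ribosome/subunit concentration, μM
    F: np.ndarray  # fraction of mRNA bound

    def __post_init__(self) -> None:
        b, F = np.asarray(self.b, float), np.asarray(self.F, float)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "F", F)
        if b.shape != F.shape:
            raise ValueError("b and F must have the same length")
        if self.c <= 0 or np.any(b < 0):
            raise ValueError("concentrations must be positive")
        if np.any((F < 0) | (F > 1)):
            raise ValueError("F must lie in [0, 1]")


@dataclass(frozen=True)
class ArrheniusSeries:
    T: np.ndarray  # kelvin
    k_app: np.ndarray  # min^-1

    def __post_init__(self) -> None:
        T, k = np.asarray(self.T, float), np.asarray(self.k_app, float)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "k_app", k)
        if T.shape != k.shape:
            raise ValueError("T and k_app must have the same length")
        if np.any(T <= 0) or np.any(k <= 0):
            raise ValueError("temperatures and rates must be positive")


@dataclass(frozen=True)
class FitResult:
    model: str
    params: dict  # name -> estimate
    se: dict  # name -> standard error
    rss: float
    flags: tuple = field(default=())

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def _exp_burst(t, amplitude, k):
    return amplitude * (1.0 - np.exp(-k * t))


def _multistart_fit(model, x, y, starts, bounds):
    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitError("no start converged")
    return best


def fit_time_course(tc: TimeCourse) -> FitResult:
    """Fit ``y = A*(1 - exp(-k t))``; returns k_app (min^-1) and amplitude."""
    t, y = tc.t, tc.y
    if len(t) < 3 or np.allclose(y, y[0]):
        raise FitError("need at least 3 points with signal variation")
    amp0 = max(float(y.max()), 1e-6)
    # rate heuristics: initial slope / amplitude, and half-rise time
    dt = t[1] - t[0] if t[0] == 0 else t[0]
    k_slope = max(float(y[1] - y[0]) / (dt * amp0), 1e-3) if len(t) > 1 else 1.0
    above = t[y >= 0.5 * amp0]
    k_half = np.log(2.0) / float(above[0]) if len(above) and above[0] > 0 else 1.0
    starts = [(amp0, k_slope), (amp0, k_half), (amp0, 1.0)]
    popt, pcov, rss = _multistart_fit(
        _exp_burst, t, y, starts, bounds=([0.0, 0.0], [np.inf, np.inf])
    )
    se = np.sqrt(np.diag(pcov))
    if not np.isfinite(popt[1]) or popt[1] <= 0:
        raise FitError("rate estimate at bound")
    return FitResult(
        model="single_exponential",
        params={"amplitude": float(popt[0]), "k_app": float(popt[1])},
        se={"amplitude": float(se[0]), "k_app": float(se[1])},
        rss=rss,
    )


def fit_arrhenius(series: ArrheniusSeries) -> FitResult:
    """OLS of ln(k_app) on 1/T; E_a = -slope*R in kcal/mol."""
    T, k = series.T, series.k_app
    if len(np.unique(T)) < 2:
        raise FitError("need at least two distinct temperatures")
    res = linregress(1.0 / T, np.log(k))
    e_a = -res.slope * R_KCAL
    se_e_a = (res.stderr or 0.0) * R_KCAL
    fitted = res.intercept + res.slope / T
    rss = float(np.sum((np.log(k) - fitted) ** 2))
    return FitResult(
        model="arrhenius",
        params={"E_a": float(e_a), "ln_prefactor": float(res.intercept)},
        se={"E_a": float(se_e_a), "ln_prefactor": float(res.intercept_stderr or 0.0)},
        rss=rss,
    )


def fit_binding(curve: BindingCurve, saturation_ratio: float = 10.0) -> FitResult:
    """Fit ``F = Fmax*bc/(bc + 1/KA)``; K_A in μM^-2, F_max dimensionless."""
    b, c, F = curve.b, curve.c, curve.F
    if len(np.unique(b)) < 3:
        raise FitError("need at least three distinct b values")
    if np.all(F < 1e-3):
        raise FitError("no binding signal")

    def model(bb, f_max, k_a):
        return f_max * (bb * c) / (bb * c + 1.0 / k_a)

    f0 = min(max(float(F.max()), 1e-3), 1.0)
    # K_A heuristic from the half-max crossing: bc = 1/K_A at F = Fmax/2
    half = np.argmin(np.abs(F - 0.5 * f0))
    bc_half = max(float(b[half] * c), 1e-6)
    starts = [(f0, 1.0 / bc_half), (f0, 1.0), (f0, 100.0)]
    popt, pcov, rss = _multistart_fit(
        model, b, F, starts, bounds=([0.0, 1e-9], [1.0, np.inf])
    )
    se = np.sqrt(np.diag(pcov))
    flags = []
    if np.all(b[b > 0] * c * popt[1] > saturation_ratio):
        flags.append("saturated")  # K_A only roughly constrained
    return FitResult(
        model="binding_isotherm",
        params={"F_max": float(popt[0]), "K_A": float(popt[1])},
        se={"F_max": float(se[0]), "K_A": float(se[1])},
        rss=rss,
        flags=tuple(flags),
    )
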