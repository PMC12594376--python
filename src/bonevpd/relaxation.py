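"""Viscous calibration from stress-relaxation curves.

Experimental relaxation data for bone are mostly limited to the elastic
range, so the viscous part of the model is calibrated indirectly: each
normalized relaxation curve s(t) is fitted with a power law s = a t^-b in
log-log space, the fitted law is extrapolated to a long-time horizon
(1e6 s) to estimate the percentage stress reduction at equilibrium, the
per-curve percentages are averaged, and the resulting mean fraction scales
the calibrated uniaxial yield strains down to their equilibrium values
(the yield surface of the infinitely-slow, overstress-free response).

The literature reduction percentages used by the calibration are shipped as
:data:`LITERATURE_REDUCTIONS`; their mean rounds to 24%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .parameters import ParameterError, YieldParameters

__all__ = [
    "RelaxationSeries",
    "PowerLawFit",
    "fit_power_law",
    "stress_reduction",
    "mean_reduction",
    "scale_yield_parameters",
    "LITERATURE_REDUCTIONS",
]

# Percentage stress reductions at the 1e6 s horizon, one per literature
# relaxation curve (labels as published; the label I3 appears twice).
LITERATURE_REDUCTIONS: tuple[tuple[str, float], ...] = (
    ("Q1", 27.0),
    ("Q2", 23.0),
    ("Q3", 24.0),
    ("Q4", 9.0),
    ("Q5", 3.0),
    ("P", 39.0),
    ("I3", 62.0),
    ("I2", 25.0),
    ("I3", 7.0),
)


@dataclass
class RelaxationSeries:
    """A normalized stress-relaxation record: s(t) with t in seconds.

    Times must be positive (the fit is performed on logarithms); the series
    is sorted by time at construction.  A non-monotone series (noise) only
    triggers a warning.
    """

    t: np.ndarray
    s: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.s = np.asarray(self.s, dtype=float).ravel()
        if self.t.size != self.s.size or self.t.size < 3:
            raise ParameterError("series needs at least 3 (t, s) pairs")
        if np.any(self.t <= 0) or np.any(self.s <= 0):
            raise ParameterError("times and stresses must be positive")
        order = np.argsort(self.t)
        self.t = self.t[order]
        self.s = self.s[order]
        if np.any(np.diff(self.t) <= 0):
            raise ParameterError("times must be distinct")
        if np.any(np.diff(self.s) > 0):
            warnings.warn(
                f"relaxation series {self.label or '<unnamed>'} is not monotone "
                "non-increasing (noise?)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted s(t) = a t^-b with the log-space residual sum of squares."""

    a: float
    b: float
    rss: float

    def __call__(self, t) -> np.ndarray:
        return self.a * np.asarray(t, dtype=float) ** (-self.b)


def fit_power_law(series: RelaxationSeries) -> PowerLawFit:
    """Least-squares fit of s(t) = a t^-b in log-log space.

    Linear regression of log s on log t; the slope is -b and the intercept
    log a.  The fit is scale-equivariant: scaling s by c scales a by c and
    leaves b unchanged.
    """
    x = np.log(series.t)
    y = np.log(series.s)
    (slope, intercept), res = np.polyfit(x, y, 1, full=True)[:2]
    rss = float(res[0]) if res.size else 0.0
    return PowerLawFit(a=float(np.exp(intercept)), b=float(-slope), rss=rss)


def stress_reduction(fit: PowerLawFit, t_ref: float, horizon: float = 1e6) -> float:
    """Percentage stress reduction between t_ref and the horizon.

    100 (1 - s(horizon)/s(t_ref)) under the fitted law; a pure power law has
    no finite nonzero asymptote, so the stated 1e6 s horizon operationalizes
    the "asymptotic" value.  Clipped to [0, 100].
    """
    if not horizon > t_ref > 0:
        raise ParameterError("need horizon > t_ref > 0")
    ratio = (horizon / t_ref) ** (-fit.b)
    return float(np.clip(100.0 * (1.0 - ratio), 0.0, 100.0))


def mean_reduction(reductions) -> float:
    """Mean of percentage reductions, as a fraction of 1.

    The arithmetic mean is rounded to the nearest integer percent before
    conversion (the calibration works with whole-percent reductions), e.g.
    the nine literature values average 24.33% and yield 0.24.
    """
    reductions = np.asarray(list(reductions), dtype=float)
    if reductions.size == 0:
        raise ParameterError("empty reduction list")
    return round(float(reductions.mean())) / 100.0


def scale_yield_parameters(yp: YieldParameters, fraction: float) -> YieldParameters:
    """Scale the uniaxial yield strains by ``fraction`` (equilibrium set).

    Despite the name "reduction", the equilibrium yield strains equal the
    calibrated ones multiplied by the mean-reduction fraction; interaction
    coefficient and fabric vectors are untouched.
    """
    if not 0.0 < fraction <= 1.0:
        raise ParameterError("fraction must lie in (0, 1]")
    return replace(yp, eps0p=yp.eps0p * fraction, eps0m=yp.eps0m * fraction)
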