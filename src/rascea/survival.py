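"""Closed-form Weibull survival machinery.

Each time-to-event endpoint (progression-free survival or overall survival,
one per treatment arm) is summarised by a two-parameter Weibull law

    S(u) = exp(-scale * u ** shape)

where ``u`` is time expressed in the curve's *native* unit.  The shape
parameter governs how the hazard evolves: shape > 1 gives a hazard that
rises with time (typical for progression and death in advanced cancer),
shape = 1 reduces to the exponential law.  The scale parameter is tied to
the native time unit, which is why the unit travels with the curve rather
than being a global convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad

__all__ = [
    "TIME_UNITS",
    "UNITS_PER_YEAR",
    "WeibullCurve",
    "CurveBook",
    "survival_at",
    "median_time",
    "restricted_mean",
    "per_cycle_event_prob",
    "rescale_to_median",
]

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375  # DAYS_PER_YEAR / 12

#: native units per year, the single place unit conversions are defined
UNITS_PER_YEAR = {
    "day": DAYS_PER_YEAR,
    "week": DAYS_PER_YEAR / 7.0,       # 52.1786
    "cycle_14d": DAYS_PER_YEAR / 14.0,  # 26.0893
    "month": 12.0,
    "year": 1.0,
}

TIME_UNITS = tuple(UNITS_PER_YEAR)


@dataclass(frozen=True)
class WeibullCurve:
    """One endpoint/arm survival law.

    Parameters
    ----------
    scale : float
        Weibull scale (lambda), per native-unit**shape.  Must be positive.
    shape : float
        Weibull shape (gamma), dimensionless.  Must be positive.
    time_unit : str
        Native unit of the time axis; one of :data:`TIME_UNITS`.
    label : str
        Free text identifying endpoint and arm.
    """

    scale: float
    shape: float
    time_unit: str = "cycle_14d"
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"scale must be a positive finite number, got {self.scale}")
        if not (self.shape > 0 and math.isfinite(self.shape)):
            raise ValueError(f"shape must be a positive finite number, got {self.shape}")
        if self.time_unit not in UNITS_PER_YEAR:
            raise ValueError(
                f"time_unit {self.time_unit!r} not one of {sorted(UNITS_PER_YEAR)}"
            )

    @property
    def units_per_year(self) -> float:
        return UNITS_PER_YEAR[self.time_unit]


@dataclass(frozen=True)
class CurveBook:
    """The four survival curves driving a two-arm comparison."""

    pfs_control: WeibullCurve
    pfs_cetuximab: WeibullCurve
    os_control: WeibullCurve
    os_cetuximab: WeibullCurve

    def for_arm(self, arm: str) -> tuple[WeibullCurve, WeibullCurve]:
        """Return (PFS, OS) curves for ``arm`` in {'control', 'cetuximab'}."""
        if arm == "control":
            return self.pfs_control, self.os_control
        if arm == "cetuximab":
            return self.pfs_cetuximab, self.os_cetuximab
        raise ValueError(f"unknown arm {arm!r}")


def survival_at(curve: WeibullCurve, t):
    """Survival probability at time ``t`` (years).  Vectorised over ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival_at requires t >= 0")
    u = t * curve.units_per_year
    out = np.exp(-curve.scale * u**curve.shape)
    return float(out) if out.ndim == 0 else out


def median_time(curve: WeibullCurve) -> float:
    """Time (years) at which survival crosses 0.5: (ln 2 / scale)**(1/shape)."""
    u_med = (math.log(2.0) / curve.scale) ** (1.0 / curve.shape)
    return u_med / curve.units_per_year


def restricted_mean(
    curve: WeibullCurve, horizon: float, discount_rate: float = 0.0
) -> float:
    """Discounted restricted mean survival time in years over [0, horizon].

    Integrates S(t) * (1 + r)^(-t) with deterministic adaptive quadrature.
    With r = 0 and a long horizon this converges to
    scale**(-1/shape) * Gamma(1 + 1/shape) native units, the Weibull mean.
    """
    if not (math.isfinite(horizon) and horizon > 0):
        raise ValueError("horizon must be positive and finite")
    if not (0 <= discount_rate < 1) or not math.isfinite(discount_rate):
        raise ValueError("discount_rate must lie in [0, 1)")
    # the integrand is negligible once -ln S exceeds ~37 (S < 1e-16), so the
    # quadrature range is capped there; adaptive quadrature then handles both
    # the possible cusp at t=0 (shape < 1) and slowly decaying tails
    u_tail = (37.0 / curve.scale) ** (1.0 / curve.shape)
    t_max = min(horizon, u_tail / curve.units_per_year)
    value, _ = quad(
        lambda t: survival_at(curve, t) * (1.0 + discount_rate) ** (-t),
        0.0, t_max, limit=500, epsabs=1e-12, epsrel=1e-10,
    )
    return float(value)


_underflow_logged = False


def per_cycle_event_prob(
    curve: WeibullCurve, cycle_index: int, cycle_length_days: float = 14.0
) -> float:
    """Conditional event probability over cycle ``cycle_index``.

    Returns 1 - S(t_{k+1}) / S(t_k) on the cycle grid.  For shape > 1 this
    sequence is nondecreasing in k (increasing hazard).  Deep in the tail,
    where S underflows, the cycle is treated as absorbing.
    """
    global _underflow_logged
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    dt = cycle_length_days / DAYS_PER_YEAR
    s0 = survival_at(curve, cycle_index * dt)
    if s0 < 1e-300:
        if not _underflow_logged:
            log.warning(
                "survival underflow at cycle %d for %s; treating as absorbing",
                cycle_index, curve.label or "curve",
            )
            _underflow_logged = True
        return 1.0
    s1 = survival_at(curve, (cycle_index + 1) * dt)
    return min(1.0, max(0.0, 1.0 - s1 / s0))


def rescale_to_median(curve: WeibullCurve, new_median: float) -> WeibullCurve:
    """Return a curve with the same shape whose median equals ``new_median`` years.

    Used by one-way sensitivity analysis, which perturbs a curve through its
    median survival time rather than through the (unitful, unintuitive)
    scale parameter.
    """
    if not (new_median > 0 and math.isfinite(new_median)):
        raise ValueError("new_median must be positive and finite")
    u_med = new_median * curve.units_per_year
    new_scale = math.log(2.0) / u_med**curve.shape
    return replace(curve, scale=new_scale)
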