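"""Endpoints: life-years, QALYs, incremental cost-effectiveness ratios.

QALYs weight state occupancy by health-state utilities.  The progressed
state carries different utilities under follow-on chemotherapy/supportive
care versus follow-on targeted therapy; the intervention arm applies a
configurable blend of the two (the fraction receiving targeted follow-on
therapy), which is fixed once by calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import CohortTrace, ModelConfig, _integrate, state_years

__all__ = [
    "UtilityBook",
    "StrategyResult",
    "Comparison",
    "qalys",
    "icer",
    "net_monetary_benefit",
]


@dataclass(frozen=True)
class UtilityBook:
    """Health-state utility weights in [0, 1]."""

    u_pfs: float = 0.85
    u_pd_chemo: float = 0.24
    u_pd_targeted: float = 0.68
    pd_targeted_fraction_cetux_arm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u_pfs", "u_pd_chemo", "u_pd_targeted",
                     "pd_targeted_fraction_cetux_arm"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def u_pd(self, arm: str) -> float:
        """Progressed-state utility for ``arm``."""
        if arm == "control":
            return self.u_pd_chemo
        if arm == "cetuximab":
            f = self.pd_targeted_fraction_cetux_arm
            return (1.0 - f) * self.u_pd_chemo + f * self.u_pd_targeted
        raise ValueError(f"unknown arm {arm!r}")


@dataclass(frozen=True)
class StrategyResult:
    """Totals for one strategy: cost and (dis)counted effect endpoints."""

    name: str
    cost: float
    pf_ly: float
    total_ly: float
    qaly: float


@dataclass(frozen=True)
class Comparison:
    """Pairwise incremental results, intervention minus comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    delta_pf_ly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    dominance: str  # none | intervention_dominates | comparator_dominates


def qalys(
    trace: CohortTrace, arm: str, utilities: UtilityBook, config: ModelConfig
) -> float:
    """Discounted quality-adjusted life-years for one arm's trace."""
    u_pd = utilities.u_pd(arm)
    values = (trace.pf * utilities.u_pfs + trace.pd * u_pd) * trace.df
    return _integrate(values, trace)


def icer(intervention: StrategyResult, comparator: StrategyResult) -> Comparison:
    """Incremental ratios with dominance handling.

    Ratios are reported only when neither strategy dominates; a dominated
    comparison carries the dominance label instead of a ratio.
    """
    d_cost = intervention.cost - comparator.cost
    d_qaly = intervention.qaly - comparator.qaly
    d_ly = intervention.total_ly - comparator.total_ly
    d_pf = intervention.pf_ly - comparator.pf_ly

    dominance = "none"
    if d_qaly <= 0 and d_cost >= 0 and not (d_qaly == 0 and d_cost == 0):
        dominance = "comparator_dominates"
    elif d_qaly >= 0 and d_cost <= 0 and not (d_qaly == 0 and d_cost == 0):
        dominance = "intervention_dominates"

    icer_q = d_cost / d_qaly if dominance == "none" and d_qaly > 0 else None
    icer_l = d_cost / d_ly if dominance == "none" and d_ly > 0 else None
    return Comparison(
        intervention=intervention.name,
        comparator=comparator.name,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
        delta_pf_ly=d_pf,
        icer_per_qaly=icer_q,
        icer_per_ly=icer_l,
        dominance=dominance,
    )


def net_monetary_benefit(leg: StrategyResult, threshold: float) -> float:
    """threshold * QALYs - cost; higher is preferred at that threshold."""
    if threshold < 0 or not math.isfinite(threshold):
        raise ValueError("threshold must be a nonnegative finite number")
    return threshold * leg.qaly - leg.cost
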