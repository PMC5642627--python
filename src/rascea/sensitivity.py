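"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis reruns the full deterministic model at each parameter's
range ends, everything else held at base; survival parameters are perturbed
through their median survival time.  The probabilistic analysis jointly
samples cost parameters from triangular distributions and
proportion/utility parameters from beta distributions (method-of-moments,
with utility standard errors at 25% of the mean), re-evaluating both
strategies per draw; results feed cost-effectiveness acceptability curves.

Each parameter owns an independent RNG substream keyed by a hash of its
name, so adding or removing a parameter never perturbs the draws of the
others.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import _integrate
from .config import ParamSet, ParamSpec
from .costing import CostBook, accrue_costs, screening_cost_per_treated_patient
from .pipeline import base_case, build_arm_trace

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PSAResult",
    "sample_param",
    "one_way",
    "tornado",
    "run_psa",
    "ceac",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter sampling


def _beta_ab(mean: float, sd: float) -> tuple[float, float] | None:
    var = sd * sd
    if var <= 0 or var >= mean * (1.0 - mean):
        return None
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


_fallback_logged: set[str] = set()


def sample_param(spec: ParamSpec, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw ``size`` PSA values for one parameter.

    Triangular(min=low, mode=base, max=high) for cost parameters; beta with
    moments mean=base and sd = 25% of the mean for utilities, or
    sd = (high - low) / (2 * 1.96) for other proportions.  Infeasible beta
    moments fall back to the range-based standard deviation (logged once).
    ``fixed`` parameters stay at base.
    """
    if spec.psa_distribution == "fixed":
        return np.full(size, spec.base)
    if spec.psa_distribution == "triangular":
        if spec.low == spec.high:
            return np.full(size, spec.base)
        return rng.triangular(spec.low, spec.base, spec.high, size)
    # beta
    mean = spec.base
    if mean <= 0.0 or mean >= 1.0:
        return np.full(size, mean)
    sd_primary = (
        0.25 * mean
        if spec.target.startswith("utilities.")
        else (spec.high - spec.low) / (2.0 * 1.96)
    )
    ab = _beta_ab(mean, sd_primary)
    if ab is None:
        sd_range = (spec.high - spec.low) / (2.0 * 1.96)
        ab = _beta_ab(mean, sd_range)
        if spec.name not in _fallback_logged:
            log.warning(
                "beta moments infeasible for %s (sd=%.4g); using range-fit sd",
                spec.name, sd_primary,
            )
            _fallback_logged.add(spec.name)
    if ab is None:  # degenerate range as well: keep the point mass
        return np.full(size, mean)
    return rng.beta(ab[0], ab[1], size)


def _param_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, order-insensitive substream for one parameter."""
    digest = int(hashlib.md5(name.encode()).hexdigest()[:8], 16)
    return np.random.default_rng(np.random.SeedSequence((int(seed), digest)))


# ---------------------------------------------------------------------------
# one-way / tornado


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_base: float
    icer_low: float   # ICER with the parameter at its low range end
    icer_high: float  # ICER with the parameter at its high range end

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _pap_icer(ps: ParamSet) -> float:
    cmp_ = base_case(ps).vs_control_pap
    if cmp_.icer_per_qaly is None:
        # dominance: signed sentinel keeps the bar direction meaningful
        return -np.inf if cmp_.dominance == "intervention_dominates" else np.inf
    return cmp_.icer_per_qaly


def one_way(ps: ParamSet, spec: ParamSpec) -> TornadoEntry:
    """Deterministic model at the range ends of one parameter.

    The reported ratio is the cetuximab-with-PAP versus control ICER per
    QALY, the comparison shown in the published tornado figure.
    """
    return TornadoEntry(
        name=spec.name,
        icer_base=_pap_icer(ps),
        icer_low=_pap_icer(ps.with_value(spec.target, spec.low)),
        icer_high=_pap_icer(ps.with_value(spec.target, spec.high)),
    )


def tornado(ps: ParamSet) -> pd.DataFrame:
    """All one-way entries, widest bar first."""
    entries = [one_way(ps, spec) for spec in ps.param_specs]
    frame = pd.DataFrame(
        {
            "parameter": [e.name for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_base": [e.icer_base for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "width": [e.width for e in entries],
        }
    )
    return frame.sort_values("width", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    """Joint parameter draws evaluated through the deterministic model."""

    n_draws: int
    seed: int
    pap_enabled: bool
    frame: pd.DataFrame  # cost/qaly per strategy per draw, plus deltas

    @property
    def delta_cost(self) -> np.ndarray:
        return self.frame["delta_cost"].to_numpy()

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.frame["delta_qaly"].to_numpy()


def _strategy_weights(ps: ParamSet, arm: str, pap_enabled: bool | None, trace):
    """Discounted accrual weight of each unit cost for one strategy.

    The strategy cost is linear in every unit cost given the trace and the
    costing conventions, so one pass with a unit cost book yields the exact
    per-draw cost as a dot product.  Screening is excluded here (its
    prevalence loading is nonlinear) and handled per draw.
    """
    from dataclasses import replace

    strategy = ps.strategy(arm)
    if pap_enabled is not None and arm == "cetuximab":
        strategy = replace(strategy, pap_enabled=pap_enabled)
    cov = strategy.coverage_fraction
    # weights are extracted at full coverage; the coverage share is applied
    # once, in the per-draw dot product
    strategy = replace(strategy, screening_applied=False, coverage_fraction=1.0)
    unit_costs = CostBook(
        folfiri_per_cycle=1.0,
        cetuximab_per_100mg=1.0,
        salvage_per_cycle=1.0,
        ras_test_per_unit=1.0,
        terminal_care=1.0,
        sae_unit_costs={k: 1.0 for k in ps.costs.sae_unit_costs},
    )
    ledger = accrue_costs(trace, strategy, unit_costs, ps.dosing, ps.model, ps.pap)
    weights = ledger.by_component().to_dict()
    return {
        "folfiri": weights.get("folfiri", 0.0),
        "cetuximab": weights.get("cetuximab", 0.0),
        "salvage": weights.get("salvage", 0.0),
        "terminal": weights.get("terminal", 0.0),
        "coverage": cov,
        "screening": ps.strategy(arm).screening_applied,
        "sae_expected_units": {
            e: p for e, p in strategy.sae_probabilities.items()
        },
    }


def run_psa(
    ps: ParamSet, n: int = 1000, seed: int | None = None, pap_enabled: bool | None = None
) -> PSAResult:
    """``n`` joint draws of all non-fixed parameters, model re-evaluated per draw.

    Survival curves enter at their base-case values (no distribution is
    attached to them), so the cohort traces are computed once and the
    per-draw evaluation reduces to exact linear accounting over the sampled
    unit costs and utilities.  Identical seeds give bit-identical results.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    seed = ps.seed if seed is None else int(seed)
    pap = ps.cetuximab.pap_enabled if pap_enabled is None else pap_enabled

    draws = {
        spec.name: sample_param(spec, _param_rng(seed, spec.name), n)
        for spec in ps.param_specs
    }

    def value(target: str, default: float) -> np.ndarray:
        for spec in ps.param_specs:
            if spec.target == target:
                return draws[spec.name]
        return np.full(n, default)

    folfiri = value("costs.folfiri_per_cycle", ps.costs.folfiri_per_cycle)
    cet_price = value("costs.cetuximab_per_100mg", ps.costs.cetuximab_per_100mg)
    salvage = value("costs.salvage_per_cycle", ps.costs.salvage_per_cycle)
    terminal = value("costs.terminal_care", ps.costs.terminal_care)
    ras_test = value("costs.ras_test_per_unit", ps.costs.ras_test_per_unit)
    prevalence = value("cetuximab.ras_prevalence", ps.cetuximab.ras_prevalence)
    u_pfs = value("utilities.u_pfs", ps.utilities.u_pfs)
    u_pd_chemo = value("utilities.u_pd_chemo", ps.utilities.u_pd_chemo)
    u_pd_targ = value("utilities.u_pd_targeted", ps.utilities.u_pd_targeted)
    sae_costs = {
        e: value(f"costs.sae.{e}", c) for e, c in ps.costs.sae_unit_costs.items()
    }

    f = ps.utilities.pd_targeted_fraction_cetux_arm
    u_pd = {"control": u_pd_chemo,
            "cetuximab": (1.0 - f) * u_pd_chemo + f * u_pd_targ}

    out = {}
    for arm in ("control", "cetuximab"):
        trace = build_arm_trace(ps, arm)
        w = _strategy_weights(ps, arm, pap, trace)
        cost = (
            folfiri * w["folfiri"]
            + cet_price * w["cetuximab"]
            + salvage * w["salvage"]
            + terminal * w["terminal"]
        )
        if w["screening"]:
            cost = cost + ras_test / (1.0 - prevalence)
        for event, prob in w["sae_expected_units"].items():
            cost = cost + prob * sae_costs[event]
        cost = cost * w["coverage"]
        a_pf = _integrate(trace.pf * trace.df, trace)
        a_pd = _integrate(trace.pd * trace.df, trace)
        qaly = u_pfs * a_pf + u_pd[arm] * a_pd
        out[f"cost_{arm}"] = cost
        out[f"qaly_{arm}"] = qaly

    frame = pd.DataFrame(out)
    frame["delta_cost"] = frame["cost_cetuximab"] - frame["cost_control"]
    frame["delta_qaly"] = frame["qaly_cetuximab"] - frame["qaly_control"]
    return PSAResult(n_draws=n, seed=seed, pap_enabled=pap, frame=frame)


def ceac(psa: PSAResult, thresholds) -> pd.DataFrame:
    """Probability each strategy is cost-effective across willingness to pay.

    At each threshold the cetuximab strategy counts the draws in which its
    net monetary benefit is at least the control's (ties go to the
    intervention); the two probabilities sum to one.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid must be non-empty")
    nmb_gain = (
        thresholds[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    )
    p_cetux = (nmb_gain >= 0).mean(axis=1)
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "p_cetuximab": p_cetux,
            "p_control": 1.0 - p_cetux,
        }
    )
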