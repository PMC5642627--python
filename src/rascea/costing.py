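"""Per-cycle and one-off cost accrual for each treatment strategy.

Components follow the payer perspective of the analysis:

* first-line chemotherapy (FOLFIRI) while progression-free, priced per
  14-day cycle;
* cetuximab on top of chemotherapy in the intervention arm, with weekly
  dosing scaled by body surface area, whole-vial wastage, and an optional
  patient assistance program (PAP) under which the payer covers only the
  "paid" months of a pay/donate calendar;
* RAS screening loading: tests are consumed by the whole screened
  population but only wild-type patients enter treatment, so the per-treated
  cost is the unit price divided by the wild-type fraction;
* salvage chemotherapy after progression (optionally capped per patient);
* terminal care charged when patients die;
* expected severe-adverse-event management, one-off at model entry;
* an insurance coverage fraction scaling the payer's share linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTrace, ModelConfig

__all__ = [
    "CostBook",
    "DosingRule",
    "PAPSchedule",
    "StrategySpec",
    "CostLedger",
    "vials_needed",
    "payer_pays_cetuximab",
    "cetuximab_cycle_cost",
    "screening_cost_per_treated_patient",
    "accrue_costs",
]


@dataclass(frozen=True)
class CostBook:
    """Unit costs, 2016 US dollars."""

    folfiri_per_cycle: float = 2050.5
    cetuximab_per_100mg: float = 637.4
    salvage_per_cycle: float = 2411.8
    ras_test_per_unit: float = 176.9
    terminal_care: float = 1980.1
    sae_unit_costs: dict = field(
        default_factory=lambda: {
            "vomiting": 175.7,
            "rash_acne": 11.1,
            "fatigue": 1524.6,
            "neutropenia": 2694.6,
            "diarrhea": 891.5,
        }
    )

    def __post_init__(self) -> None:
        for name in (
            "folfiri_per_cycle",
            "cetuximab_per_100mg",
            "salvage_per_cycle",
            "ras_test_per_unit",
            "terminal_care",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if any(v < 0 for v in self.sae_unit_costs.values()):
            raise ValueError("SAE unit costs must be nonnegative")


@dataclass(frozen=True)
class DosingRule:
    """Cetuximab dosing: 400 mg/m2 loading then 250 mg/m2 weekly."""

    loading_dose_mg_m2: float = 400.0
    maintenance_dose_mg_m2: float = 250.0
    infusions_per_cycle: int = 2  # weekly infusions in a 14-day cycle
    vial_size_mg: float = 100.0
    bsa_m2: float = 1.72

    def __post_init__(self) -> None:
        if self.vial_size_mg <= 0:
            raise ValueError("vial_size_mg must be positive")
        if self.loading_dose_mg_m2 < 0 or self.maintenance_dose_mg_m2 < 0:
            raise ValueError("doses must be nonnegative")
        if self.bsa_m2 <= 0:
            raise ValueError("bsa_m2 must be positive")
        if self.infusions_per_cycle < 1:
            raise ValueError("infusions_per_cycle must be >= 1")


@dataclass(frozen=True)
class PAPSchedule:
    """Pay/donate calendar of the cetuximab patient assistance program.

    The payer covers the first ``lead_pay_months`` months, the producer
    donates the next ``lead_free_months``; thereafter blocks of
    ``repeat_pay_months`` paid + ``repeat_free_months`` donated months repeat
    while the patient remains on treatment.  ``cycles_per_month`` maps the
    monthly calendar onto the 14-day cycle grid (2.0 is the documented
    approximation of 30.4375/14 = 2.17).
    """

    lead_pay_months: int = 2
    lead_free_months: int = 2
    repeat_pay_months: int = 1
    repeat_free_months: int = 3
    cycles_per_month: float = 2.0

    def __post_init__(self) -> None:
        for name in ("lead_pay_months", "repeat_pay_months"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("lead_free_months", "repeat_free_months"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cycles_per_month <= 0:
            raise ValueError("cycles_per_month must be positive")


@dataclass(frozen=True)
class StrategySpec:
    """One arm's treatment, screening and costing switches."""

    name: str = "control"
    pap_enabled: bool = False
    screening_applied: bool = False
    ras_prevalence: float = 0.41
    coverage_fraction: float = 1.0
    salvage_cycles_cap: int | None = None
    sae_probabilities: dict = field(default_factory=dict)
    cetuximab_pricing: str = "per_vial"  # or "per_unit_cycle"
    terminal_care_mode: str = "once"  # or "per_cycle"

    def __post_init__(self) -> None:
        if self.name not in ("control", "cetuximab"):
            raise ValueError("name must be 'control' or 'cetuximab'")
        if not (0 <= self.ras_prevalence < 1):
            raise ValueError("ras_prevalence must lie in [0, 1)")
        if not (0 <= self.coverage_fraction <= 1):
            raise ValueError("coverage_fraction must lie in [0, 1]")
        if self.name == "control" and (self.pap_enabled or self.screening_applied):
            raise ValueError("control strategy cannot enable PAP or screening")
        if self.cetuximab_pricing not in ("per_vial", "per_unit_cycle"):
            raise ValueError("cetuximab_pricing must be 'per_vial' or 'per_unit_cycle'")
        if self.terminal_care_mode not in ("once", "per_cycle"):
            raise ValueError("terminal_care_mode must be 'once' or 'per_cycle'")
        if self.salvage_cycles_cap is not None and self.salvage_cycles_cap < 0:
            raise ValueError("salvage_cycles_cap must be >= 0 or None")
        if any(not (0 <= p <= 1) for p in self.sae_probabilities.values()):
            raise ValueError("SAE probabilities must lie in [0, 1]")


def vials_needed(dose_mg_per_m2: float, bsa: float, vial_size_mg: float) -> int:
    """Whole vials opened per infusion; partial vials are discarded."""
    if vial_size_mg <= 0:
        raise ValueError("vial size must be positive")
    if dose_mg_per_m2 < 0 or bsa <= 0:
        raise ValueError("dose must be >= 0 and bsa > 0")
    if dose_mg_per_m2 == 0:
        return 0
    return math.ceil(dose_mg_per_m2 * bsa / vial_size_mg)


def payer_pays_cetuximab(cycle_index, schedule: PAPSchedule):
    """Whether the payer covers cetuximab in the given cycle(s) under the PAP.

    Vectorised over ``cycle_index``.  Cycles map to (1-based) treatment
    months via ``schedule.cycles_per_month``; the month pattern is
    lead_pay paid, lead_free donated, then repeating repeat_pay paid +
    repeat_free donated blocks.
    """
    k = np.asarray(cycle_index)
    if np.any(k < 0):
        raise ValueError("cycle_index must be >= 0")
    month = np.floor(k / schedule.cycles_per_month).astype(int) + 1
    paid = month <= schedule.lead_pay_months
    after_lead = month - (schedule.lead_pay_months + schedule.lead_free_months)
    block = schedule.repeat_pay_months + schedule.repeat_free_months
    in_repeat_pay = (after_lead >= 1) & (
        ((after_lead - 1) % block) < schedule.repeat_pay_months
    )
    out = paid | in_repeat_pay
    return bool(out) if out.ndim == 0 else out


def cetuximab_cycle_cost(
    cycle_index: int,
    dosing: DosingRule,
    costbook: CostBook,
    pap_enabled: bool,
    schedule: PAPSchedule | None = None,
    pricing: str = "per_vial",
) -> float:
    """Payer cost of cetuximab for one on-treatment cycle.

    Under ``per_vial`` pricing, cycle 0 contains one loading infusion plus
    maintenance infusions, later cycles only maintenance infusions, each
    costed by whole vials.  Under ``per_unit_cycle`` pricing a flat listed
    price unit is charged per cycle (the calibration convention, see the
    methods note).  Donated months under the PAP cost the payer nothing.
    """
    if pap_enabled:
        if schedule is None:
            raise ValueError("PAP enabled but no schedule given")
        if not payer_pays_cetuximab(cycle_index, schedule):
            return 0.0
    price = costbook.cetuximab_per_100mg
    if pricing == "per_unit_cycle":
        return price
    v_maint = vials_needed(dosing.maintenance_dose_mg_m2, dosing.bsa_m2, dosing.vial_size_mg)
    if cycle_index == 0:
        v_load = vials_needed(dosing.loading_dose_mg_m2, dosing.bsa_m2, dosing.vial_size_mg)
        vials = v_load + (dosing.infusions_per_cycle - 1) * v_maint
    else:
        vials = dosing.infusions_per_cycle * v_maint
    return vials * price


def screening_cost_per_treated_patient(test_cost: float, prevalence: float) -> float:
    """RAS tests consumed per wild-type patient identified and treated."""
    if not (0 <= prevalence < 1):
        raise ValueError("prevalence must lie in [0, 1)")
    return test_cost / (1.0 - prevalence)


@dataclass
class CostLedger:
    """Per-cycle cost components of one strategy run."""

    frame: pd.DataFrame  # columns: cycle, component, undiscounted, discounted

    @property
    def total(self) -> float:
        return float(self.frame["discounted"].sum())

    def by_component(self) -> pd.Series:
        return self.frame.groupby("component")["discounted"].sum()


def _salvage_occupancy(trace: CohortTrace, cap: int | None) -> np.ndarray:
    """Progressed occupancy eligible for salvage at each cycle start.

    With an uncapped policy this is the progressed occupancy itself.  With a
    per-patient cap of ``cap`` cycles, eligibility is limited by the mass of
    patients who left the progression-free state within the last ``cap``
    cycles (an upper bound on recent progressors still alive), so each
    progressing patient is charged at most ``cap`` salvage cycles.
    """
    pd_occ = trace.pd[:-1]
    if cap is None:
        return pd_occ
    if cap == 0:
        return np.zeros_like(pd_occ)
    exits = np.maximum(0.0, -np.diff(trace.pf))  # PF exits per interval
    csum = np.concatenate(([0.0], np.cumsum(exits)))
    n = len(pd_occ)
    recent = np.array([csum[k] - csum[max(0, k - cap)] for k in range(n)])
    return np.minimum(pd_occ, recent)


def accrue_costs(
    trace: CohortTrace,
    strategy: StrategySpec,
    costbook: CostBook,
    dosing: DosingRule,
    config: ModelConfig,
    schedule: PAPSchedule | None = None,
) -> CostLedger:
    """Discounted payer cost of one strategy over the whole trace.

    Treatment costs accrue while progression-free (treatment continues until
    progression), charged on cycle-start occupancy; salvage accrues on
    progressed occupancy subject to the per-patient cap; terminal care is a
    one-off at death entry (or per cycle dead if so configured); screening
    and expected SAE management are one-offs at model entry.  Everything is
    scaled by the insurance coverage fraction.
    """
    n = len(trace.t_years) - 1
    if n < 1:
        raise ValueError("trace must contain at least one cycle")
    k = np.arange(n)
    pf = trace.pf[:-1]
    df = trace.df[:-1]
    cov = strategy.coverage_fraction

    rows: list[pd.DataFrame] = []

    def add(component: str, undisc: np.ndarray, disc: np.ndarray, cycles=k) -> None:
        rows.append(
            pd.DataFrame(
                {
                    "cycle": cycles,
                    "component": component,
                    "undiscounted": undisc * cov,
                    "discounted": disc * cov,
                }
            )
        )

    folfiri = pf * costbook.folfiri_per_cycle
    add("folfiri", folfiri, folfiri * df)

    if strategy.name == "cetuximab":
        per_cycle = np.array(
            [
                cetuximab_cycle_cost(
                    int(i),
                    dosing,
                    costbook,
                    strategy.pap_enabled,
                    schedule,
                    strategy.cetuximab_pricing,
                )
                for i in k
            ]
        )
        cet = pf * per_cycle
        add("cetuximab", cet, cet * df)

    salvage = _salvage_occupancy(trace, strategy.salvage_cycles_cap) * costbook.salvage_per_cycle
    add("salvage", salvage, salvage * df)

    if strategy.terminal_care_mode == "once":
        new_deaths = np.diff(trace.dead)
        term = new_deaths * costbook.terminal_care
        add("terminal", term, term * trace.df[1:])
    else:
        term = trace.dead[:-1] * costbook.terminal_care
        add("terminal", term, term * df)

    one_off = np.zeros(1)
    if strategy.screening_applied:
        scr = one_off + screening_cost_per_treated_patient(
            costbook.ras_test_per_unit, strategy.ras_prevalence
        )
        add("screening", scr, scr, cycles=np.zeros(1, dtype=int))

    if strategy.sae_probabilities:
        expected = sum(
            p * costbook.sae_unit_costs.get(event, 0.0)
            for event, p in strategy.sae_probabilities.items()
        )
        sae = one_off + expected
        add("sae", sae, sae, cycles=np.zeros(1, dtype=int))

    return CostLedger(frame=pd.concat(rows, ignore_index=True))
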