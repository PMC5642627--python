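import dataclasses

import numpy as np
import pytest

from rascea.cohort import CohortTrace, ModelConfig, build_trace
from rascea.costing import (
    CostBook,
    DosingRule,
    PAPSchedule,
    StrategySpec,
    accrue_costs,
    cetuximab_cycle_cost,
    payer_pays_cetuximab,
    screening_cost_per_treated_patient,
    vials_needed,
)

DOSING = DosingRule()
PAP = PAPSchedule()


def one_cycle_alive_trace():
    t = np.array([0.0, 14.0 / 365.25])
    return CohortTrace(
        t_years=t, pf=np.ones(2), pd=np.zeros(2), dead=np.zeros(2),
        df=np.ones(2), cycle_years=14.0 / 365.25,
    )


class TestVialsNeeded:
    def test_maintenance_dose(self):
        assert vials_needed(250.0, 1.72, 100.0) == 5  # 430 mg

    def test_loading_dose(self):
        assert vials_needed(400.0, 1.72, 100.0) == 7  # 688 mg

    def test_zero_dose(self):
        assert vials_needed(0.0, 1.72, 100.0) == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            vials_needed(250.0, 1.72, 0.0)
        with pytest.raises(ValueError):
            vials_needed(-1.0, 1.72, 100.0)


class TestPayerPaysCetuximab:
    def test_first_cycle_paid(self):
        assert payer_pays_cetuximab(0, PAP)

    def test_months_three_and_four_free(self):
        # 2 cycles/month: cycles 4..7 fall in treatment months 3-4 (donated)
        for k in range(4, 8):
            assert not payer_pays_cetuximab(k, PAP)

    def test_repeating_block(self):
        # after the lead 2 paid + 2 free months: month 5 paid, months 6-8 free
        assert payer_pays_cetuximab(8, PAP) and payer_pays_cetuximab(9, PAP)
        for k in range(10, 16):
            assert not payer_pays_cetuximab(k, PAP)
        assert payer_pays_cetuximab(16, PAP)

    def test_no_free_months_always_paid(self):
        always = PAPSchedule(lead_pay_months=1, lead_free_months=0,
                             repeat_pay_months=1, repeat_free_months=0)
        assert np.all(payer_pays_cetuximab(np.arange(100), always))

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            payer_pays_cetuximab(-1, PAP)


class TestCetuximabCycleCost:
    BOOK = CostBook()

    def test_first_cycle_no_pap(self):
        cost = cetuximab_cycle_cost(0, DOSING, self.BOOK, pap_enabled=False)
        assert cost == pytest.approx((7 + 5) * 637.4)  # 7,648.8

    def test_later_cycles_no_pap(self):
        cost = cetuximab_cycle_cost(3, DOSING, self.BOOK, pap_enabled=False)
        assert cost == pytest.approx(10 * 637.4)  # 6,374.0

    def test_donated_month_costs_nothing(self):
        assert cetuximab_cycle_cost(5, DOSING, self.BOOK, True, PAP) == 0.0

    def test_per_unit_cycle_pricing(self):
        cost = cetuximab_cycle_cost(0, DOSING, self.BOOK, False,
                                    pricing="per_unit_cycle")
        assert cost == pytest.approx(637.4)

    def test_pap_without_schedule_rejected(self):
        with pytest.raises(ValueError):
            cetuximab_cycle_cost(0, DOSING, self.BOOK, pap_enabled=True)


class TestScreening:
    def test_published_loading(self):
        assert screening_cost_per_treated_patient(176.9, 0.41) == pytest.approx(
            299.83, abs=0.01
        )

    def test_zero_prevalence(self):
        assert screening_cost_per_treated_patient(176.9, 0.0) == 176.9

    def test_half_prevalence_doubles(self):
        assert screening_cost_per_treated_patient(100.0, 0.5) == pytest.approx(200.0)

    def test_prevalence_one_rejected(self):
        with pytest.raises(ValueError):
            screening_cost_per_treated_patient(176.9, 1.0)


class TestAccrueCosts:
    def test_zero_cost_book(self, calibrated):
        trace = build_trace(*calibrated.curves.for_arm("control"), calibrated.model)
        zero = CostBook(folfiri_per_cycle=0, cetuximab_per_100mg=0,
                        salvage_per_cycle=0, ras_test_per_unit=0, terminal_care=0,
                        sae_unit_costs={})
        ledger = accrue_costs(trace, StrategySpec(), zero, DOSING,
                              calibrated.model, PAP)
        assert ledger.total == 0.0

    def test_one_cycle_all_alive_control(self):
        ledger = accrue_costs(
            one_cycle_alive_trace(), StrategySpec(), CostBook(), DOSING,
            ModelConfig(), PAP,
        )
        assert ledger.total == pytest.approx(2050.5)

    def test_monotone_in_unit_costs(self, calibrated):
        trace = build_trace(*calibrated.curves.for_arm("cetuximab"), calibrated.model)
        strategy = calibrated.cetuximab
        rng = np.random.default_rng(7)
        base_book = calibrated.costs
        base_total = accrue_costs(trace, strategy, base_book, calibrated.dosing,
                                  calibrated.model, calibrated.pap).total
        fields = ["folfiri_per_cycle", "cetuximab_per_100mg", "salvage_per_cycle",
                  "ras_test_per_unit", "terminal_care"]
        for _ in range(3):
            name = fields[rng.integers(len(fields))]
            bumped = dataclasses.replace(
                base_book, **{name: getattr(base_book, name) * (1 + rng.uniform(0, 1))}
            )
            total = accrue_costs(trace, strategy, bumped, calibrated.dosing,
                                 calibrated.model, calibrated.pap).total
            assert total >= base_total

    def test_coverage_scales_linearly(self, calibrated):
        trace = build_trace(*calibrated.curves.for_arm("cetuximab"), calibrated.model)
        full = dataclasses.replace(calibrated.cetuximab, coverage_fraction=1.0)
        partial = dataclasses.replace(calibrated.cetuximab, coverage_fraction=0.37)
        t_full = accrue_costs(trace, full, calibrated.costs, calibrated.dosing,
                              calibrated.model, calibrated.pap).total
        t_partial = accrue_costs(trace, partial, calibrated.costs, calibrated.dosing,
                                 calibrated.model, calibrated.pap).total
        assert t_partial == pytest.approx(0.37 * t_full, rel=1e-12)

    def test_pap_cheaper_than_no_pap(self, calibrated):
        trace = build_trace(*calibrated.curves.for_arm("cetuximab"), calibrated.model)
        with_pap = dataclasses.replace(calibrated.cetuximab, pap_enabled=True)
        without = dataclasses.replace(calibrated.cetuximab, pap_enabled=False)
        args = (calibrated.costs, calibrated.dosing, calibrated.model, calibrated.pap)
        cet = lambda s: accrue_costs(trace, s, *args).by_component()["cetuximab"]
        assert cet(with_pap) < cet(without)

    def test_no_pap_equals_always_paid_schedule(self, calibrated):
        trace = build_trace(*calibrated.curves.for_arm("cetuximab"), calibrated.model)
        always = PAPSchedule(lead_pay_months=1, lead_free_months=0,
                             repeat_pay_months=1, repeat_free_months=0,
                             cycles_per_month=calibrated.pap.cycles_per_month)
        with_pap = dataclasses.replace(calibrated.cetuximab, pap_enabled=True)
        without = dataclasses.replace(calibrated.cetuximab, pap_enabled=False)
        args = (calibrated.costs, calibrated.dosing, calibrated.model)
        t1 = accrue_costs(trace, with_pap, *args, always).total
        t2 = accrue_costs(trace, without, *args, calibrated.pap).total
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_salvage_cap_reduces_cost(self, calibrated):
        trace = build_trace(*calibrated.curves.for_arm("control"), calibrated.model)
        args = (calibrated.costs, calibrated.dosing, calibrated.model, calibrated.pap)
        uncapped = dataclasses.replace(calibrated.control, salvage_cycles_cap=None)
        capped = dataclasses.replace(calibrated.control, salvage_cycles_cap=3)
        zero = dataclasses.replace(calibrated.control, salvage_cycles_cap=0)
        s = lambda strat: accrue_costs(trace, strat, *args).by_component()["salvage"]
        assert s(zero) == 0.0
        assert s(zero) < s(capped) < s(uncapped)


class TestStrategySpecValidation:
    def test_control_cannot_enable_pap_or_screening(self):
        with pytest.raises(ValueError):
            StrategySpec(name="control", pap_enabled=True)
        with pytest.raises(ValueError):
            StrategySpec(name="control", screening_applied=True)

    @pytest.mark.parametrize("kwargs", [
        {"ras_prevalence": 1.0},
        {"coverage_fraction": 1.5},
        {"cetuximab_pricing": "per_gram"},
        {"terminal_care_mode": "weekly"},
        {"salvage_cycles_cap": -1},
    ])
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StrategySpec(name="cetuximab", **kwargs)
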