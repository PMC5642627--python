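import dataclasses

import numpy as np
import pandas as pd
import pytest

from rascea.config import ParamSpec
from rascea.sensitivity import (
    _param_rng,
    ceac,
    one_way,
    run_psa,
    sample_param,
    tornado,
)


def degenerate(spec: ParamSpec) -> ParamSpec:
    return ParamSpec(name=spec.name, base=spec.base, low=spec.base, high=spec.base,
                     psa_distribution="fixed", target=spec.target)


class TestSampleParam:
    def test_triangular_within_bounds(self):
        spec = ParamSpec("c", 637.4, 318.7, 956.1, "triangular", "costs.cetuximab_per_100mg")
        draws = sample_param(spec, _param_rng(1, "c"), 10_000)
        assert np.all((draws >= 318.7) & (draws <= 956.1))

    def test_triangular_mean_matches_closed_form(self):
        spec = ParamSpec("c", 2050.5, 1025.3, 3075.8, "triangular",
                         "costs.folfiri_per_cycle")
        n = 100_000
        draws = sample_param(spec, _param_rng(2, "c"), n)
        mean_exact = (1025.3 + 2050.5 + 3075.8) / 3.0
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - mean_exact) < 3 * se

    def test_beta_utility_sd_recovery(self):
        spec = ParamSpec("u_pfs", 0.85, 0.68, 1.0, "beta", "utilities.u_pfs")
        n = 100_000
        draws = sample_param(spec, _param_rng(3, "u_pfs"), n)
        # target sd = 25% of the mean = 0.2125; compare within 3 se of the sd
        sd = draws.std(ddof=1)
        se_sd = sd / np.sqrt(2 * (n - 1))
        assert abs(sd - 0.2125) < 3 * se_sd
        assert np.all((draws >= 0) & (draws <= 1))

    def test_fixed_returns_base(self):
        spec = ParamSpec("bsa", 1.72, 1.72, 1.72, "fixed", "dosing.bsa_m2")
        assert np.all(sample_param(spec, _param_rng(4, "bsa"), 10) == 1.72)

    def test_substreams_are_order_insensitive(self):
        spec = ParamSpec("c", 637.4, 318.7, 956.1, "triangular",
                         "costs.cetuximab_per_100mg")
        a = sample_param(spec, _param_rng(11, "c"), 5)
        b = sample_param(spec, _param_rng(11, "c"), 5)
        np.testing.assert_array_equal(a, b)


class TestOneWayTornado:
    def test_degenerate_range_zero_width(self, calibrated):
        spec = degenerate(calibrated.param_specs[0])
        entry = one_way(calibrated, spec)
        assert entry.width == 0.0
        assert entry.icer_low == entry.icer_base == entry.icer_high

    def test_cetuximab_price_monotone(self, calibrated):
        spec = next(s for s in calibrated.param_specs
                    if s.target == "costs.cetuximab_per_100mg")
        entry = one_way(calibrated, spec)
        assert entry.icer_low < entry.icer_high

    def test_os_median_is_most_influential(self, calibrated):
        frame = tornado(calibrated)
        widths = dict(zip(frame["parameter"], frame["width"]))
        os_width = widths["median_os_cetuximab"]
        for name, w in widths.items():
            if name.startswith("cost_"):
                assert os_width >= w

    def test_zero_width_ranges_reproduce_base_icer(self, calibrated, bc):
        ps = dataclasses.replace(
            calibrated,
            param_specs=tuple(degenerate(s) for s in calibrated.param_specs),
        )
        frame = tornado(ps)
        base_icer = bc.vs_control_pap.icer_per_qaly
        np.testing.assert_allclose(frame["icer_low"], base_icer, rtol=1e-12)
        np.testing.assert_allclose(frame["icer_high"], base_icer, rtol=1e-12)


class TestRunPsa:
    def test_degenerate_distributions_match_base_case(self, calibrated, bc):
        ps = dataclasses.replace(
            calibrated,
            param_specs=tuple(degenerate(s) for s in calibrated.param_specs),
        )
        result = run_psa(ps, n=3)
        frame = result.frame
        assert frame["cost_control"].iloc[0] == pytest.approx(bc.control.cost, rel=1e-9)
        assert frame["cost_cetuximab"].iloc[0] == pytest.approx(
            bc.cetuximab_pap.cost, rel=1e-9
        )
        assert frame["qaly_control"].iloc[0] == pytest.approx(bc.control.qaly, rel=1e-9)
        assert frame["qaly_cetuximab"].iloc[0] == pytest.approx(
            bc.cetuximab_pap.qaly, rel=1e-9
        )

    def test_seeded_bit_reproducibility(self, calibrated):
        a = run_psa(calibrated, n=200, seed=42)
        b = run_psa(calibrated, n=200, seed=42)
        pd.testing.assert_frame_equal(a.frame, b.frame, check_exact=True)

    def test_different_seeds_differ(self, calibrated):
        a = run_psa(calibrated, n=50, seed=1)
        b = run_psa(calibrated, n=50, seed=2)
        assert not a.frame.equals(b.frame)

    def test_pap_toggle_changes_only_cetuximab_cost(self, calibrated):
        on = run_psa(calibrated, n=50, seed=5, pap_enabled=True)
        off = run_psa(calibrated, n=50, seed=5, pap_enabled=False)
        pd.testing.assert_series_equal(on.frame["cost_control"], off.frame["cost_control"])
        pd.testing.assert_series_equal(on.frame["qaly_cetuximab"], off.frame["qaly_cetuximab"])
        assert np.all(on.frame["cost_cetuximab"] < off.frame["cost_cetuximab"])

    def test_nonpositive_n_rejected(self, calibrated):
        with pytest.raises(ValueError):
            run_psa(calibrated, n=0)


class TestCeac:
    def test_threshold_zero_is_fraction_cheaper(self, calibrated):
        psa = run_psa(calibrated, n=500, seed=9)
        frame = ceac(psa, [0.0])
        expected = float((psa.delta_cost <= 0).mean())
        assert frame["p_cetuximab"].iloc[0] == pytest.approx(expected)

    def test_large_threshold_limit(self, calibrated):
        psa = run_psa(calibrated, n=500, seed=9)
        frame = ceac(psa, [1e12])
        expected = float((psa.delta_qaly > 0).mean())
        assert frame["p_cetuximab"].iloc[0] >= expected
        assert frame["p_cetuximab"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_probabilities_sum_to_one(self, calibrated):
        psa = run_psa(calibrated, n=300, seed=3)
        frame = ceac(psa, np.linspace(0, 50000, 26))
        np.testing.assert_allclose(frame["p_cetuximab"] + frame["p_control"], 1.0)

    def test_monotone_when_all_gains_positive(self, calibrated):
        psa = run_psa(calibrated, n=1000, seed=7)
        keep = psa.delta_qaly > 0
        positive = dataclasses.replace(
            psa, frame=psa.frame.loc[keep].reset_index(drop=True),
            n_draws=int(keep.sum()),
        )
        frame = ceac(positive, np.linspace(0.0, 100000.0, 101))
        assert np.all(np.diff(frame["p_cetuximab"]) >= 0)

    def test_empty_grid_rejected(self, calibrated):
        psa = run_psa(calibrated, n=10, seed=1)
        with pytest.raises(ValueError):
            ceac(psa, [])
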