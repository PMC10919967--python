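"""Excess hazard, cumulative hazard integration and the RADS transform."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from radsurv import (
    BaselineRateTable,
    DataError,
    DomainError,
    ExposureProfile,
    RADSSettings,
    cumulative_hazard,
    degenerate_weight_set,
    excess_hazard,
    rads,
    rads_point_estimate,
    weighted_dose,
)

from conftest import flat_baseline, make_spec


class TestWeightedDose:
    def test_neutron_component_weighted_by_rbe(self):
        assert weighted_dose(0.1, 0.01, 10.0) == pytest.approx(0.2)

    def test_no_neutron_component(self):
        assert weighted_dose(0.34, 0.0, 10.0) == 0.34

    def test_unit_rbe_degenerates_to_sum(self):
        assert weighted_dose(0.0, 0.05, 1.0) == 0.05

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            weighted_dose(-0.1, 0.0, 10.0)
        with pytest.raises(DomainError):
            weighted_dose(0.1, 0.0, 0.0)


class TestExcessHazard:
    def test_zero_excess_risk_gives_zero(self, settings):
        assert excess_hazard(0.0, 0.0, 0.01, settings) == 0.0

    def test_mixed_transfer_with_ddref(self):
        s = RADSSettings(ddref=2.0)
        # (0.5 * 1.0 * 0.01 + 0.5 * 100 / 10000) / 2
        assert excess_hazard(1.0, 100.0, 0.01, s) == pytest.approx(0.005, rel=1e-12)

    def test_pure_multiplicative_transfer(self):
        s = RADSSettings(ddref=1.0, transfer_weight_err=1.0, transfer_weight_ear=0.0)
        assert excess_hazard(1.0, 0.0, 0.02, s) == pytest.approx(0.02, rel=1e-12)

    def test_ear_only_ddref_scope(self):
        s = RADSSettings(ddref=2.0, ddref_scope="ear_only")
        # 0.5 * 1.0 * 0.01 + (0.5 * 100/10000) / 2
        assert excess_hazard(1.0, 100.0, 0.01, s) == pytest.approx(0.0075, rel=1e-12)

    def test_negative_hazard_floored(self, settings):
        assert excess_hazard(-5.0, 0.0, 0.01, settings) == 0.0


class TestCumulativeHazard:
    def test_constant_integrand_is_exact(self):
        # h = 0.01/PY over [45, 65] -> H = 0.2, exact for the trapezoid rule
        s = RADSSettings(ddref=1.0, transfer_weight_err=0.0,
                         transfer_weight_ear=1.0, latency=5.0)
        profile = ExposureProfile(1.0, 40.0, 65.0, "male")
        provider = lambda ages: (np.zeros_like(ages), np.full_like(ages, 100.0))
        H = cumulative_hazard(provider, flat_baseline(), profile, s)
        assert H == pytest.approx(0.2, rel=1e-12)

    def test_empty_integration_range(self, settings):
        profile = ExposureProfile(1.0, 60.0, 64.0, "male")  # a <= e + l
        provider = lambda ages: (np.ones_like(ages), np.zeros_like(ages))
        assert cumulative_hazard(provider, flat_baseline(), profile, settings) == 0.0

    def test_linear_integrand_is_exact(self):
        # h(u) = c * u with c = 0.001 over [0.001, 10]: trapezoid exact on
        # linear integrands; integration starts at e + l = 10^-3 ~ 0
        s = RADSSettings(ddref=1.0, transfer_weight_err=0.0,
                         transfer_weight_ear=1.0, latency=0.0, grid_step=1.0)
        profile = ExposureProfile(1.0, 0.001, 10.0, "male")
        provider = lambda ages: (np.zeros_like(ages), 10.0 * ages)
        H = cumulative_hazard(provider, flat_baseline(), profile, s)
        exact = 0.001 * (10.0 ** 2 - 0.001 ** 2) / 2.0
        assert H == pytest.approx(exact, rel=1e-9)

    def test_interval_additivity(self, registry, baseline, settings, weight_sets):
        ws = weight_sets[("BIC", "original")]
        specs = registry

        def H(e, a):
            profile = ExposureProfile(1.0, 40.0, a, "female")
            from radsurv.mmi import averaged_excess_risk_curve
            provider = lambda ages: (
                averaged_excess_risk_curve(ws, "ERR", specs, profile, ages),
                averaged_excess_risk_curve(ws, "EAR", specs, profile, ages))
            s = settings.with_(latency=e - 40.0)
            return cumulative_hazard(provider, baseline, profile, s)

        total = H(45.0, 65.0)
        assert total > 0
        assert abs(H(45.0, 55.0) + H(55.0, 65.0) - total) < 1e-12

    def test_baseline_coverage_gap_reported(self, settings):
        rows = [{"age": float(a), "sex": sex, "rate_per_100000": 100.0}
                for a in range(40, 60) for sex in ("male", "female")]
        short = BaselineRateTable(pd.DataFrame(rows))
        profile = ExposureProfile(1.0, 40.0, 80.0, "male")
        provider = lambda ages: (np.ones_like(ages), np.zeros_like(ages))
        with pytest.raises(DataError, match="cover"):
            cumulative_hazard(provider, short, profile, settings)


class TestRADSTransform:
    def test_zero_hazard_zero_rads(self):
        assert rads(0.0) == 0.0

    def test_small_hazard(self):
        assert rads(0.0247) == pytest.approx(1.0 - math.exp(-0.0247), rel=1e-12)
        assert rads(0.0247) == pytest.approx(0.02440, abs=5e-6)

    def test_large_hazard_approaches_one_from_below(self):
        assert 0.9999 < rads(10.0) < 1.0

    def test_negative_hazard_rejected(self):
        with pytest.raises(DomainError):
            rads(-0.01)

    @hsettings(max_examples=100, derandomize=True)
    @given(H=st.floats(0.0, 5.0))
    def test_bounds_and_small_hazard_expansion(self, H):
        value = rads(H)
        assert 0.0 <= value < 1.0
        assert (value == 0.0) == (H == 0.0)
        assert abs(value - H) <= H * H / 2.0 + 1e-15

    def test_strictly_increasing(self):
        grid = np.linspace(0.0, 3.0, 50)
        vals = rads(grid)
        assert np.all(np.diff(vals) > 0)


class TestRADSPointEstimate:
    def test_zero_coefficients_give_zero(self, baseline, settings):
        specs = [make_spec("GRANT_L", endpoint="ERR"),
                 make_spec("GRANT_L", endpoint="EAR")]
        ws = degenerate_weight_set("GRANT_L")
        profile = ExposureProfile(1.0, 40.0, 65.0, "male")
        assert rads_point_estimate(ws, specs, baseline, profile, settings) == 0.0

    def test_constant_hazard_closed_form(self):
        # single GRANT_L ERR model, neutral modifiers, flat baseline:
        # h = w_err * alpha * D * m / DDREF is constant over the window
        m = 0.01
        alpha, D = 0.4, 1.0
        s = RADSSettings(ddref=2.0, latency=5.0)
        specs = [make_spec("GRANT_L", endpoint="ERR", alpha=alpha),
                 make_spec("GRANT_L", endpoint="EAR")]
        ws = degenerate_weight_set("GRANT_L")
        profile = ExposureProfile(D, 40.0, 65.0, "male")
        h = 0.5 * alpha * D * m / 2.0
        expected = 1.0 - math.exp(-h * 20.0)
        got = rads_point_estimate(ws, specs, flat_baseline(1000.0), profile, s)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_dose_for_linear_models(self, registry, baseline,
                                                settings, weight_sets):
        ws = weight_sets[("AIC", "same")]  # linear + LQ UNSCEAR mix
        values = [rads_point_estimate(
            ws, registry, baseline,
            ExposureProfile(d, 40.0, 65.0, "male"), settings)
            for d in (0.05, 0.17, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_quadrature_converges_under_grid_halving(self, registry, baseline,
                                                     weight_sets, lunar_male):
        ws = weight_sets[("BIC", "original")]
        coarse = rads_point_estimate(ws, registry, baseline, lunar_male,
                                     RADSSettings(grid_step=1.0))
        half = rads_point_estimate(ws, registry, baseline, lunar_male,
                                   RADSSettings(grid_step=0.5))
        quarter = rads_point_estimate(ws, registry, baseline, lunar_male,
                                      RADSSettings(grid_step=0.25))
        assert abs(half - coarse) < 1e-6
        # second-order quadrature: each halving shrinks the change ~4x
        assert abs(quarter - half) < abs(half - coarse) / 2.0


class TestBaselineTable:
    def test_csv_round_trip(self, tmp_path, baseline):
        path = tmp_path / "baseline.csv"
        baseline.to_csv(path)
        loaded = BaselineRateTable.from_csv(path)
        pd.testing.assert_frame_equal(loaded.table, baseline.table)

    def test_unit_conversion_happens_once(self):
        table = flat_baseline(1000.0)
        np.testing.assert_allclose(table.rate_fractions("male"), 0.01)

    def test_interpolation_flat_beyond_edges_linear_between(self):
        rows = [{"age": a, "sex": sex, "rate_per_100000": r}
                for (a, r) in [(0.0, 100.0), (10.0, 300.0)]
                for sex in ("male", "female")]
        table = BaselineRateTable(pd.DataFrame(rows))
        # midpoints at 5 and 15; linear in between, clamped outside
        got = table.interpolate("male", [0.0, 5.0, 10.0, 15.0, 40.0])
        np.testing.assert_allclose(got * 1e5, [100.0, 100.0, 200.0, 300.0, 300.0])

    def test_requires_both_sexes_and_increasing_bands(self):
        male_only = pd.DataFrame([{"age": 0.0, "sex": "male",
                                   "rate_per_100000": 1.0}])
        with pytest.raises(DataError):
            BaselineRateTable(male_only)
        dup = pd.DataFrame([{"age": 0.0, "sex": s, "rate_per_100000": 1.0}
                            for s in ("male", "female")] * 2)
        with pytest.raises(DataError):
            BaselineRateTable(dup)
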