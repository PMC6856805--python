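import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pharmera.errors import FitFailureError, InvalidParameterError
from pharmera.fate import (MineralizationCurve, RateConstant, SorptionRecord,
                           TimeUnit, convert_rate, dt50_from_rate,
                           estimate_stp_removal, fit_first_order, koc,
                           rate_from_dt50)
from pharmera.synthetic import gen_mineralization_curve


class TestConvertRate:
    def test_hour_to_minute(self):
        r = convert_rate(RateConstant(0.0174, TimeUnit.per_hour), TimeUnit.per_minute)
        assert r.value == pytest.approx(0.00029, abs=5e-6)  # 2 sig figs

    def test_zero_stays_zero(self):
        assert convert_rate(RateConstant(0.0, TimeUnit.per_day), TimeUnit.per_minute).value == 0.0

    def test_minute_to_hour(self):
        r = convert_rate(RateConstant(0.006, TimeUnit.per_minute), TimeUnit.per_hour)
        assert r.value == pytest.approx(0.36)

    def test_unknown_unit_rejected(self):
        with pytest.raises(InvalidParameterError):
            convert_rate(RateConstant(1.0, TimeUnit.per_hour), "per_fortnight")

    @settings(derandomize=True)
    @given(v=st.floats(0, 1e3),
           u=st.sampled_from(list(TimeUnit)), t=st.sampled_from(list(TimeUnit)))
    def test_round_trip_exact(self, v, u, t):
        r = RateConstant(v, u)
        back = convert_rate(convert_rate(r, t), u)
        assert back.value == pytest.approx(v, rel=1e-12, abs=0.0)


class TestDt50:
    def test_biodegradation_rate(self):
        assert dt50_from_rate(RateConstant(0.0174, TimeUnit.per_hour)) == pytest.approx(39.8, abs=0.05)

    def test_ln2_rate_gives_unit_half_life(self):
        assert dt50_from_rate(RateConstant(math.log(2), TimeUnit.per_day)) == pytest.approx(1.0)

    def test_sediment_half_life_consistency(self):
        assert dt50_from_rate(RateConstant(0.0495, TimeUnit.per_day)) == pytest.approx(14.0, abs=0.01)

    def test_inverse(self):
        k = rate_from_dt50(14.0)
        assert dt50_from_rate(k) == pytest.approx(14.0)

    def test_zero_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            dt50_from_rate(RateConstant(0.0, TimeUnit.per_hour))

    def test_unit_consistency_after_conversion(self):
        k = RateConstant(0.0174, TimeUnit.per_hour)
        dt50_h = dt50_from_rate(k)
        dt50_min = dt50_from_rate(convert_rate(k, TimeUnit.per_minute))
        assert dt50_min == pytest.approx(dt50_h * 60.0)


class TestFitFirstOrder:
    @pytest.mark.parametrize("k_per_h,plateau", [(0.0174, 82.2), (0.006 * 60, 82.2)])
    def test_recovers_noiseless_parameters(self, k_per_h, plateau):
        curve = gen_mineralization_curve(k_per_h, plateau, noise_sd=0.0)
        fit = fit_first_order(curve)
        assert fit.k.value == pytest.approx(k_per_h, rel=0.01)
        assert fit.plateau == pytest.approx(plateau, rel=0.01)

    def test_all_zero_curve_fails_with_diagnostics(self):
        curve = MineralizationCurve(times=(1, 2, 3, 4),
                                    cumulative_mineralized=(0, 0, 0, 0))
        with pytest.raises(FitFailureError) as err:
            fit_first_order(curve)
        assert "values" in err.value.diagnostics

    def test_too_few_points_fails(self):
        curve = MineralizationCurve(times=(1, 2, 3),
                                    cumulative_mineralized=(1, 2, 3))
        with pytest.raises(FitFailureError):
            fit_first_order(curve)

    def test_recovery_under_noise(self):
        curve = gen_mineralization_curve(0.0174, 82.2, noise_sd=0.05, seed=7)
        fit = fit_first_order(curve)
        assert fit.k.value == pytest.approx(0.0174, rel=0.10)


class TestMineralizationCurve:
    def test_rejects_decreasing_times(self):
        with pytest.raises(InvalidParameterError):
            MineralizationCurve(times=(2, 1), cumulative_mineralized=(1, 2))

    def test_rejects_percent_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            MineralizationCurve(times=(1, 2), cumulative_mineralized=(0, 150))

    def test_allows_small_dips_within_tolerance(self):
        MineralizationCurve(times=(1, 2, 3, 4),
                            cumulative_mineralized=(50, 45, 60, 70))

    def test_rejects_large_drop(self):
        with pytest.raises(InvalidParameterError):
            MineralizationCurve(times=(1, 2), cumulative_mineralized=(80, 10))


class TestKoc:
    def test_normalization(self):
        assert koc(SorptionRecord(kd=13.0, organic_carbon_fraction=0.35)) == pytest.approx(37.1, abs=0.05)

    def test_zero_kd(self):
        assert koc(SorptionRecord(kd=0.0, organic_carbon_fraction=0.5)) == 0.0

    def test_identity_at_full_carbon(self):
        assert koc(SorptionRecord(kd=5.0, organic_carbon_fraction=1.0)) == 5.0

    def test_zero_foc_rejected(self):
        with pytest.raises(InvalidParameterError):
            SorptionRecord(kd=1.0, organic_carbon_fraction=0.0)


class TestStpRemovalEstimator:
    def test_slow_biodegradation_scenario(self):
        r = estimate_stp_removal(RateConstant(0.0174, TimeUnit.per_hour))
        assert r == pytest.approx(0.12, abs=0.02)

    def test_zero_rate_gives_zero(self):
        assert estimate_stp_removal(RateConstant(0.0, TimeUnit.per_hour)) == 0.0

    def test_fast_biodegradation_scenario(self):
        r = estimate_stp_removal(RateConstant(0.006, TimeUnit.per_minute))
        assert r == pytest.approx(0.731, abs=0.02)

    @settings(derandomize=True)
    @given(k=st.floats(1e-6, 10), tau=st.floats(0.1, 100), dk=st.floats(1e-6, 1))
    def test_strictly_increasing_and_bounded(self, k, tau, dk):
        lo = estimate_stp_removal(RateConstant(k, TimeUnit.per_hour), tau)
        hi = estimate_stp_removal(RateConstant(k + dk, TimeUnit.per_hour), tau)
        assert 0.0 < lo < hi < 1.0
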