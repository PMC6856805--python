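import pytest
from hypothesis import given, settings, strategies as st

from pharmera.errors import InvalidParameterError, NoDataError
from pharmera.risk import (ROUNDING_POLICIES, AdeDerivation, IntakeScenario,
                           Verdict, daily_intake, derive_ade,
                           exceedance_summary, fish_tissue_concentration,
                           mtdi_scale, risk_quotient, secondary_poisoning_rq,
                           select_ade)
from pharmera.substance import prodrug_to_active


class TestRiskQuotient:
    def test_initial_pec_vs_ec10_pnec(self):
        rq = risk_quotient(0.299, 0.58)
        assert round(rq.quotient, 3) == 0.516
        assert rq.verdict is Verdict.no_significant_risk

    def test_highest_stp_pec_vs_stp_pnec(self):
        rq = risk_quotient(8.83, 6900.0)
        assert float(f"{rq.quotient:.3g}") == 0.00128

    def test_boundary_quotient_of_one_is_not_flagged(self):
        rq = risk_quotient(0.5, 0.5)
        assert rq.quotient == 1.0
        assert rq.verdict is Verdict.no_significant_risk

    def test_above_one_is_flagged(self):
        assert risk_quotient(1.0, 0.9).verdict is Verdict.potential_risk

    def test_zero_pnec_rejected(self):
        with pytest.raises(InvalidParameterError):
            risk_quotient(1.0, 0.0)

    @settings(derandomize=True)
    @given(e=st.floats(0, 1e3), scale=st.floats(0.1, 10), t=st.floats(1e-3, 1e3))
    def test_linear_in_exposure(self, e, scale, t):
        assert risk_quotient(e * scale, t).quotient == pytest.approx(
            risk_quotient(e, t).quotient * scale, rel=1e-9, abs=1e-12)


class TestExceedanceSummary:
    def test_fraction_from_plain_values(self):
        values = [0.1] * 105 + [2.0] * 5
        res = exceedance_summary(values, 0.58)
        assert res["n_at_risk"] == 5
        assert res["fraction_at_risk"] == pytest.approx(5 / 110)
        assert res["fraction_at_risk"] + res["fraction_safe"] == pytest.approx(1.0)

    def test_all_below(self):
        assert exceedance_summary([0.1, 0.2], 1.0)["fraction_at_risk"] == 0.0

    def test_all_above(self):
        assert exceedance_summary([2.0, 3.0], 1.0)["fraction_at_risk"] == 1.0

    def test_empty_raises(self):
        with pytest.raises(NoDataError):
            exceedance_summary([], 1.0)


class TestAdeDerivation:
    def test_teratology_chain_two_decimals(self):
        d = AdeDerivation(label="teratology", point_of_departure=2.0,
                          pod_kind="NOEL", body_weight=60.0,
                          factors=((6.2, "interspecies"), (10, "intraspecies"),
                                   (1, "duration"), (10, "severity"), (1, "pod type")),
                          rounding="two_decimals")
        res = derive_ade(d)
        assert res.unrounded == pytest.approx(0.19355, abs=1e-4)
        assert res.value == 0.19

    def test_chronic_chain_rounds_down_to_one_sig_fig(self):
        d = AdeDerivation(label="chronic", point_of_departure=2.0,
                          pod_kind="NOAEL", body_weight=60.0,
                          factors=((6.2, "interspecies"), (10, "intraspecies"),
                                   (1, "duration"), (5, "severity"), (3, "pod type")),
                          rounding="down_one_sig_fig")
        res = derive_ade(d)
        assert res.unrounded == pytest.approx(0.129, abs=1e-3)
        assert res.value == pytest.approx(0.1)

    def test_unit_factors_give_pod_times_bw(self):
        d = AdeDerivation(label="x", point_of_departure=2.0, pod_kind="NOAEL",
                          body_weight=60.0, factors=((1.0, "none"),))
        assert derive_ade(d).unrounded == 120.0

    def test_factor_order_does_not_matter(self):
        f = ((6.2, "a"), (10.0, "b"), (5.0, "c"), (3.0, "d"))
        a = derive_ade(AdeDerivation("x", 2.0, "NOAEL", 60.0, f))
        b = derive_ade(AdeDerivation("x", 2.0, "NOAEL", 60.0, tuple(reversed(f))))
        assert a.unrounded == pytest.approx(b.unrounded, rel=1e-12)

    def test_empty_factor_chain_rejected(self):
        with pytest.raises(InvalidParameterError):
            AdeDerivation("x", 2.0, "NOAEL", 60.0, ())

    def test_factor_below_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            AdeDerivation("x", 2.0, "NOAEL", 60.0, ((0.5, "bad"),))

    def test_selection_takes_protective_minimum(self, fx):
        results = [derive_ade(d) for d in fx.ade_derivations]
        assert select_ade(results).value == pytest.approx(0.1)


class TestMtdiAndIntake:
    def test_human_to_otter_scaling(self):
        assert mtdi_scale(75.0, 60.0, 10.0) == pytest.approx(12.5)

    def test_equal_weights_identity(self):
        assert mtdi_scale(75.0, 60.0, 60.0) == 75.0

    def test_half_weight(self):
        assert mtdi_scale(75.0, 60.0, 30.0) == pytest.approx(37.5)

    def test_fish_tissue_concentration(self):
        assert fish_tissue_concentration(0.671, 6.22) == pytest.approx(4.17, abs=0.005)

    def test_otter_daily_intake(self):
        scen = IntakeScenario(consumer="top_predator", body_weight=10.0,
                              fish_intake=1.0, water_intake=0.79,
                              water_concentration=0.671,
                              fish_tissue_concentration=4.17)
        assert daily_intake(scen) == pytest.approx(4.7, abs=0.01)

    def test_human_daily_intake(self):
        scen = IntakeScenario(consumer="human", body_weight=60.0,
                              fish_intake=0.115, water_intake=2.0,
                              water_concentration=0.656,
                              fish_tissue_concentration=4.17)
        assert daily_intake(scen) == pytest.approx(1.792, abs=0.002)

    def test_zero_intake(self):
        scen = IntakeScenario(consumer="human", body_weight=60.0,
                              fish_intake=0.0, water_intake=0.0,
                              water_concentration=1.0,
                              fish_tissue_concentration=1.0)
        assert daily_intake(scen) == 0.0

    def test_secondary_poisoning_quotients(self):
        assert secondary_poisoning_rq(4.7, 12.5).quotient == pytest.approx(0.376)
        assert secondary_poisoning_rq(1.792, 75.0).quotient == pytest.approx(0.024, abs=0.001)
        assert secondary_poisoning_rq(5.0, 5.0).quotient == 1.0


def test_full_secondary_poisoning_chain_from_fixture(fx):
    """The whole worked chain from bundled constants alone:
    prodrug ADE 0.1 mg/d -> 0.0739 mg active -> 0.075 rounded -> MTDI 12.5
    -> otter intake 4.7 (RQ 0.376) and human intake 1.792 (RQ 0.024)."""
    from pharmera.substance import select_bcf
    ade = select_ade(derive_ade(d) for d in fx.ade_derivations)
    mpa_mg = prodrug_to_active(ade.value, fx.profile.molecular_weight,
                               fx.profile.prodrug_molecular_weight)
    assert mpa_mg == pytest.approx(0.0739, abs=5e-5)
    mpa_rounded = ROUNDING_POLICIES[fx.ade_mpa_rounding](mpa_mg)
    assert mpa_rounded == pytest.approx(0.075)
    mtdi = mtdi_scale(mpa_rounded * 1000, 60.0, 10.0)
    assert mtdi == pytest.approx(12.5)
    bcf = select_bcf(fx.profile.bcf_by_ph, 5, 9).selected_bcf
    pec = fx.reference_concentrations["rhine_mean_flow_99th_pec_ug_L"]
    fish = fish_tissue_concentration(pec, bcf)
    otter = daily_intake(IntakeScenario(
        consumer="top_predator", body_weight=10.0, fish_intake=1.0,
        water_intake=0.79, water_concentration=pec,
        fish_tissue_concentration=fish))
    assert otter == pytest.approx(4.7, abs=0.01)
    assert secondary_poisoning_rq(otter, mtdi).quotient == pytest.approx(0.376, abs=0.001)
    human = daily_intake(IntakeScenario(
        consumer="human", body_weight=60.0, fish_intake=0.115,
        water_intake=2.0,
        water_concentration=fx.reference_concentrations["max_surface_water_mec_ug_L"],
        fish_tissue_concentration=fish))
    assert human == pytest.approx(1.792, abs=0.001)
    assert secondary_poisoning_rq(human, mpa_rounded * 1000).quotient == pytest.approx(0.024, abs=0.0005)
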