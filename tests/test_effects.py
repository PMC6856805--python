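import pytest

from pharmera.effects import (EcotoxEndpoint, MicRecord, pbt_screen,
                              pnec_abr, pnec_abr_lowest_mic,
                              pnec_abr_percentile, pnec_aquatic, pnec_stp,
                              round_down_mic_series)
from pharmera.errors import InvalidParameterError, NoDataError
from pharmera.substance import SubstanceProfile


def noec(taxon, value):
    return EcotoxEndpoint(taxon_group=taxon, endpoint_kind="NOEC", value=value)


def ec10(taxon, value):
    return EcotoxEndpoint(taxon_group=taxon, endpoint_kind="EC10", value=value)


NOECS = [noec("cyanobacterium", 83.9), noec("green_alga", 9.0),
         noec("daphnid", 630.0), noec("fish", 1.32)]
EC10S = [ec10("green_alga", 12.0), ec10("cyanobacterium", 155.0),
         ec10("daphnid", 929.0), ec10("fish", 5.8)]


class TestAquaticPnec:
    def test_noec_based(self):
        res = pnec_aquatic(NOECS, "NOEC")
        assert res.value == pytest.approx(0.132)
        assert res.basis.taxon_group.value == "fish"

    def test_ec10_based(self):
        res = pnec_aquatic(EC10S, "EC10")
        assert res.value == pytest.approx(0.58)
        assert res.basis.taxon_group.value == "fish"

    def test_identity_assessment_factor(self):
        assert pnec_aquatic([noec("fish", 10.0)], "NOEC", 1.0).value == 10.0

    def test_requested_kind_must_exist(self):
        with pytest.raises(NoDataError):
            pnec_aquatic(NOECS, "EC10")

    def test_non_aquatic_taxa_ignored(self):
        eps = NOECS + [noec("sludge_microorganisms", 0.001)]
        assert pnec_aquatic(eps, "NOEC").value == pytest.approx(0.132)

    def test_scales_inversely_with_af(self):
        assert pnec_aquatic(NOECS, "NOEC", 100.0).value == pytest.approx(0.0132)


class TestStpPnec:
    def test_sludge_respiration_ec10(self):
        assert pnec_stp(69_000.0).value == pytest.approx(6900.0)

    def test_identity_af(self):
        assert pnec_stp(100.0, 1.0).value == 100.0

    def test_simple_division(self):
        assert pnec_stp(100.0, 10.0).value == 10.0


class TestAbrPnec:
    def test_lowest_mic_method(self, fx):
        res = pnec_abr_lowest_mic(fx.mic_records)
        assert res.value == pytest.approx(312.5)

    def test_lowest_mic_single_record(self):
        assert pnec_abr_lowest_mic([MicRecord("X", "a", 100.0)]).value == 1000.0

    def test_lowest_mic_takes_minimum(self):
        mics = [MicRecord("X", "a", 50.0), MicRecord("Y", "b", 500.0)]
        assert pnec_abr_lowest_mic(mics).value == pytest.approx(500.0)

    def test_percentile_method_single_eligible_species(self, fx):
        res = pnec_abr_percentile(fx.mic_records)
        assert res.raw_value == pytest.approx(76.2, abs=0.1)
        assert res.value == 64.0
        assert res.basis["n_eligible_species"] == 1

    def test_percentile_filter_boundary(self):
        mics = [MicRecord("X", f"s{i}", 40.0) for i in range(9)]
        with pytest.raises(NoDataError, match="min_obs_per_species"):
            pnec_abr_percentile(mics)

    def test_percentile_two_eligible_species(self):
        mics = ([MicRecord("X", f"x{i}", 41.0) for i in range(10)]
                + [MicRecord("Y", f"y{i}", 100.0) for i in range(10)])
        res = pnec_abr_percentile(mics)
        assert res.raw_value == pytest.approx(200.0)

    def test_final_selection_is_lower_candidate(self, fx):
        low = pnec_abr_lowest_mic(fx.mic_records)
        perc = pnec_abr_percentile(fx.mic_records)
        assert pnec_abr(fx.mic_records).value == min(low.value, perc.value)

    def test_rounded_never_exceeds_raw(self, fx):
        res = pnec_abr_percentile(fx.mic_records)
        assert 0 < res.value <= res.raw_value


@pytest.mark.parametrize("raw,expected", [
    (76.2, 64.0), (64.0, 64.0), (63.9, 32.0), (0.3, 0.25), (1.5, 1.0),
])
def test_round_down_two_fold_dilution_series(raw, expected):
    assert round_down_mic_series(raw) == expected


class TestPbtScreen:
    def test_mpa_is_toxic_but_not_p_or_b(self, fx):
        v = pbt_screen(fx.profile, degradation_evidence=True,
                       endpoints=fx.aquatic_endpoints, cmr=True)
        assert v.persistent.verdict is False
        assert v.bioaccumulative.verdict is False
        assert v.toxic.verdict is True
        assert "NOEC" in v.toxic.rationale

    def test_high_bcf_triggers_bioaccumulation(self):
        profile = SubstanceProfile(name="x", molecular_weight=100.0,
                                   bcf_by_ph={7: 5000.0})
        v = pbt_screen(profile, degradation_evidence=True)
        assert v.bioaccumulative.verdict is True

    def test_no_chronic_data_and_no_cmr_is_undetermined(self):
        profile = SubstanceProfile(name="x", molecular_weight=100.0,
                                   bcf_by_ph={7: 1.0})
        v = pbt_screen(profile, degradation_evidence=True, endpoints=(),
                       cmr=False)
        assert v.toxic.verdict is None

    def test_missing_degradation_evidence_is_undetermined(self):
        v = pbt_screen(None, degradation_evidence=None)
        assert v.persistent.verdict is None
        assert v.bioaccumulative.verdict is None
        assert all(f.rationale for f in (v.persistent, v.bioaccumulative, v.toxic))
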