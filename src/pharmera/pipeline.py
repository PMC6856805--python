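"""End-to-end assessment chains built from the module-level operations.

:func:`assess_mpa` runs the complete tiered assessment for the bundled
mycophenolic-acid constants — exposure, effect thresholds, aquatic and
antibiotic-resistance risk quotients, the secondary-poisoning chain and
the PBT screen — and returns a nested report dictionary of plain floats
and strings, suitable for JSON serialization. Every number in the report
is computed at call time from the fixture constants; nothing is stored
pre-computed.
"""

from __future__ import annotations

from . import effects, exposure, fate, risk
from .substance import prodrug_to_active, select_bcf
from .synthetic import MpaFixture, mpa_fixture

__all__ = ["assess_mpa"]

UG_PER_MG = 1000.0


def assess_mpa(fixture: MpaFixture | None = None) -> dict:
    """Full tiered ERA for mycophenolic acid from the bundled constants."""
    fx = fixture or mpa_fixture()
    profile = fx.profile
    mw_a = profile.molecular_weight
    mw_p = profile.prodrug_molecular_weight

    # --- bioconcentration -------------------------------------------------
    bcf = select_bcf(profile.bcf_by_ph, 5.0, 9.0)

    # --- exposure ---------------------------------------------------------
    exp = fx.exposure
    initial = exposure.derive_pec(
        exp["eu_highest_per_capita_use_ug_d"],
        exposure.ExposureScenario(
            wastewater_per_capita=exp["wastewater_per_capita_L_d"],
            treated_fraction=1.0, stp_removal=0.0,
            dilution_factor=exp["default_dilution_factor"]))

    removals = fx.fate["stp_removals"]
    highest_stp = exp["highest_country_stp_pec_ug_L"]
    refined_highest = {}
    for r in removals:
        scen = exposure.ExposureScenario(
            wastewater_per_capita=exp["wastewater_per_capita_L_d"],
            treated_fraction=exp["treated_fraction"], stp_removal=r,
            dilution_factor=exp["highest_country_dilution_factor"])
        refined_highest[r] = exposure.pec_surface(highest_stp, scen)

    # --- STP removal estimator vs the published scenario removals --------
    k_list = [
        fate.RateConstant(fx.fate["k_biodeg_per_hour"], fate.TimeUnit.per_hour),
        fate.RateConstant(fx.fate["k_biodeg_sbr_cycle1_per_min"], fate.TimeUnit.per_minute),
        fate.RateConstant(fx.fate["k_biodeg_sbr_cycle5_per_min"], fate.TimeUnit.per_minute),
    ]
    removal_estimates = [fate.estimate_stp_removal(k) for k in k_list]

    # --- effect thresholds ------------------------------------------------
    pnec_noec = effects.pnec_aquatic(fx.aquatic_endpoints, "NOEC")
    pnec_ec10 = effects.pnec_aquatic(fx.aquatic_endpoints, "EC10")
    pnec_stp = effects.pnec_stp(fx.sludge_ec10)
    abr_low = effects.pnec_abr_lowest_mic(fx.mic_records)
    abr_perc = effects.pnec_abr_percentile(fx.mic_records)
    abr = effects.pnec_abr(fx.mic_records)

    # --- aquatic and resistance risk quotients ----------------------------
    ref = fx.reference_concentrations
    rq = {
        "initial_sw_vs_pnec_ec10": risk.risk_quotient(initial.surface_water_pec, pnec_ec10),
        "initial_sw_vs_pnec_noec": risk.risk_quotient(initial.surface_water_pec, pnec_noec),
        "highest_stp_vs_pnec_stp": risk.risk_quotient(highest_stp, pnec_stp),
        "max_effluent_mec_vs_pnec_stp": risk.risk_quotient(ref["max_effluent_mec_ug_L"], pnec_stp),
        "highest_stp_vs_pnec_abr": risk.risk_quotient(highest_stp, abr),
        "max_effluent_mec_vs_pnec_abr": risk.risk_quotient(ref["max_effluent_mec_ug_L"], abr),
    }

    # --- secondary poisoning ----------------------------------------------
    ade_results = [risk.derive_ade(d) for d in fx.ade_derivations]
    selected = risk.select_ade(ade_results)
    ade_mpa_unrounded = prodrug_to_active(selected.value, mw_a, mw_p)
    ade_mpa = risk.ROUNDING_POLICIES[fx.ade_mpa_rounding](ade_mpa_unrounded)
    otter_cfg = fx.intake_defaults["top_predator"]
    human_cfg = fx.intake_defaults["human"]
    mtdi_otter = risk.mtdi_scale(ade_mpa * UG_PER_MG,
                                 human_cfg["body_weight"], otter_cfg["body_weight"])

    water_pec = ref["rhine_mean_flow_99th_pec_ug_L"]
    fish_conc = risk.fish_tissue_concentration(water_pec, bcf.selected_bcf)
    otter = risk.IntakeScenario(consumer="top_predator",
                                body_weight=otter_cfg["body_weight"],
                                fish_intake=otter_cfg["fish_intake"],
                                water_intake=otter_cfg["water_intake"],
                                water_concentration=water_pec,
                                fish_tissue_concentration=fish_conc)
    # the human drinking-water route uses the highest measured surface-water
    # concentration while the fish burden stays PEC-derived (mixed mode,
    # reproducing the published worst case); no drinking-water removal
    human = risk.IntakeScenario(consumer="human",
                                body_weight=human_cfg["body_weight"],
                                fish_intake=human_cfg["fish_intake"],
                                water_intake=human_cfg["water_intake"],
                                water_concentration=ref["max_surface_water_mec_ug_L"],
                                fish_tissue_concentration=fish_conc)
    otter_intake = risk.daily_intake(otter)
    human_intake = risk.daily_intake(human)
    otter_rq = risk.secondary_poisoning_rq(otter_intake, mtdi_otter)
    human_rq = risk.secondary_poisoning_rq(human_intake, ade_mpa * UG_PER_MG)

    # --- PBT screen -------------------------------------------------------
    pbt = effects.pbt_screen(profile, fx.degradation_evidence,
                             fx.aquatic_endpoints, cmr=fx.cmr)

    return {
        "bcf": {"selected": bcf.selected_bcf,
                "values_used": list(bcf.values_used),
                "ph_range": [bcf.ph_low, bcf.ph_high]},
        "exposure": {
            "initial_stp_pec_ug_L": initial.stp_influent_pec,
            "initial_sw_pec_ug_L": initial.surface_water_pec,
            "highest_country_stp_pec_ug_L": highest_stp,
            "highest_country_sw_pec_ug_L_by_removal": refined_highest,
        },
        "stp_removal_estimates": {
            "scenario_removals": list(removals),
            "single_tank_estimates": removal_estimates,
        },
        "pnec": {
            "aquatic_noec": pnec_noec.to_dict(),
            "aquatic_ec10": pnec_ec10.to_dict(),
            "stp": pnec_stp.to_dict(),
            "abr_lowest_mic": abr_low.to_dict(),
            "abr_percentile": abr_perc.to_dict(),
            "abr_selected": abr.to_dict(),
        },
        "risk_quotients": {k: v.to_row() for k, v in rq.items()},
        "secondary_poisoning": {
            "ade_candidates_mg_d": [r.to_dict() for r in ade_results],
            "ade_selected_mg_d": selected.value,
            "ade_active_unrounded_mg_d": ade_mpa_unrounded,
            "ade_active_mg_d": ade_mpa,
            "mtdi_top_predator_ug_d": mtdi_otter,
            "fish_tissue_ug_kg": fish_conc,
            "top_predator_intake_ug_d": otter_intake,
            "top_predator_rq": otter_rq.to_row(),
            "human_intake_ug_d": human_intake,
            "human_rq": human_rq.to_row(),
        },
        "pbt": pbt.to_dict(),
    }
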