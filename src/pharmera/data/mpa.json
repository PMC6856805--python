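{
  "notes": [
    "Literature-derived constants for mycophenolic acid (MPA) and its prodrug mycophenolate mofetil (MPM).",
    "Strain-level S. aureus MIC values other than the reported lowest (31.25 mg/L) and highest (125 mg/L) are synthetic stand-ins placed on the two-fold dilution series; only the lowest value and the observation count enter any derivation.",
    "eu_highest_per_capita_use_ug_d and highest_country dilution/stp values are back-computed from the published PEC table; country-level water-use and dilution inputs are not reproduced here."
  ],
  "substance": {
    "name": "mycophenolic acid",
    "molecular_weight": 320.34,
    "prodrug_name": "mycophenolate mofetil",
    "prodrug_molecular_weight": 433.5,
    "pka_values": [4.58, 8.045],
    "log_dow_by_ph": {"5": 2.28, "7": 0.48, "9": -1.54},
    "water_solubility_by_ph": {"5": 45.0, "7": 710.0},
    "vapor_pressure": 4.27e-07,
    "bcf_by_ph": {"1": 486.0, "5": 161.0, "6": 23.2, "7": 2.49, "8": 1.0, "9": 1.0, "10": 1.0},
    "hydrolysis_loss_screen": {"5": 46.15, "7": 29.03, "9": 36.67},
    "photolysis_rate_by_condition": {
      "ph5_winter": 0.0017, "ph5_summer": 0.0059,
      "ph7_winter": 0.0049, "ph7_summer": 0.018,
      "ph9_winter": 0.0087, "ph9_summer": 0.031,
      "uv_c": 0.0284, "artificial_sunlight": 0.004
    }
  },
  "fate": {
    "k_biodeg_per_hour": 0.0174,
    "k_biodeg_sbr_cycle1_per_min": 0.0017,
    "k_biodeg_sbr_cycle5_per_min": 0.006,
    "k_hydrolysis_per_min": 0.0002,
    "mineralization_plateau_percent": 82.2,
    "sediment_dt50_days": 14.0,
    "kd_soil_L_per_kg": [2.2, 2.8, 5.0],
    "kd_sludge_L_per_kg": [9.3, 13.0],
    "koc_max_L_per_kg": 37.0,
    "stp_removals": [0.12, 0.436, 0.731]
  },
  "exposure": {
    "eu_highest_per_capita_use_ug_d": 598.0,
    "wastewater_per_capita_L_d": 200.0,
    "treated_fraction": 0.8,
    "default_dilution_factor": 10.0,
    "highest_country_stp_pec_ug_L": 8.83,
    "highest_country_dilution_factor": 15.0
  },
  "aquatic_endpoints": [
    {"taxon_group": "cyanobacterium", "endpoint_kind": "NOEC", "value": 83.9, "species": "Anabaena flos-aquae", "duration": "72 h", "basis": "growth rate and yield"},
    {"taxon_group": "green_alga", "endpoint_kind": "NOEC", "value": 9.0, "species": "Raphidocelis subcapitata", "duration": "96 h", "basis": "growth rate"},
    {"taxon_group": "daphnid", "endpoint_kind": "NOEC", "value": 630.0, "species": "Daphnia magna", "duration": "21 d", "basis": "reproduction"},
    {"taxon_group": "fish", "endpoint_kind": "NOEC", "value": 1.32, "species": "Danio rerio", "duration": "57 d", "basis": "F1 length and wet weight"},
    {"taxon_group": "cyanobacterium", "endpoint_kind": "EC10", "value": 155.0, "species": "Anabaena flos-aquae", "duration": "72 h", "basis": "growth rate"},
    {"taxon_group": "green_alga", "endpoint_kind": "EC10", "value": 12.0, "species": "Raphidocelis subcapitata", "duration": "96 h", "basis": "growth rate"},
    {"taxon_group": "daphnid", "endpoint_kind": "EC10", "value": 929.0, "species": "Daphnia magna", "duration": "21 d", "basis": "reproduction"},
    {"taxon_group": "fish", "endpoint_kind": "EC10", "value": 5.8, "species": "Danio rerio", "duration": "57 d", "basis": "posthatch survival"}
  ],
  "sludge_ec10_ug_L": 69000.0,
  "sludge_ec50_ug_L": 2213000.0,
  "mic_records": [
    {"species": "Staphylococcus aureus", "strain": "SA-01", "mic": 31.25},
    {"species": "Staphylococcus aureus", "strain": "SA-02", "mic": 31.25},
    {"species": "Staphylococcus aureus", "strain": "SA-03", "mic": 62.5},
    {"species": "Staphylococcus aureus", "strain": "SA-04", "mic": 62.5},
    {"species": "Staphylococcus aureus", "strain": "SA-05", "mic": 62.5},
    {"species": "Staphylococcus aureus", "strain": "SA-06", "mic": 62.5},
    {"species": "Staphylococcus aureus", "strain": "SA-07", "mic": 62.5},
    {"species": "Staphylococcus aureus", "strain": "SA-08", "mic": 125.0},
    {"species": "Staphylococcus aureus", "strain": "SA-09", "mic": 125.0},
    {"species": "Staphylococcus aureus", "strain": "SA-10", "mic": 125.0},
    {"species": "Staphylococcus aureus", "strain": "SA-11", "mic": 125.0},
    {"species": "Staphylococcus aureus", "strain": "SA-12", "mic": 125.0},
    {"species": "Staphylococcus epidermidis", "strain": "SE-01", "mic": 125.0},
    {"species": "Shigella flexneri", "strain": "SF-01", "mic": 250.0},
    {"species": "Shigella flexneri", "strain": "SF-02", "mic": 500.0},
    {"species": "Proteus vulgaris", "strain": "PV-01", "mic": 250.0},
    {"species": "Proteus vulgaris", "strain": "PV-02", "mic": 500.0},
    {"species": "Escherichia coli", "strain": "EC-01", "mic": 250.0},
    {"species": "Escherichia coli", "strain": "EC-02", "mic": 500.0},
    {"species": "Pseudomonas aeruginosa", "strain": "PA-01", "mic": 250.0},
    {"species": "Pseudomonas aeruginosa", "strain": "PA-02", "mic": 500.0},
    {"species": "Salmonella enteritidis", "strain": "SEN-01", "mic": 125.0},
    {"species": "Salmonella enteritidis", "strain": "SEN-02", "mic": 250.0}
  ],
  "ade_derivations": [
    {
      "label": "chronic_oral_rat",
      "point_of_departure": 2.0,
      "pod_kind": "NOAEL",
      "body_weight": 60.0,
      "rounding": "down_one_sig_fig",
      "factors": [
        [6.2, "extrapolation from rats to humans"],
        [10.0, "variability between individuals"],
        [1.0, "study duration of 1 yr for rodents"],
        [5.0, "severity of systemic toxicity (hematopoiesis, immunotoxicity)"],
        [3.0, "use of an established NOAEL instead of an NOEL"]
      ]
    },
    {
      "label": "teratology_rat",
      "point_of_departure": 2.0,
      "pod_kind": "NOEL",
      "body_weight": 60.0,
      "rounding": "two_decimals",
      "factors": [
        [6.2, "extrapolation from rats to humans"],
        [10.0, "variability between individuals"],
        [1.0, "whole period of organogenesis covered"],
        [10.0, "teratogenic effect without maternal toxicity"],
        [1.0, "use of an established NOEL"]
      ]
    }
  ],
  "ade_mpa_rounding": "nearest_0p005",
  "intake_defaults": {
    "top_predator": {"body_weight": 10.0, "fish_intake": 1.0, "water_intake": 0.79},
    "human": {"body_weight": 60.0, "fish_intake": 0.115, "water_intake": 2.0}
  },
  "reference_concentrations": {
    "rhine_mean_flow_99th_pec_ug_L": 0.671,
    "max_surface_water_mec_ug_L": 0.656,
    "max_effluent_mec_ug_L": 4.19,
    "mec_loq_ug_L": 0.001,
    "n_mecs": 110,
    "n_mec_nondetects": 51
  },
  "cmr": true,
  "degradation_evidence": true
}
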