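{
  "version": "2017-workshop-1.0",
  "case_definition": {
    "interdental_cal_min_mm": 1,
    "interdental_min_nonadjacent_teeth": 2,
    "buccal_lingual_cal_min_mm": 3,
    "buccal_lingual_min_teeth": 2
  },
  "staging": {
    "severity_cal_stage_i_mm": [1, 2],
    "severity_cal_stage_ii_mm": [3, 4],
    "severity_cal_stage_iii_min_mm": 5,
    "complexity_pd_min_mm": 6,
    "complexity_furcation_min_class": 2,
    "stage_iv_teeth_lost_min": 5,
    "stage_iv_remaining_teeth_below": 20
  },
  "grading": {
    "ratio_a_below": 0.25,
    "ratio_c_above": 1.0,
    "smoking_grade_c_min_per_day": 10,
    "hba1c_grade_c_min_percent": 7.0
  },
  "extent": {
    "generalized_min_fraction": 0.30
  },
  "gingival": {
    "gingivitis_bop_min_fraction": 0.10,
    "generalized_gingivitis_bop_fraction": 0.30
  },
  "secondary": {
    "tooth_prosthesis_flags": ["defective_restoration", "subgingival_margin", "enamel_projection", "root_proximity"],
    "occlusal_trauma_flags": ["fremitus", "widened_pdl"],
    "occlusal_trauma_mobility_min_class": 2,
    "mucogingival_recession_min_mm": 2,
    "endo_perio_pd_min_mm": 6,
    "abscess_suppuration_pd_min_mm": 4,
    "systemic_manifestation_codes": [
      "papillon_lefevre_syndrome",
      "leukocyte_adhesion_deficiency",
      "hypophosphatasia",
      "chediak_higashi_syndrome",
      "down_syndrome",
      "ehlers_danlos_syndrome_iv_viii",
      "langerhans_cell_histiocytosis",
      "glycogen_storage_disease",
      "congenital_neutropenia"
    ]
  }
}
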