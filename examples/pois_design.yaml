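# Perioperative enhanced-recovery study design: three consecutive treatment
# blocks (preoperative, intraoperative, postoperative), 18 protocol items,
# 7 confounders acting on every block, 5 acting on postoperative items only,
# 3 external covariates acting directly on the outcomes, and two outcome
# sets each spanning two latent dimensions.
id_column: id

blocks:
  - index: 1
    treatments:
      - {name: preop_stay_days, kind: continuous}
      - {name: no_bowel_prep, kind: binary}
      - {name: glucidic_drink, kind: binary}
      - {name: premedication, kind: binary}
  - index: 2
    treatments:
      - {name: iv_fluids_mlkgh, kind: continuous}
      - {name: epidural_anesthesia, kind: binary}
      - {name: antibiotic_prophylaxis, kind: binary}
      - {name: normothermia, kind: binary}
      - {name: ponv_prophylaxis, kind: binary}
      - {name: no_surgical_drainage, kind: binary}
  - index: 3
    treatments:
      - {name: iv_fluids_pod1_mlkg, kind: continuous}
      - {name: morphine, kind: binary}
      - {name: thromboembolism_prophylaxis, kind: binary}
      - {name: prokinetics, kind: binary}
      - {name: ngt_removal_pod0, kind: binary}
      - {name: iv_fluid_stop_pod2, kind: binary}
      - {name: uc_removal_pod1, kind: binary}
      - {name: ambulation_pod1, kind: binary}

confounders_all:
  - year_of_surgery
  - age
  - male_gender
  - asa_gt2
  - baseline_hb
  - preop_weight_loss
  - diabetes_mellitus

confounders_post:
  - {name: intraop_fluid_loss_mlkg, enters_at_block: 3}
  - {name: surgery_length_min, enters_at_block: 3}
  - {name: max_pain_pod1_4, enters_at_block: 3}
  - {name: laparotomy, enters_at_block: 3}
  - {name: surgical_stoma, enters_at_block: 3}

external_covariates:
  - colon_surgery
  - malignant_lesion
  - blood_transfusion

outcome_sets:
  primary:
    complications: [any_complication, ssi, medical_complication]
    discharge: [trd_after_pod5, discharge_after_pod6]
  secondary:
    gastrointestinal:
      [bowel_recovery_after_pod1, iv_fluid_resumption, ngt_replacement,
       ponv_occurrence]
    severe: [surgical_reintervention, hospital_readmission, death_within_pod30]

continuous_columns:
  - year_of_surgery
  - age
  - baseline_hb
  - intraop_fluid_loss_mlkg
  - surgery_length_min
  - max_pain_pod1_4
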