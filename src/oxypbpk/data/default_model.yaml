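# Default cholesterol / 4beta-hydroxycholesterol PBPK model configuration.
#
# Compound parameters are the published final model inputs; intrinsic
# clearances are the reverse-translated (CYP27A1, HLM) and optimized (CYP3A4,
# with CYP3A5/CYP3A7 siblings at 5.6% / 2.8% of the CYP3A total) values.
# Physiology is the mean healthy adult used for the derivations: body weight
# 67.5 kg (back-derived; the 4beta-OHC-side derivations used 63.5 kg, stored
# under `reference`), liver weight 1737.11 g, MPPGL 39.79 mg/g, hepatic blood
# flow 90 L/h.  CYP3A5 / CYP3A7 abundances are documented placeholders (the
# underlying population library is proprietary); the CYP3A5 extensive-
# metabolizer mean of 103 pmol/mg is calibrated so the EM/PM 4beta-OHC ratio
# falls in the reported 1.04-1.13 range.
name: cholesterol-4bohc-default
physiology:
  body_weight: 67.5        # kg
  liver_weight: 1737.11    # g
  mppgl: 39.79             # mg microsomal protein / g liver
  hepatic_blood_flow: 90.0 # L/h
  hematocrit: 0.45
  sex: male
  age: 35.0
  abundances:              # pmol/mg microsomal protein
    CYP3A4: 137.0
    CYP3A5: 1.0            # CYP3A5 poor-metabolizer baseline
    CYP3A7: 2.0            # adult residual expression (placeholder)
    CYP27A1: 41.93
enzymes:
  CYP3A4: {enzyme: CYP3A4, abundance_mean: 137.0, abundance_cv: 41.0, kdeg: 0.0193}
  CYP3A5: {enzyme: CYP3A5, abundance_mean: 103.0, abundance_cv: 41.0, kdeg: 0.0193}
  CYP3A7: {enzyme: CYP3A7, abundance_mean: 2.0, abundance_cv: 41.0, kdeg: 0.0193}
  CYP27A1: {enzyme: CYP27A1, abundance_mean: 41.93, abundance_cv: 30.0, kdeg: 0.0193}
compounds:
  cholesterol:
    name: cholesterol
    molecular_weight: 386.65
    logP: 7.02
    blood_to_plasma: 0.55
    fu_plasma: 0.0021
    vss: 0.10              # L/kg
    kp_liver: 3.07
    binding_protein: apolipoprotein B
    pathways:
      - {enzyme: CYP3A4, clint: 4.17e-7, basis: per_pmol}   # µL/min/pmol, optimized
      - {enzyme: CYP3A5, clint: 2.55e-8, basis: per_pmol}
      - {enzyme: CYP3A7, clint: 1.27e-8, basis: per_pmol}
      - {enzyme: CYP27A1, clint: 3.13e-3, basis: per_pmol}
      - {enzyme: HLM, clint: 0.350, basis: per_mg}          # µL/min/mg
  4b-hydroxycholesterol:
    name: 4b-hydroxycholesterol
    molecular_weight: 402.35
    logP: 6.16
    blood_to_plasma: 0.55
    fu_plasma: 0.0051
    vss: 0.05
    kp_liver: 3.87
    binding_protein: apolipoprotein B
    pathways:
      - {enzyme: CYP27A1, clint: 0.02, basis: per_pmol}
      - {enzyme: HLM, clint: 0.84, basis: per_mg}
dosing:
  cholesterol_infusion:
    compound: cholesterol
    route: iv_infusion
    dose: 1.73             # mg/kg/day, continuous IV infusion
    interval: 24.0
    start_day: 0.0
    duration_days: 700.0
perpetrators:
  # Literature-informed one-compartment PK conveniences, not model ground
  # truth; the induction parameters Ind_max = 16 and IndC50 = 0.32 µM are the
  # published rifampicin multiple-dose values.
  rifampicin:
    name: rifampicin
    pk: {ka: 1.0, v_f: 53.0, cl_f: 7.0, fu: 0.15, kp_liver: 1.0, molecular_weight: 822.94}
    regimen: {compound: rifampicin, route: oral, dose: 600.0, interval: 24.0, start_day: 700.0, duration_days: 30.0}
    interaction: {mechanism: induction, ind_max: 16.0, ind_c50: 0.32, target_enzymes: [CYP3A4, CYP3A5, CYP3A7]}
reference:
  # Inputs of the reverse-translation chain (stored for reproducibility).
  parent_body_weight: 67.5      # kg, cholesterol-side derivations
  metabolite_body_weight: 63.5  # kg, 4beta-OHC-side derivations
  parent_thalf_h: 1105.2        # 46.05 days
  metabolite_thalf_h: 62.0
  parent_fm_cyp27a1: 0.27
  parent_fm_cyp3a: 2.1e-5       # initial, pre-optimization
  metabolite_fm_cyp27a1: 0.5
  cyp3a5_pct_of_cyp3a: 5.6      # % of CYP3A CLint
  cyp3a7_pct_of_cyp3a: 2.8
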