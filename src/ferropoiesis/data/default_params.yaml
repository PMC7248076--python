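sigmoids:
  hepcidin_production:
    v_min: 0.2
    v_max: 8.0
    v_nor: 2.0
    b: 4.0
  zferro:
    v_min: 0.05
    v_max: 1.05
    v_nor: 1.0
    b: -3.0
  ztrf:
    v_min: 0.5
    v_max: 1.2
    v_nor: 1.0
    b: -2.0
  epo_production:
    v_min: 0.05
    v_max: 10.0
    v_nor: 1.0
    b: -6.0
  amp_ce:
    v_min: 0.05
    v_max: 1.2
    v_nor: 1.0
    b: 0.6
  amp_peb:
    v_min: 0.05
    v_max: 1.5
    v_nor: 1.0
    b: 0.8
  maturation:
    v_min: 0.6
    v_max: 1.8
    v_nor: 1.0
    b: 0.8
weights:
  k_HEPFS: 0.3
  k_HEPFP: 1.0
  k_HEPHB: 0.5
  k_TRFFP: 1.0
  k_TRFHB: 1.0
  k_TRFFS: 1.0
  k_TRFHEP: 0.3
iron:
  k_S: 0.02
  k_ul: 9.0
  k_MM: 3.0
  k_PEB: 1.0
  d_TRFl: 0.5
  k_TRFu: 8.0
  alpha: 2.0
  d_Fe: 0.05
  d_entero: 3.0
  Delay_intest: 2.0
  FeDiet_nor: 15.0
  Fe_intest_max: 30.0
  Fe_tinf: 0.010416666666666666
  HEP_inflammation: 0.0
  hep_production_factor: 1.0
  diet_factor: 1.0
references:
  NTBI_0: 1.0
  TRFl_0: 1.0
  TRFu_0: 1.0
  F_S0: 1.0
  F_HB0: 1.0
  HEP_0: 1.0
  HB_nor: 14.0
cells:
  beta_S: 0.35
  tau_BE: 6.0
  tau_CE: 6.0
  tau_PEB: 4.0
  tau_MEB: 5.0
  tau_RET: 2.0
  n_ages: 15
  ery_transit_days: 110.0
  theta_rand: 0.001
  d_rand: 0.1
  chemo_s_S: 0.15
  chemo_s_BE: 1.0
  chemo_s_CE: 1.0
  chemo_s_PEB: 1.0
epo:
  k_el: 3.0
  k_cp: 1.0
  k_pc: 1.0
  B_max: 2.0
  k_int: 2.0
  k_a: 1.0
  bioavailability_sc: 0.7
  epo_amount_ss_iu: 50.0
  body_weight_kg: 70.0
bridges:
  blood_volume_l: 5.0
  hct_nor: 0.42
  rbc_nor_10e6_ul: 4.8
  ret_nor_10e3_ul: 60.0
  ferritin_ref_ug_l: 100.0
  serum_iron_ref_ug_dl: 100.0
  epo_ref_miu_ml: 10.0
  iv_iron_mg_per_unit: 10.0
derived:
  d_HEP: 2.0
  k_FeTRF: 0.4000000000000001
  k_lu: 0.75
  d_TRFu: 7.5
  k_HB: 0.95
  k_intest: 12.0
  epo_production_scale: 5.0
  Zferro_0: 1.0
  ZTRF_0: 1.0
  F_P0: 1.4000000000000001
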