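# Cyclosporine compound file.
#
# Physico-chemistry, plasma binding, the nine saturable tissue-binding sites,
# CYP3A4 metabolism and P-glycoprotein efflux with their published units.
# The `platform` block holds the three parameters the published compound set
# does not determine (they belong to the anatomy/absorption platform); they
# were calibrated once against the single-dose healthy-volunteer IV and oral
# profiles and are fixed thereafter.
name: cyclosporine
phys_chem:
  molecular_weight_g_mol: 1203.0
  charge_class: neutral
  log_p: 3.25
  solubility_ug_ml: 190.0
  intestinal_permeability_cm_min: 4.5e-05
plasma_binding:
  fraction_unbound: 0.06
binding_sites:
  - {tissue: lung,        k_m_umol_l: 0.05, k_off: 4.75,    k_off_unit: per_s, b_c_umol_l: 8.48}
  - {tissue: heart,       k_m_umol_l: 0.02, k_off: 2.18,    k_off_unit: per_s, b_c_umol_l: 3.72}
  - {tissue: bone,        k_m_umol_l: 0.28, k_off: 27.68,   k_off_unit: per_s, b_c_umol_l: 18.7}
  - {tissue: skin,        k_m_umol_l: 0.27, k_off: 27.18,   k_off_unit: per_s, b_c_umol_l: 25.9}
  - {tissue: kidney,      k_m_umol_l: 0.5,  k_off: 0.00389, k_off_unit: per_h, b_c_umol_l: 104.0}
  - {tissue: spleen,      k_m_umol_l: 0.56, k_off: 0.00225, k_off_unit: per_h, b_c_umol_l: 132.0}
  - {tissue: liver,       k_m_umol_l: 0.15, k_off: 0.00271, k_off_unit: per_h, b_c_umol_l: 38.7}
  - {tissue: intestine,   k_m_umol_l: 0.74, k_off: 0.00558, k_off_unit: per_h, b_c_umol_l: 78.1}
  - {tissue: blood_cells, k_m_umol_l: 0.15, k_off: 150.0,   k_off_unit: per_s, b_c_umol_l: 3.86}
metabolism:
  systemic:
    k_m_nmol_ml: 0.5
    v_max_nmol_min_g: 0.78
    b_c_liver_umol_l: 4.32
    relative_abundance:
      liver: 1.0
      colon: 0.71            # large intestine, non-mucosal tissue
      small_intestine: 0.4   # non-mucosal tissue
      stomach: 0.35
      kidney: 0.03
      muscle: 0.01
      brain: 0.01
  intestinal:
    cl_ii_l_h: 50.0
    b_c_by_segment_umol_l:
      duodenum: 1.08
      upper_jejunum: 1.05
      lower_jejunum: 0.99
      upper_ileum: 0.84
      lower_ileum: 1.44
efflux:
  k_m_umol_l: 0.09
  v_max_nmol_ml_min: 2.14
  b_c_colon_umol_l: 1.0
  brain_b_c_umol_l: 1.0
  # relative distribution aboral over the small intestine (sums to 1), with the
  # colon carrying the baseline capacity b_c_colon
  intestinal_relative_distribution:
    ileum: 0.55
    jejunum: 0.38
    duodenum: 0.07
    colon: 1.0
platform:
  # global scalar on the membrane-affinity term of the tissue-composition
  # partition model (calibrated against the IV arms)
  partition_scalar: 0.12
  # basolateral mucosa->portal permeation clearance, unbound basis
  # (calibrated against F_I of the 100 mg oral arm)
  basolateral_clearance_l_h: 34.7
  # effective absorptive surface enlargement of the small-intestinal mucosa
  # (folds + villi + microvilli; calibrated against F_A and t_max)
  surface_enlargement_small_intestine: 80.0
  surface_enlargement_colon: 2.0
  # transcapillary permeation clearance per litre of tissue for organs with
  # continuous (non-fenestrated) capillaries; limits early distribution of the
  # large cyclic peptide (calibrated against the IV C_MAX)
  tissue_permeability_l_min_per_l: 0.02
  brain_efflux_enabled: true
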