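# Global and species-specific PBPK-PD model parameters for GalNAc-siRNAs.
#
# Scalar entries are global (shared across mouse/monkey/human); mappings keyed
# by species are species-specific. The canonical set is the model's summary
# parameter table; an alternate species calibration that circulated alongside
# the canonical one (differing for ka, P_liver, k_recycle_liver) is provided
# under `alternate_species_set` and is selectable via
# assemble_parameterization(..., species_set="alternate").
#
# Units:
#   rate constants suffixed _min are min^-1, all others h^-1
#   k_on, k_onRISC are second-order in L/nmol/h
#   k_RNase is second-order, per (umol/L of RNase) per h
#   R_tot, RISC_tot, RNase_* are umol/L; SC_50 is nmol/L
canonical:
  ka: {mouse: 0.84, monkey: 4.57, human: 7.73}
  P_liver_cm_min: {mouse: 0.02, monkey: 3.05e-3, human: 1.21e-4}
  fu: 1.0
  k_uptake_liver_min: 0.29
  k_recycle_liver_min: {mouse: 1.33e-3, monkey: 8.22e-4, human: 4.27e-5}
  k_uptake_kidney_min: 24.98
  k_recycle_kidney_min: 3.90e-4
  k_uptake_gonads_min: 1.48
  k_uptake_lung_min: 0.06
  k_uptake_heart_min: 0.39
  k_uptake_spleen_min: 0.17
  # generic platform value for all remaining tissues
  k_uptake_default_min: 0.29
  k_RNase: 1.21e-4
  RNase_kidney: 1.17
  RNase_remaining: 2.75e-2
  R_tot: {mouse: 5.23, monkey: 2.46, human: 2.46}
  k_on: 0.53
  k_off: 1.53
  k_deg_R: 1.53
  k_deg: 1.52
  k_int: 5.14
  k_cle: 1.32
  k_rec: 13.8
  # mouse is the standard individual; monkey/human scaled allometrically
  # with exponent -0.25 on body weight
  k_endosome_std: 5.0e-3
  f_escape: 0.01
  k_deg_C: 0.1
  RISC_tot: 3.0e-4
  k_onRISC: {mouse: 2.73e-4, monkey: 2.73e-4, human: 1.68e-5}
  k_offRISC: 1.0e-7
  S_max: 58.84
  SC_50: 3.52
  k_deg_mRNA: 0.06
  k_deg_protein: 0.05
  gamma: 1.5
  # compound characteristics never tabulated; documented assumptions
  MW: 16000.0
  hydrodynamic_radius_nm: 3.0
alternate_species_set:
  ka: {monkey: 4.22, human: 7.18}
  P_liver_cm_min: {monkey: 1.56e-3, human: 1.21e-5}
  # the alternate calibration reports these in h^-1
  k_recycle_liver_min: {monkey: 3.833e-7, human: 7.117e-7}
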