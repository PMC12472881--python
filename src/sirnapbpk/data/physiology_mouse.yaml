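# Reference physiology: mouse (CD-1-like reference individual).
# Compiled from standard open physiology compendia (organ weights as fractions
# of body weight, regional plasma-flow fractions of cardiac plasma output,
# vascular/interstitial volume fractions of organ volume). Tissue density
# 1 kg/L is assumed throughout. Values are documented package defaults and
# fully overridable; see docs/methods.md.
#
# q_frac: fraction of systemic cardiac plasma output perfusing the organ
#         (lung is in series with the total flow and carries q_frac = 1).
# l_frac: organ lymph flow as a fraction of organ plasma flow.
# scap_cm2_per_g: capillary exchange surface area per gram of tissue.
# f_endo: endosomal volume as a fraction of the vascular volume; defaults to
#         the top-level f_endosomal, enlarged for the liver (fenestrated
#         sinusoidal endothelium) and kidney (proximal-tubule reabsorptive
#         endosomal apparatus, the known renal accumulation site for
#         oligonucleotides).
species: mouse
body_weight_kg: 0.025
hematocrit: 0.45
cardiac_plasma_output_L_h_per_kg: 18.4
gfr_L_h_per_kg: 0.60
plasma_volume_frac: 0.049
venous_fraction: 0.667
f_endosomal: 0.01
organs:
  liver:    {v_frac: 0.0550, f_vascular: 0.11, f_interstitial: 0.16, q_frac: 0.161, l_frac: 0.020, scap_cm2_per_g: 250, f_endo: 0.05}
  kidney:   {v_frac: 0.0167, f_vascular: 0.07, f_interstitial: 0.20, q_frac: 0.091, l_frac: 0.002, scap_cm2_per_g: 350, f_endo: 0.15}
  lung:     {v_frac: 0.0073, f_vascular: 0.15, f_interstitial: 0.18, q_frac: 1.0,   l_frac: 0.002, scap_cm2_per_g: 300}
  heart:    {v_frac: 0.0050, f_vascular: 0.06, f_interstitial: 0.10, q_frac: 0.066, l_frac: 0.002, scap_cm2_per_g: 100}
  spleen:   {v_frac: 0.0035, f_vascular: 0.22, f_interstitial: 0.15, q_frac: 0.011, l_frac: 0.002, scap_cm2_per_g: 250}
  gonads:   {v_frac: 0.0042, f_vascular: 0.04, f_interstitial: 0.16, q_frac: 0.006, l_frac: 0.002, scap_cm2_per_g: 70}
  brain:    {v_frac: 0.0165, f_vascular: 0.03, f_interstitial: 0.15, q_frac: 0.033, l_frac: 0.001, scap_cm2_per_g: 20}
  muscle:   {v_frac: 0.3840, f_vascular: 0.01, f_interstitial: 0.13, q_frac: 0.159, l_frac: 0.002, scap_cm2_per_g: 70}
  skin:     {v_frac: 0.1650, f_vascular: 0.02, f_interstitial: 0.30, q_frac: 0.058, l_frac: 0.002, scap_cm2_per_g: 70}
  adipose:  {v_frac: 0.0700, f_vascular: 0.01, f_interstitial: 0.14, q_frac: 0.070, l_frac: 0.002, scap_cm2_per_g: 70}
  bone:     {v_frac: 0.1070, f_vascular: 0.04, f_interstitial: 0.10, q_frac: 0.110, l_frac: 0.002, scap_cm2_per_g: 70}
  gut:      {v_frac: 0.0420, f_vascular: 0.02, f_interstitial: 0.09, q_frac: 0.141, l_frac: 0.005, scap_cm2_per_g: 70}
  pancreas: {v_frac: 0.0060, f_vascular: 0.06, f_interstitial: 0.12, q_frac: 0.010, l_frac: 0.002, scap_cm2_per_g: 70}
  stomach:  {v_frac: 0.0060, f_vascular: 0.03, f_interstitial: 0.10, q_frac: 0.010, l_frac: 0.002, scap_cm2_per_g: 70}
  carcass:  {v_frac: 0.0600, f_vascular: 0.04, f_interstitial: 0.15, q_frac: 0.074, l_frac: 0.002, scap_cm2_per_g: 70}
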