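# Reference physiology: cynomolgus monkey. See physiology_mouse.yaml for the
# column conventions and docs/methods.md for provenance of these defaults.
species: monkey
body_weight_kg: 3.0
hematocrit: 0.40
cardiac_plasma_output_L_h_per_kg: 4.67
gfr_L_h_per_kg: 0.12
plasma_volume_frac: 0.045
venous_fraction: 0.667
f_endosomal: 0.01
organs:
  liver:    {v_frac: 0.0270, f_vascular: 0.11, f_interstitial: 0.16, q_frac: 0.185, l_frac: 0.020, scap_cm2_per_g: 250, f_endo: 0.05}
  kidney:   {v_frac: 0.0055, f_vascular: 0.07, f_interstitial: 0.20, q_frac: 0.140, l_frac: 0.002, scap_cm2_per_g: 350, f_endo: 0.15}
  lung:     {v_frac: 0.0080, f_vascular: 0.15, f_interstitial: 0.18, q_frac: 1.0,   l_frac: 0.002, scap_cm2_per_g: 300}
  heart:    {v_frac: 0.0040, f_vascular: 0.06, f_interstitial: 0.10, q_frac: 0.050, l_frac: 0.002, scap_cm2_per_g: 100}
  spleen:   {v_frac: 0.0020, f_vascular: 0.22, f_interstitial: 0.15, q_frac: 0.012, l_frac: 0.002, scap_cm2_per_g: 250}
  gonads:   {v_frac: 0.0010, f_vascular: 0.04, f_interstitial: 0.16, q_frac: 0.002, l_frac: 0.002, scap_cm2_per_g: 70}
  brain:    {v_frac: 0.0220, f_vascular: 0.03, f_interstitial: 0.15, q_frac: 0.060, l_frac: 0.001, scap_cm2_per_g: 20}
  muscle:   {v_frac: 0.4300, f_vascular: 0.01, f_interstitial: 0.13, q_frac: 0.160, l_frac: 0.002, scap_cm2_per_g: 70}
  skin:     {v_frac: 0.1000, f_vascular: 0.02, f_interstitial: 0.30, q_frac: 0.060, l_frac: 0.002, scap_cm2_per_g: 70}
  adipose:  {v_frac: 0.0500, f_vascular: 0.01, f_interstitial: 0.14, q_frac: 0.040, l_frac: 0.002, scap_cm2_per_g: 70}
  bone:     {v_frac: 0.1200, f_vascular: 0.04, f_interstitial: 0.10, q_frac: 0.060, l_frac: 0.002, scap_cm2_per_g: 70}
  gut:      {v_frac: 0.0350, f_vascular: 0.02, f_interstitial: 0.09, q_frac: 0.150, l_frac: 0.005, scap_cm2_per_g: 70}
  pancreas: {v_frac: 0.0020, f_vascular: 0.06, f_interstitial: 0.12, q_frac: 0.010, l_frac: 0.002, scap_cm2_per_g: 70}
  stomach:  {v_frac: 0.0050, f_vascular: 0.03, f_interstitial: 0.10, q_frac: 0.012, l_frac: 0.002, scap_cm2_per_g: 70}
  carcass:  {v_frac: 0.0900, f_vascular: 0.04, f_interstitial: 0.15, q_frac: 0.059, l_frac: 0.002, scap_cm2_per_g: 70}
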