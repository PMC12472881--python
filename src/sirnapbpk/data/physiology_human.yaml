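# Reference physiology: adult human (73 kg reference individual). See
# physiology_mouse.yaml for the column conventions and docs/methods.md for
# provenance of these defaults.
species: human
body_weight_kg: 73.0
hematocrit: 0.44
cardiac_plasma_output_L_h_per_kg: 2.48
gfr_L_h_per_kg: 0.0986
plasma_volume_frac: 0.0436
venous_fraction: 0.667
f_endosomal: 0.01
organs:
  liver:    {v_frac: 0.0260, f_vascular: 0.11, f_interstitial: 0.16, q_frac: 0.2000, l_frac: 0.020, scap_cm2_per_g: 250, f_endo: 0.05}
  kidney:   {v_frac: 0.0044, f_vascular: 0.07, f_interstitial: 0.20, q_frac: 0.1750, l_frac: 0.002, scap_cm2_per_g: 350, f_endo: 0.15}
  lung:     {v_frac: 0.0076, f_vascular: 0.15, f_interstitial: 0.18, q_frac: 1.0,    l_frac: 0.002, scap_cm2_per_g: 300}
  heart:    {v_frac: 0.0047, f_vascular: 0.06, f_interstitial: 0.10, q_frac: 0.0400, l_frac: 0.002, scap_cm2_per_g: 100}
  spleen:   {v_frac: 0.0026, f_vascular: 0.22, f_interstitial: 0.15, q_frac: 0.0150, l_frac: 0.002, scap_cm2_per_g: 250}
  gonads:   {v_frac: 0.0005, f_vascular: 0.04, f_interstitial: 0.16, q_frac: 0.0005, l_frac: 0.002, scap_cm2_per_g: 70}
  brain:    {v_frac: 0.0200, f_vascular: 0.03, f_interstitial: 0.15, q_frac: 0.1140, l_frac: 0.001, scap_cm2_per_g: 20}
  muscle:   {v_frac: 0.4000, f_vascular: 0.01, f_interstitial: 0.13, q_frac: 0.1700, l_frac: 0.002, scap_cm2_per_g: 70}
  skin:     {v_frac: 0.0371, f_vascular: 0.02, f_interstitial: 0.30, q_frac: 0.0580, l_frac: 0.002, scap_cm2_per_g: 70}
  adipose:  {v_frac: 0.2142, f_vascular: 0.01, f_interstitial: 0.14, q_frac: 0.0500, l_frac: 0.002, scap_cm2_per_g: 70}
  bone:     {v_frac: 0.1429, f_vascular: 0.04, f_interstitial: 0.10, q_frac: 0.0420, l_frac: 0.002, scap_cm2_per_g: 70}
  gut:      {v_frac: 0.0171, f_vascular: 0.02, f_interstitial: 0.09, q_frac: 0.0900, l_frac: 0.005, scap_cm2_per_g: 70}
  pancreas: {v_frac: 0.0014, f_vascular: 0.06, f_interstitial: 0.12, q_frac: 0.0100, l_frac: 0.002, scap_cm2_per_g: 70}
  stomach:  {v_frac: 0.0021, f_vascular: 0.03, f_interstitial: 0.10, q_frac: 0.0100, l_frac: 0.002, scap_cm2_per_g: 70}
  carcass:  {v_frac: 0.0700, f_vascular: 0.04, f_interstitial: 0.15, q_frac: 0.0255, l_frac: 0.002, scap_cm2_per_g: 70}
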