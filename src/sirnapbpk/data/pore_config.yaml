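# Two-pore capillary-wall transport constants (package defaults).
# Standard two-pore literature values for large-molecule distribution:
# small/large pore radii, the fraction of hydraulic conductance carried by
# large pores, the isogravimetric recirculation flux as a multiple of organ
# lymph flow, and the anatomical constants converting capillary surface area
# into a pore-area-to-diffusion-path ratio. All overridable.
r_small_nm: 4.5
r_large_nm: 25.0
alpha_large: 0.05
circ_factor: 1.0
frac_area_small: 5.0e-4
wall_thickness_cm: 5.0e-5
temperature_K: 310.0
viscosity_Pa_s: 7.0e-4
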