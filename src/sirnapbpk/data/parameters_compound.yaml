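# Compound-specific model parameters for the three reference GalNAc-siRNAs.
# F (subcutaneous bioavailability, fraction) and k_recycle_tissue_min
# (endosomal recycling in off-target tissues, min^-1) are shared across
# species; k_DR (RISC-complex degradation, h^-1) is species-specific.
# null means no estimate exists for that compound x species (no PD data);
# PD simulation is unavailable for those combinations.
siRNA-1:
  F: 0.47
  k_recycle_tissue_min: 3.23e-5
  k_DR: {mouse: 9.72e-3, monkey: 8.02e-3, human: null}
siRNA-2:
  F: 0.22
  k_recycle_tissue_min: 3.49e-4
  k_DR: {mouse: null, monkey: 5.28e-3, human: 4.17e-4}
siRNA-3:
  F: 0.22
  k_recycle_tissue_min: 3.23e-5
  k_DR: {mouse: null, monkey: 1.94e-3, human: 2.02e-4}
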