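# sirnapbpk

Whole-body physiologically based pharmacokinetic–pharmacodynamic
(WB-PBPK-PD) modeling of GalNAc-conjugated siRNAs.

N-acetylgalactosamine-conjugated small interfering RNAs (GalNAc-siRNAs) are
cleared from plasma within minutes, accumulate almost entirely in the liver
through the asialoglycoprotein receptor (ASGPR) on hepatocytes, yet also
distribute measurably into kidney and other off-target organs and
re-circulate slowly back into plasma.  Their pharmacology — silencing of a
hepatic target mRNA and knockdown of the downstream plasma protein —
persists for weeks to months.  This package provides a mechanistic
simulator for that entire chain, for mouse, cynomolgus monkey and human,
aimed at modelers doing preclinical-to-clinical translation of
GalNAc-siRNA candidates.

## Model

The body is represented as 15 tissue compartments (each split into
vascular, interstitial, endothelial-endosomal and intracellular spaces)
connected by organ plasma and lymph flows, plus venous/arterial plasma
pools and a first-order subcutaneous depot (dose × F absorbed at rate
k_a).  The core processes:

- **Two-pore extravasation** — transcapillary solute flux per pore class
  (small/large) follows the Patlak equation
  J = J_v(1−σ)·(C_v − C_i e^(−Pe))/(1 − e^(−Pe)), Pe = J_v(1−σ)/PS, with
  sieving σ and permeability–surface product PS computed from the solute's
  hydrodynamic radius via pore-hindrance factors.
- **Non-specific endosomal trafficking** — first-order uptake
  (k_uptake.tissue) and recycling (k_recycle.tissue) between the
  endothelial contact pool and the endosomal space, with tabulated
  tissue-specific rates (kidney ≫ gonads > heart > spleen > lung).
- **Eliminations** — glomerular filtration of unbound drug
  (GFR · f_u · C), and RNase-mediated degradation
  (k_RNase · [RNase] · C) in plasma and non-liver endosomes; RNase is
  disabled in the liver, where a separate first-order endosomal
  degradation rate k_endosome (allometrically scaled across species with
  exponent −0.25) governs the long hepatic half-life.
- **ASGPR-mediated liver uptake (TMDD)** — interstitial drug binds free
  receptor (k_on, k_off), the surface complex internalizes (k_int) and is
  cleaved (k_cle), returning receptor to the surface (k_rec) while the
  drug enters the hepatocyte endosome; receptor turnover obeys
  k_syn = R_tot · k_deg.
- **RISC kinetics and PD** — a fraction f_escape of processed endosomal
  drug reaches the cytoplasm, loads RISC (k_onRISC, k_offRISC, complex
  loss k_DR), and the loaded complex C_RISC drives an indirect-response
  model:

      dmRNA/dt    = k_deg.mRNA · (mRNA₀ − (1 + S_max·C_RISC/(SC₅₀ + C_RISC)) · mRNA)
      dProtein/dt = k_deg.protein · (Protein₀ · (mRNA/mRNA₀)^γ − Protein)

All tabulated global, species-specific and compound-specific parameters
(three reference compounds, siRNA-1/2/3) ship as plain-text YAML with
per-value provenance tags, alongside a documented open-literature
physiology table per species.  The package also implements trapezoidal
NCA, AFE/AAFE model-performance metrics (bands 0.5 ≤ AFE ≤ 2, AAFE ≤ 2),
local sensitivity analysis S_ij = (ΔAUC/AUC)/(Δp/p) with WHO
classification, a log-residual least-squares objective, a seeded
Monte-Carlo multistart fitter (relative-improvement break condition
0.001), and a synthetic-study generator mirroring the preclinical designs
(destructive sampling, n = 3/time point, lognormal concentration noise).

## Worked example

```python
import numpy as np
from sirnapbpk import DoseRegimen, assemble_parameterization, simulate

param = assemble_parameterization("siRNA-1", "mouse")
res = simulate(param, DoseRegimen(dose=3.0, compound_id="siRNA-1"),
               t_end=1008.0)

t = res.time
for name in ("plasma", "liver", "kidney", "mrna"):
    c = res.curves[name]
    i = np.argmax(c) if name != "mrna" else np.argmin(c)
    print(f"{name:>6}: extreme {c[i]:10.4g} {res.units[name]} "
          f"at t = {t[i]:.2f} h")
print(f"mass-balance residual: {res.audit.max_residual:.2e}")
```

prints

```
plasma: extreme     0.3544 ug/mL at t = 0.09 h
 liver: extreme      20.16 ug/g at t = 6.32 h
kidney: extreme      4.908 ug/g at t = 9.08 h
  mrna: extreme      94.24 % at t = 177.10 h
mass-balance residual: 1.93e-14
```

A 3 mg/kg subcutaneous dose peaks in plasma within minutes and is cleared
in hours (rapid distribution), while the liver accumulates ~20 µg/g —
four-fold more than kidney — and then declines with a ~150 h half-life set
by k_endosome.  Target mRNA reaches its nadir (~94% of baseline at this
low dose; ~45% at 100 mg/kg) only after a week, reflecting the slow
endosome → cytoplasm → RISC cascade.  The audit confirms drug mass is
conserved to machine precision.

A thin CLI mirrors the library:
`sirnapbpk simulate|synth|fit|sensitivity|evaluate --help`.

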