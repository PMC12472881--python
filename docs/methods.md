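# Methods

This note documents the model implemented in `sirnapbpk`, the assumptions
behind it, the defaults and why they were chosen, and the limits of what
the synthetic-data studies can demonstrate.

## Model structure

**Circulation.** Fifteen tissues (liver, kidney, lung, heart, spleen,
gonads, brain, muscle, skin, adipose, bone, gut, pancreas, stomach,
remaining/carcass) are perfused in parallel from an arterial plasma pool;
the lung sits in series carrying the total cardiac plasma output.  Each
organ's lymph flow drains its interstitium directly to venous plasma, so
the fluid-flow graph is closed (net flow into every node is zero in the
drug-free state).  The portal circulation is not resolved: the liver
receives its combined (arterial + portal) plasma flow directly from the
arterial pool.  All states are amounts in µmol; observables are derived
concentrations.

**Subcompartments.** Every organ carries vascular, interstitial,
endothelial-endosomal and intracellular spaces.  Intracellular uptake is
zero in all organs; the intracellular space exists only in the liver,
implicitly, as the hepatocyte reference volume for the receptor/RISC
states.  Subcompartment volumes derive from documented per-organ vascular
and interstitial fractions; the endosomal space is a fraction `f_endo` of
the vascular volume — 0.01 by default, 0.05 for liver (fenestrated
sinusoidal endothelium) and 0.15 for kidney, standing in for the
proximal-tubule reabsorptive endosomal apparatus that is the known renal
accumulation site of oligonucleotides.

**Two-pore extravasation.** Per pore class the solute flux is the Patlak
expression J_v(1−σ)(C_v − C_i·e^(−Pe))/(1−e^(−Pe)) with
Pe = J_v(1−σ)/PS.  σ comes from the convective hindrance
W = Φ(2−Φ)(1−λ²/3), Φ = (1−λ)², λ = a/r_pore; PS from the Renkin
diffusive hindrance, Stokes–Einstein free diffusivity at 310 K, and a
pore-area/path term proportional to the organ's capillary surface area.
Fluid fluxes: the large pores carry α_L of the hydraulic conductance plus
an isogravimetric recirculation flux J_circ (a configurable multiple of
the organ lymph flow, default 1); small pores carry the remainder minus
J_circ; the net fluid flux equals the lymph flow.  Because the fluid
fluxes are state-independent, each organ's two-pore flux reduces to
a·C_v − b·C_i with precomputed coefficients.  Pore constants (r_s = 4.5 nm,
r_L = 25 nm, α_L = 0.05, fractional small-pore area 5×10⁻⁴ over a 0.5 µm
path) are standard two-pore literature values, bundled in
`data/pore_config.yaml` and fully overridable; they are stand-ins for the
unpublished values of the source platform.

**Endosomal trafficking.** The tabulated first-order constants
k_uptake.tissue / k_recycle.tissue (min⁻¹) act, by default, on the
*endothelial contact pool* V_endo·(C_vascular + C_interstitial), i.e. the
uptake clearance scales with the organ's endosomal volume, as in
platform-style large-molecule models.  This keeps glomerular filtration
the dominant plasma clearance and makes the captured kidney amount linear
in k_kid.uptake.  Two alternative conventions are available through
`ModelConfig(endosomal_uptake=...)`: first-order in the full
vascular+interstitial amounts, or in the interstitial amount only.
Recycling returns the endosomal amount entirely to the interstitial side
by default (`recycle_to_interstitial` allows a split).

**Eliminations.** Filtration: GFR·f_u·C from the kidney vascular space
into a urine sink.  RNase: second-order k_RNase·[RNase]·C — the tabulated
k_RNase (printed as a first-order constant) is combined with the tabulated
RNase abundances so that both quantities enter the model; it acts in the
central plasma pools (abundance = the "remaining tissue" value) and in
every non-liver endosome (kidney abundance 1.17 µmol/L, elsewhere
2.75×10⁻² µmol/L), and is identically zero in all liver compartments.
The liver endosome instead degrades drug at k_endosome.

**ASGPR/TMDD.** Free surface receptor (initialized at R_tot, maintained by
k_syn = R_tot·k_deg) binds liver interstitial drug at k_on (second order,
concentrations in the hepatocyte volume); the surface complex dissociates
(k_off) or internalizes (k_int); the internal complex is cleaved (k_cle),
sending drug to the hepatocyte endosome and receptor to an internalized
pool that recycles to the surface (k_rec) or degrades (k_deg.R).  This
topology — drug release only at cleavage, receptor recycling after — is
one reconstruction of the published description; it is the simplest chain
consistent with the named constants.  The liver additionally has a
bidirectional passive permeability P_liver·S_cap between vascular and
interstitial spaces, added to its two-pore flux.

**Escape and RISC.** Endosomal drug is processed first order at
k_endosome; a fraction f_escape (1%) of that processed flux enters the
cytoplasm as antisense strand (1:1 molar with parent drug), the rest is
degraded.  (`escape_at_cleavage` instead applies the fraction to the
cleavage outflow.)  Cytoplasmic antisense degrades at k_deg.C or loads
free RISC (k_onRISC, second order); the loaded complex dissociates
(k_offRISC) or is lost at k_DR.  k_DR destroys only the siRNA cargo and
returns free RISC, keeping the total RISC pool constant — chosen because
RISC_tot is a fixed literature constant.  k_onRISC is treated as second
order (L/nmol/h) throughout.

**PD.** Loaded-RISC concentration (nmol/L, hepatocyte volume) stimulates
mRNA degradation in an indirect-response model with S_max, SC₅₀; protein
turns over against (mRNA)^γ.  Baselines are 1 internally and reported
as % of baseline.

## Parameters

Global constants, species columns (k_a, P_liver, k_recycle.liver, R_tot,
k_onRISC) and compound values (F, k_recycle.tissue, k_DR for siRNA-1/2/3)
are bundled in `data/parameters_global.yaml` / `data/parameters_compound.yaml`
with per-value provenance tags.  Species translation: k_endosome scales
from the mouse standard individual (0.025 kg) by (BW_i/BW_std)^(−0.25);
receptor density uses the tabulated per-species values (5.23 µmol/L mouse,
2.46 monkey/human).  F and k_recycle.tissue are shared across species, the
reading implied by the compound table's layout.  Where the summary tables
and the narrative text disagree (monkey/human k_a, P_liver,
k_recycle.liver), the tables are canonical and the text values ship as a
selectable `alternate` species set.  k_DR has no estimate for siRNA-2/3 in
mouse or siRNA-1 in human; those combinations assemble for PK only
(`include_pd=False`), and requesting PD raises an explicit error.
Molecular weight (16 kDa) and hydrodynamic radius (3 nm) are never
tabulated; they are documented assumptions, exposed as ordinary
parameters because the sensitivity analysis shows the radius matters.

Physiology tables are compiled from standard open compendia (organ-weight
fractions, regional flow fractions, GFR, cardiac plasma output per kg;
tissue density 1 kg/L) with default body weights 0.025 / 3.0 / 73 kg.
Rescaling to another body weight is strictly proportional, leaving flow
ratios and volume fractions unchanged.

## Numerics

Stiff integration via LSODA by default; the fitting path uses BDF, which
is 2–3× faster on this system at matching accuracy.  Default tolerances
rtol 1e-8 / atol 1e-12 µmol; fitting and the test suite use 1e-6/1e-10,
which moves the plasma AUC by <0.1%.  Dose events restart the integrator with the
depot incremented by F·dose (mg/kg converted through MW and body weight).
Mass balance is audited at every output time — drug in system plus
cumulative sinks must equal the bioavailable dose administered — and a
relative defect above 0.1%, or negative-state excursions beyond 0.1% of
the dose, abort the simulation loudly.  Observable extraction clips
solver-level negative round-off at zero.  Huge Péclet numbers fall back
to the convective limit; |Pe| < 1e-8 uses the series expansion.

## Fitting, metrics, sensitivity

The objective is the sum of squared residuals in log₁₀ concentration
space (data span >3 orders of magnitude) and in linear %-of-baseline
space for PD, equally weighted per observation; simulation failures
return a large finite penalty.  The fitter draws multistart points
log-uniform (or uniform) within bounds from a seeded generator and
refines the best start with Nelder–Mead in blocks, stopping when the
relative loss improvement over a block falls below 0.001 — the only
stated contract of the original optimizer.  Same seed, same trajectory.

AFE/AAFE are geometric means of (|log|) AUC_sim/AUC_obs ratios computed
per curve and pooled, with adequacy bands 0.5–2 and ≤2.  Sensitivity
coefficients use a forward +10% perturbation of one parameter and the
AUC₀₋₈₀₀₀ₕ of the chosen observable at 1 mg/kg (parameters already at a
physical upper bound, e.g. f_u = 1, are perturbed −10% instead); classes
follow the WHO bands (high ≥0.5, medium ≥0.2, low ≥0.1).

## Synthetic studies

The generator emulates the preclinical designs: subcutaneous dosing
(0.1–300 mg/kg), destructive terminal sampling with n = 3 independent
replicates per time point, plasma/tissue concentrations and
baseline-normalized PD.  Residual noise is multiplicative lognormal for
concentrations (default CV 20%, unbiased in log space) and additive
Gaussian in percentage points for PD (default SD 5, truncated to
[0, 120]% to mimic assay normalization); the magnitudes are documented
assumptions, as the source studies never state them.  Sampling grids
(dense ≤24 h, sparse to 1008 h) were chosen to resolve the three plasma
phases; the real studies only state "warranted time points".  The
generating truth (parameters and noiseless curves) is returned for
recovery studies.

Recovery experiments in the tests and the acceptance script refit one
parameter at a time with the others held at truth, over 20 replicate
studies, using targeted single- or two-dose datasets (e.g. liver only for
k_endosome, liver mRNA at 100 mg/kg for the PD parameters) and a reduced
multistart (2 starts, ≤40 simplex iterations); these problem sizes keep
each experiment at a few seconds while leaving the estimators'
median error well inside the acceptance margins.

## What the synthetic studies do and do not show

Passing recovery tests show that the estimation machinery is unbiased and
precise *under the model that generated the data*, with the stated noise
and design.  They do not probe structural misspecification (real tissue
data include binding, heterogeneity and assay artifacts absent here),
inter-animal variability (the generator uses one parameter set), or
identifiability when several correlated parameters float together.

## Known limitations

- The exact compartment wiring of the source platform (portal vein,
  endosomal subcompartment sizes, pore constants) is not published; the
  reconstruction here is documented and overridable but is an
  interpretation.
- Plasma AUC₀₋₈₀₀₀ₕ is nearly insensitive to the hydrodynamic radius in
  this implementation: extravasation is reversible distribution, and the
  filtration contract GFR·f_u·C carries no size-dependent glomerular
  sieving, so the window AUC is set by the irreversible clearances.
  Platforms that sieve filtration by solute size will show the radius in
  plasma exposure as well.
- The liver endothelial-endosomal pool drains with t½ ≈ 8.7 h
  (k_recycle.liver) and captures far less recirculating drug than the
  kidney pool (k_kid.uptake is 86× larger), so removing the liver
  unspecific uptake shifts the late plasma phase only modestly here; the
  weeks-long terminal phase is fed mainly by the kidney and off-target
  endosomal pools.
- Kidney handling is a surrogate: true renal oligonucleotide accumulation
  runs through filtration followed by proximal-tubule reabsorption, which
  this structure folds into the enlarged kidney endosomal compartment.
- No inter-occasion or population variability, no IV dosing, no LLOQ
  censoring, no Ago2/ASGPR-subunit species differences.
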