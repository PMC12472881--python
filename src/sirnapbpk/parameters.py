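"""Compound and species model parameters, translation rules, and assembly.

Houses every kinetic constant of the GalNAc-siRNA disposition model: the
subcutaneous depot (F, ka), two-pore solute properties (MW, hydrodynamic
radius), non-specific endosomal trafficking rates per tissue, ribonuclease
degradation, the hepatic ASGPR TMDD constants, RISC kinetics, and the
indirect-response PD parameters.  ``assemble_parameterization`` merges the
bundled global/species table with the compound table, applies the
interspecies translation rules (allometric scaling of the liver endosomal
degradation rate; species-specific receptor density), and tags every value
with its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .physiology import SpeciesPhysiology, load_species_physiology

#: mouse is the standard individual for allometric scaling
ALLOMETRIC_EXPONENT = -0.25

_SPECIES_KEYS = ("ka", "P_liver_cm_min", "k_recycle_liver_min", "R_tot",
                 "k_onRISC")


class MissingParameterError(KeyError):
    """A parameter required by the ODE right-hand side has no value."""


def allometric_scale_kendosome(k_std: float, BW_std: float, BW_i: float) -> float:
    """Scale a rate constant from the standard individual by body weight.

    Uses the power law ``k_i = k_std * (BW_i / BW_std) ** -0.25``.
    """
    if k_std <= 0 or BW_std <= 0 or BW_i <= 0:
        raise ValueError("k_std, BW_std and BW_i must all be positive")
    return k_std * (BW_i / BW_std) ** ALLOMETRIC_EXPONENT


def receptor_synthesis_rate(R_tot: float, k_deg: float) -> float:
    """Zero-order ASGPR synthesis rate holding the free receptor at R_tot.

    ``k_syn = R_tot * k_deg`` (umol/L/h) makes ``R = R_tot`` the drug-free
    steady state of the receptor turnover equation.
    """
    if R_tot < 0 or k_deg < 0:
        raise ValueError("R_tot and k_deg must be non-negative")
    return R_tot * k_deg


@dataclass(frozen=True)
class CompoundParameterSet:
    """All compound x species kinetic constants consumed by the model.

    Units: rates in 1/h unless the name ends in ``_min`` (1/min); ``k_on``
    and ``k_onRISC`` in L/nmol/h; ``k_RNase`` per (umol/L RNase) per h;
    densities/abundances in umol/L; ``SC_50`` in nmol/L; ``MW`` g/mol;
    ``hydrodynamic_radius_nm`` nm.  ``k_uptake_min`` / ``k_recycle_min`` map
    tissue name to the non-specific endosomal uptake/recycling constants.
    """

    compound_id: str
    species: str
    MW: float
    hydrodynamic_radius_nm: float
    fu: float
    F: float
    ka: float
    P_liver_cm_min: float
    k_uptake_min: dict[str, float]
    k_recycle_min: dict[str, float]
    k_RNase: float
    RNase_kidney: float
    RNase_remaining: float
    R_tot: float
    k_on: float
    k_off: float
    k_int: float
    k_cle: float
    k_rec: float
    k_deg: float
    k_deg_R: float
    k_syn: float
    k_endosome: float
    f_escape: float
    k_deg_C: float
    RISC_tot: float
    k_onRISC: float
    k_offRISC: float
    k_DR: float | None
    S_max: float
    SC_50: float
    k_deg_mRNA: float
    k_deg_protein: float
    gamma: float

    def __post_init__(self) -> None:
        for name, lo, hi in (("F", 0.0, 1.0), ("fu", 0.0, 1.0),
                             ("f_escape", 0.0, 1.0)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        for name in ("ka", "k_RNase", "k_on", "k_off", "k_int", "k_cle",
                     "k_rec", "k_deg", "k_deg_R", "k_endosome", "k_deg_C",
                     "k_onRISC", "k_offRISC", "k_deg_mRNA", "k_deg_protein"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class Parameterization:
    """A complete, provenance-tagged model input: compound + physiology."""

    compound: CompoundParameterSet
    species: SpeciesPhysiology
    provenance: dict[str, str] = field(default_factory=dict)

    def with_updates(self, **updates: Any) -> "Parameterization":
        """Return a copy with named compound parameters replaced.

        Nested tissue rates are addressed as e.g. ``k_uptake_min__kidney``;
        the physiological ``GFR`` may be updated as well.  Updated values are
        tagged ``optimized`` in the provenance map.
        """
        plain: dict[str, Any] = {}
        uptake = dict(self.compound.k_uptake_min)
        recycle = dict(self.compound.k_recycle_min)
        prov = dict(self.provenance)
        phys = self.species
        for key, value in updates.items():
            if key.startswith("k_uptake_min__"):
                uptake[key.split("__", 1)[1]] = value
            elif key.startswith("k_recycle_min__"):
                recycle[key.split("__", 1)[1]] = value
            elif key == "GFR":
                phys = replace(phys, GFR=value)
            else:
                plain[key] = value
            prov[key] = "optimized"
        compound = replace(self.compound, k_uptake_min=uptake,
                           k_recycle_min=recycle, **plain)
        if "R_tot" in plain or "k_deg" in plain:
            compound = replace(compound, k_syn=receptor_synthesis_rate(
                compound.R_tot, compound.k_deg))
            prov["k_syn"] = "derived"
        return Parameterization(compound=compound, species=phys,
                                provenance=prov)

    def get(self, key: str) -> float:
        """Read a (possibly nested) compound parameter by update-key syntax."""
        if key.startswith("k_uptake_min__"):
            return self.compound.k_uptake_min[key.split("__", 1)[1]]
        if key.startswith("k_recycle_min__"):
            return self.compound.k_recycle_min[key.split("__", 1)[1]]
        if key == "GFR":
            return self.species.GFR
        return getattr(self.compound, key)


def _load_yaml(name: str, source: str | Path | None = None) -> dict:
    path = Path(source) if source else Path(
        str(resources.files("sirnapbpk").joinpath("data", name)))
    return yaml.safe_load(path.read_text())


def _species_value(table: dict, key: str, species: str) -> Any:
    v = table[key]
    if isinstance(v, dict):
        if species not in v:
            raise MissingParameterError(
                f"parameter {key!r} has no value for species {species!r}")
        return v[species]
    return v


def assemble_parameterization(
    compound_id: str,
    species: str | SpeciesPhysiology,
    body_weight: float | None = None,
    species_set: str = "canonical",
    overrides: dict[str, Any] | None = None,
) -> Parameterization:
    """Build the full provenance-tagged parameterization for compound x species.

    Merges the global parameter table, the species-specific columns, and the
    compound table; scales the liver endosomal degradation rate allometrically
    from the mouse standard individual; and derives the receptor synthesis
    rate from the receptor steady-state identity.  ``species_set="alternate"``
    swaps in the alternate species calibration for ka, P_liver and
    k_recycle_liver.  ``overrides`` are applied last (tagged ``override``).
    """
    phys = (species if isinstance(species, SpeciesPhysiology)
            else load_species_physiology(species, body_weight))
    sp = phys.species

    raw = _load_yaml("parameters_global.yaml")
    table = dict(raw["canonical"])
    if species_set == "alternate":
        for key, per_species in raw["alternate_species_set"].items():
            merged = dict(table[key]) if isinstance(table[key], dict) else {}
            merged.update(per_species)
            table[key] = merged
    elif species_set != "canonical":
        raise ValueError(f"unknown species_set {species_set!r}")

    compounds = _load_yaml("parameters_compound.yaml")
    if compound_id not in compounds:
        raise MissingParameterError(
            f"unknown compound {compound_id!r}; bundled compounds: "
            f"{sorted(compounds)}")
    comp = compounds[compound_id]

    prov: dict[str, str] = {}
    values: dict[str, Any] = {}
    for key in table:
        values[key] = _species_value(table, key, sp)
        prov[key] = ("species_table" if key in _SPECIES_KEYS else
                     "global_table")

    # compound-specific (F shared across species by table layout)
    F = comp["F"]
    k_recycle_tissue = comp["k_recycle_tissue_min"]
    k_DR = comp["k_DR"].get(sp)
    prov.update(F="compound_table", k_recycle_tissue_min="compound_table",
                k_DR="compound_table" if k_DR is not None else "missing")

    # species translation: allometric scaling of liver endosomal degradation,
    # mouse (reference body weight) is the standard individual
    bw_std = load_species_physiology("mouse").reference_body_weight
    if sp == "mouse":
        k_endosome = values["k_endosome_std"]
        prov["k_endosome"] = "global_table"
    else:
        k_endosome = allometric_scale_kendosome(
            values["k_endosome_std"], bw_std, phys.body_weight)
        prov["k_endosome"] = "scaled"

    k_syn = receptor_synthesis_rate(values["R_tot"], values["k_deg"])
    prov["k_syn"] = "derived"

    uptake = {t: values["k_uptake_default_min"] for t in phys.organs}
    for t in ("liver", "kidney", "gonads", "lung", "heart", "spleen"):
        uptake[t] = values[f"k_uptake_{t}_min"]
    recycle = {t: k_recycle_tissue for t in phys.organs}
    recycle["liver"] = values["k_recycle_liver_min"]
    recycle["kidney"] = values["k_recycle_kidney_min"]

    cps = CompoundParameterSet(
        compound_id=compound_id,
        species=sp,
        MW=values["MW"],
        hydrodynamic_radius_nm=values["hydrodynamic_radius_nm"],
        fu=values["fu"],
        F=F,
        ka=values["ka"],
        P_liver_cm_min=values["P_liver_cm_min"],
        k_uptake_min=uptake,
        k_recycle_min=recycle,
        k_RNase=values["k_RNase"],
        RNase_kidney=values["RNase_kidney"],
        RNase_remaining=values["RNase_remaining"],
        R_tot=values["R_tot"],
        k_on=values["k_on"],
        k_off=values["k_off"],
        k_int=values["k_int"],
        k_cle=values["k_cle"],
        k_rec=values["k_rec"],
        k_deg=values["k_deg"],
        k_deg_R=values["k_deg_R"],
        k_syn=k_syn,
        k_endosome=k_endosome,
        f_escape=values["f_escape"],
        k_deg_C=values["k_deg_C"],
        RISC_tot=values["RISC_tot"],
        k_onRISC=values["k_onRISC"],
        k_offRISC=values["k_offRISC"],
        k_DR=k_DR,
        S_max=values["S_max"],
        SC_50=values["SC_50"],
        k_deg_mRNA=values["k_deg_mRNA"],
        k_deg_protein=values["k_deg_protein"],
        gamma=values["gamma"],
    )
    param = Parameterization(compound=cps, species=phys, provenance=prov)
    if overrides:
        param = param.with_updates(**overrides)
        for k in overrides:
            param.provenance[k] = "override"
    return param
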