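"""Anatomical and physiological parameter tables for mouse, monkey, and human.

The whole-body model represents 15 tissues (liver, kidney, lung, heart,
spleen, gonads, brain, muscle, skin, adipose, bone, gut, pancreas, stomach,
and a remaining/carcass pool), each split into vascular, interstitial,
endothelial-endosomal, and intracellular subcompartments, connected by
organ-specific plasma and lymph flows plus central venous and arterial
plasma pools.  Lung sits in series with the total cardiac plasma output;
the remaining organs are perfused in parallel from the arterial pool.
Lymph drains each interstitium directly back to venous plasma.

Reference physiologies are bundled as plain-text YAML tables (one per
species) compiled from standard open physiology compendia, replacing the
closed platform database such models usually rely on.  All values can be
overridden by pointing the loader at a user YAML file of the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

TISSUES = (
    "liver", "kidney", "lung", "heart", "spleen", "gonads", "brain",
    "muscle", "skin", "adipose", "bone", "gut", "pancreas", "stomach",
    "carcass",
)

SUPPORTED_SPECIES = ("mouse", "monkey", "human")


class UnsupportedSpeciesError(ValueError):
    """Raised for species without a bundled reference physiology."""


@dataclass(frozen=True)
class OrganPhysiology:
    """Subcompartment volumes (L), flows (L/h) and exchange area of one organ.

    ``Q_blood`` is the organ plasma flow; ``L_lymph`` the lymph drainage from
    the interstitium; ``S_cap`` the capillary exchange surface area (cm^2);
    ``f_endothelial`` the endothelial endosomal volume as a fraction of the
    vascular volume.
    """

    organ_name: str
    V_vascular: float
    V_interstitial: float
    V_intracellular: float
    V_endosomal: float
    Q_blood: float
    L_lymph: float
    S_cap: float
    f_endothelial: float

    def __post_init__(self) -> None:
        for name in ("V_vascular", "V_interstitial", "V_intracellular",
                     "V_endosomal", "Q_blood", "L_lymph", "S_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"{self.organ_name}: {name} must be strictly positive")
        if self.L_lymph >= self.Q_blood:
            raise ValueError(
                f"{self.organ_name}: lymph flow must be below plasma flow")

    @property
    def V_total(self) -> float:
        return (self.V_vascular + self.V_interstitial
                + self.V_intracellular + self.V_endosomal)


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Whole-body physiology: organs, plasma pools, GFR, cardiac output."""

    species: str
    body_weight: float
    organs: dict[str, OrganPhysiology]
    GFR: float
    hematocrit: float
    Q_cardiac: float
    V_venous: float
    V_arterial: float
    reference_body_weight: float = field(default=0.0)

    def __post_init__(self) -> None:
        missing = set(TISSUES) - set(self.organs)
        extra = set(self.organs) - set(TISSUES)
        if missing or extra:
            raise ValueError(
                f"organ set mismatch: missing={sorted(missing)} "
                f"extra={sorted(extra)}")
        resid = abs(self.systemic_flow - self.Q_cardiac) / self.Q_cardiac
        if resid > 1e-6:
            raise ValueError(
                f"organ flows do not close to cardiac plasma output "
                f"(relative residual {resid:.2e})")

    @property
    def systemic_flow(self) -> float:
        """Sum of parallel (non-lung) organ plasma flows."""
        return sum(o.Q_blood for name, o in self.organs.items()
                   if name != "lung")

    @property
    def total_lymph_flow(self) -> float:
        return sum(o.L_lymph for o in self.organs.values())


def _data_path(name: str) -> Path:
    return Path(str(resources.files("sirnapbpk").joinpath("data", name)))


def load_species_physiology(
    species: str,
    body_weight: float | None = None,
    source: str | Path | None = None,
) -> SpeciesPhysiology:
    """Load the bundled reference physiology, optionally rescaled to a body weight.

    Rescaling is strictly proportional: all volumes, flows and GFR scale
    linearly with ``body_weight / reference_body_weight``, so flow ratios and
    volume fractions are invariant.  ``source`` may point at a user YAML file
    with the bundled layout to override the reference tables.
    """
    if species not in SUPPORTED_SPECIES:
        raise UnsupportedSpeciesError(
            f"unsupported species {species!r}; expected one of "
            f"{SUPPORTED_SPECIES}")
    if body_weight is not None and body_weight <= 0:
        raise ValueError("body_weight must be positive")

    path = Path(source) if source else _data_path(f"physiology_{species}.yaml")
    raw = yaml.safe_load(path.read_text())

    bw_ref = float(raw["body_weight_kg"])
    bw = float(body_weight) if body_weight is not None else bw_ref
    q_cardiac = raw["cardiac_plasma_output_L_h_per_kg"] * bw
    gfr = raw["gfr_L_h_per_kg"] * bw
    f_endo = float(raw["f_endosomal"])
    v_plasma = raw["plasma_volume_frac"] * bw
    v_ven = v_plasma * raw["venous_fraction"]
    v_art = v_plasma - v_ven

    q_fracs = {n: o["q_frac"] for n, o in raw["organs"].items() if n != "lung"}
    q_sum = sum(q_fracs.values())

    organs: dict[str, OrganPhysiology] = {}
    for name, row in raw["organs"].items():
        v_tot = row["v_frac"] * bw  # tissue density 1 kg/L
        v_vas = row["f_vascular"] * v_tot
        v_int = row["f_interstitial"] * v_tot
        f_endo_organ = row.get("f_endo", f_endo)
        v_endo = f_endo_organ * v_vas
        if name == "lung":
            # lung carries the total systemic flow plus its own lymph return
            q = q_cardiac
            lymph = row["l_frac"] * q
            q = q_cardiac + lymph
        else:
            # normalize so parallel flows close exactly to cardiac output
            q = q_cardiac * row["q_frac"] / q_sum
            lymph = row["l_frac"] * q
        organs[name] = OrganPhysiology(
            organ_name=name,
            V_vascular=v_vas,
            V_interstitial=v_int,
            V_intracellular=v_tot - v_vas - v_int - v_endo,
            V_endosomal=v_endo,
            Q_blood=q,
            L_lymph=lymph,
            S_cap=row["scap_cm2_per_g"] * v_tot * 1000.0,  # g at density 1
            f_endothelial=f_endo_organ,
        )

    return SpeciesPhysiology(
        species=species,
        body_weight=bw,
        organs=organs,
        GFR=gfr,
        hematocrit=float(raw["hematocrit"]),
        Q_cardiac=q_cardiac,
        V_venous=v_ven,
        V_arterial=v_art,
        reference_body_weight=bw_ref,
    )
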