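"""Hepatic ASGPR-mediated uptake (extended TMDD), endosomal processing,
cytoplasmic escape, and RISC loading kinetics.

Topology: free surface receptor R binds interstitial drug (second order,
k_on) to a surface complex DR_s which can dissociate (k_off) or internalize
(k_int).  The internalized complex DR_i is cleaved (k_cle), releasing the
drug into the hepatocyte endosomal pool and the receptor into an
internalized pool that recycles to the surface (k_rec) or is degraded
(k_deg_R).  Endosomal drug is processed first order at k_endosome; a
fraction f_escape of that processed flux reaches the cytoplasm as antisense
strand (1:1 molar with parent drug), the remainder is degraded.  Cytoplasmic
antisense loads free RISC (second order, k_onRISC) into the active complex
CRISC, which can dissociate (k_offRISC, returning antisense) or be degraded
(k_DR).  Degradation of the loaded complex destroys only the siRNA cargo
and returns free RISC, so total RISC is conserved at RISC_tot.  Receptor
homeostasis is maintained by zero-order synthesis k_syn = R_tot * k_deg.

All quantities here are amounts (umol); second-order steps divide by the
hepatocyte reference volume to form concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import CompoundParameterSet


@dataclass(frozen=True)
class LiverAsgprParams:
    """Rate constants (1/h; k_on/k_onRISC in (umol/L)^-1 h^-1) and volumes."""

    k_on_u: float
    k_off: float
    k_int: float
    k_cle: float
    k_rec: float
    k_deg: float
    k_deg_R: float
    k_syn_amount: float  # umol/h, zero-order in the hepatocyte volume
    k_endosome: float
    f_escape: float
    k_deg_C: float
    k_onRISC_u: float
    k_offRISC: float
    k_DR: float
    V_hep: float

    @classmethod
    def from_compound(cls, p: "CompoundParameterSet",
                      V_hep: float) -> "LiverAsgprParams":
        return cls(
            k_on_u=p.k_on * 1000.0,  # L/nmol/h -> (umol/L)^-1 h^-1
            k_off=p.k_off,
            k_int=p.k_int,
            k_cle=p.k_cle,
            k_rec=p.k_rec,
            k_deg=p.k_deg,
            k_deg_R=p.k_deg_R,
            k_syn_amount=p.k_syn * V_hep,
            k_endosome=p.k_endosome,
            f_escape=p.f_escape,
            k_deg_C=p.k_deg_C,
            k_onRISC_u=p.k_onRISC * 1000.0,
            k_offRISC=p.k_offRISC,
            k_DR=p.k_DR if p.k_DR is not None else 0.0,
            V_hep=V_hep,
        )


class LiverDerivatives(NamedTuple):
    d_interstitial: float
    dR: float
    dDRS: float
    dDRI: float
    dRI: float
    dEA: float
    dA: float
    dRF: float
    dCR: float
    endosome_degradation: float
    cytoplasm_degradation: float
    risc_degradation: float


def asgpr_binding_rhs(
    C_liver_interstitial: float, R: float, DRS: float, p: LiverAsgprParams,
) -> tuple[float, float, float]:
    """TMDD surface reactions: (binding flux, dR w/o recycling, dDRS).

    The binding flux (umol/h) leaves the interstitial drug pool
    stoichiometrically; dR here covers synthesis, degradation, association
    and dissociation (receptor return from the internalized pool is added by
    the caller).
    """
    if C_liver_interstitial < 0 or R < 0 or DRS < 0:
        raise ValueError("states must be non-negative")
    bind = p.k_on_u * C_liver_interstitial * R
    dR = p.k_syn_amount - p.k_deg * R - bind + p.k_off * DRS
    dDRS = bind - (p.k_off + p.k_int) * DRS
    return bind, dR, dDRS


def endosomal_processing_rhs(
    DRI: float, RI: float, EA: float, p: LiverAsgprParams,
    escape_at_cleavage: bool = False,
) -> tuple[float, float, float, float, float]:
    """Internalized-complex cleavage and endosomal drug processing.

    Returns (dDRI, dRI, dEA, escape flux to cytoplasm, degradation flux).
    By default the escape fraction applies to the first-order endosomal
    processing flux k_endosome * EA; with ``escape_at_cleavage`` it applies
    to the cleavage outflow instead (the endosomal pool then degrades fully
    at k_endosome).
    """
    cleave = p.k_cle * DRI
    dDRI = -cleave  # inflow k_int*DRS added by caller
    dRI = cleave - (p.k_rec + p.k_deg_R) * RI
    if escape_at_cleavage:
        escape = p.f_escape * cleave
        into_endosome = cleave - escape
        degradation = p.k_endosome * EA
    else:
        escape = p.f_escape * p.k_endosome * EA
        into_endosome = cleave
        degradation = (1.0 - p.f_escape) * p.k_endosome * EA
    dEA = into_endosome - escape * (0.0 if escape_at_cleavage else 1.0) \
        - degradation
    return dDRI, dRI, dEA, escape, degradation


def risc_kinetics_rhs(
    A: float, RF: float, CR: float, p: LiverAsgprParams,
) -> tuple[float, float, float, float]:
    """RISC loading: returns (dA from RISC steps, dRF, dCR, k_DR loss flux).

    Free RISC is regenerated on both dissociation and cargo degradation, so
    RF + CR is conserved.
    """
    load = p.k_onRISC_u * (A / p.V_hep) * RF
    risc_loss = p.k_DR * CR
    dA = -load + p.k_offRISC * CR
    dRF = -load + (p.k_offRISC + p.k_DR) * CR
    dCR = load - (p.k_offRISC + p.k_DR) * CR
    return dA, dRF, dCR, risc_loss


def rhs_contributions(
    p: LiverAsgprParams,
    C_int: float,
    R: float, DRS: float, DRI: float, RI: float, EA: float,
    A: float, RF: float, CR: float,
    escape_at_cleavage: bool = False,
) -> LiverDerivatives:
    """Full hepatocyte derivative block used by the whole-body RHS."""
    bind = p.k_on_u * C_int * R
    dR = (p.k_syn_amount - p.k_deg * R - bind + p.k_off * DRS
          + p.k_rec * RI)
    dDRS = bind - (p.k_off + p.k_int) * DRS
    internalize = p.k_int * DRS
    dDRI, dRI, dEA, escape, endo_deg = endosomal_processing_rhs(
        DRI, RI, EA, p, escape_at_cleavage)
    dDRI += internalize
    cyt_deg = p.k_deg_C * A
    dA_risc, dRF, dCR, risc_loss = risc_kinetics_rhs(A, RF, CR, p)
    dA = escape - cyt_deg + dA_risc
    return LiverDerivatives(
        d_interstitial=-bind + p.k_off * DRS,
        dR=dR, dDRS=dDRS, dDRI=dDRI, dRI=dRI, dEA=dEA, dA=dA,
        dRF=dRF, dCR=dCR,
        endosome_degradation=endo_deg,
        cytoplasm_degradation=cyt_deg,
        risc_degradation=risc_loss,
    )
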