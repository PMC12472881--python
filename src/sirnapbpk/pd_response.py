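"""Indirect-response pharmacodynamics: mRNA silencing and protein knockdown.

The loaded RISC concentration stimulates the first-order loss of target
mRNA (relative to a baseline of 1, i.e. 100%):

    dmRNA/dt = k_deg_mRNA * (mRNA_0 - (1 + S_max*C/(SC_50 + C)) * mRNA)

and the protein pool turns over against the mRNA level raised to an
empirical power gamma:

    dProtein/dt = k_deg_protein * (Protein_0 * (mRNA/mRNA_0)^gamma - Protein)

Both baselines are 1 (reported as % of baseline by the I/O layer).  SC_50
and the driving concentration are in nmol/L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import CompoundParameterSet

MRNA_BASELINE = 1.0
PROTEIN_BASELINE = 1.0


@dataclass(frozen=True)
class PdParams:
    S_max: float
    SC_50: float  # nmol/L
    k_deg_mRNA: float
    k_deg_protein: float
    gamma: float

    @classmethod
    def from_compound(cls, p: "CompoundParameterSet") -> "PdParams":
        return cls(S_max=p.S_max, SC_50=p.SC_50, k_deg_mRNA=p.k_deg_mRNA,
                   k_deg_protein=p.k_deg_protein, gamma=p.gamma)


def mrna_rhs(mRNA: float, CRISC_nmol: float, S_max: float, SC_50: float,
             k_deg_mRNA: float) -> float:
    """Turnover of target mRNA with stimulated degradation."""
    stim = S_max * CRISC_nmol / (SC_50 + CRISC_nmol) if CRISC_nmol > 0 else 0.0
    return k_deg_mRNA * (MRNA_BASELINE - (1.0 + stim) * mRNA)


def protein_rhs(Protein: float, mRNA: float, k_deg_protein: float,
                gamma: float) -> float:
    """Turnover of target protein tracking the mRNA level to the power gamma."""
    m = max(mRNA, 0.0)
    return k_deg_protein * (PROTEIN_BASELINE * (m / MRNA_BASELINE) ** gamma
                            - Protein)


def steady_state_knockdown(CRISC_nmol: float, S_max: float, SC_50: float,
                           gamma: float) -> tuple[float, float]:
    """Closed-form steady states for a constant loaded-RISC concentration.

    mRNA_ss = 1 / (1 + S_max*C/(SC_50 + C)); Protein_ss = mRNA_ss ** gamma.
    """
    if CRISC_nmol < 0:
        raise ValueError("CRISC must be non-negative")
    stim = S_max * CRISC_nmol / (SC_50 + CRISC_nmol) if CRISC_nmol > 0 else 0.0
    mrna_ss = 1.0 / (1.0 + stim)
    return mrna_ss, mrna_ss ** gamma
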