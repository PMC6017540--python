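"""Ligand-efficiency indices and the PSA/MW drug-likeness classification.

A docking score ΔG (kcal/mol) is converted to a predicted inhibition constant
with the standard thermodynamic relation at a 1 M reference state,

    Ki = exp(ΔG / RT),        pKi = −log10 Ki,

and pKi is then normalised by size and polarity to give the ligand-efficiency
index (LEI) family:

    LE   = ΔG / NHEA                     (kcal/mol per heavy atom)
    BEI  = pKi / (MW / 1000)             (potency per kDa)
    SEI  = pKi / (PSA / 100)             (potency per 100 Å² polar surface)
    NSEI = pKi / NPOL
    NBEI = pKi / NHEA
    nBEI = −log10(Ki / NHEA) = pKi + log10 NHEA
    mBEI = −log10(Ki / MW)   = pKi + log10 MW      (MW in Da)

Indices whose denominator vanishes (PSA = 0 or NPOL = 0, pure hydrocarbons)
are carried as NaN, never as 0.  Ki is always recomputed from ΔG so scores
from different engines stay commensurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .descriptors import DescriptorSet

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.987204e-3

#: Default temperature (K) for the ΔG → Ki conversion.
T_STANDARD = 298.15


class ChemSpaceBand(str, Enum):
    """Drug-likeness band of the PSA/MW ratio in the SEI–BEI plane."""

    POOR = "poor"
    ACCEPTABLE = "acceptable"
    GOOD = "good"


#: PSA/MW gradient lines drawn on the SEI–BEI plot, steepest (most polar) first.
DEFAULT_GRADIENTS = (0.753, 0.320, 0.200, 0.150, 0.110, 0.090)

#: Band cut points: ratios above POOR_CUT are poor, at or below GOOD_CUT good.
#: Midpoints between the named gradient planes (0.320/0.200 and 0.200/0.150).
POOR_CUT = 0.260
GOOD_CUT = 0.175


@dataclass(frozen=True)
class EfficiencyIndices:
    Ki: float  # molar
    pKi: float
    LE: float  # kcal/mol per heavy atom (negative = favourable)
    BEI: float
    SEI: float  # NaN when PSA == 0
    NSEI: float  # NaN when NPOL == 0
    NBEI: float
    nBEI: float
    mBEI: float


def ki_from_dG(dG: float, T: float = T_STANDARD) -> float:
    """Predicted Ki (molar) from a binding free energy in kcal/mol.

    ``ki_from_dG(0.0)`` is exactly 1 M (the reference state).
    """
    if not math.isfinite(dG):
        raise ValueError(f"dG must be finite, got {dG}")
    return math.exp(dG / (R_KCAL * T))


def pki_from_dG(dG: float, T: float = T_STANDARD) -> float:
    # computed in log space directly so pKi == -log10(Ki) to full precision
    return -dG / (R_KCAL * T * math.log(10.0))


def compute_indices(dG: float, d: DescriptorSet, T: float = T_STANDARD) -> EfficiencyIndices:
    """The seven-index LEI vector for one compound at one docking score."""
    if d.NHEA < 1:
        raise ValueError("NHEA must be >= 1")
    ki = ki_from_dG(dG, T)
    pki = -math.log10(ki)
    return EfficiencyIndices(
        Ki=ki,
        pKi=pki,
        LE=dG / d.NHEA,
        BEI=pki / (d.MW / 1000.0),
        SEI=pki / (d.PSA / 100.0) if d.PSA > 0 else math.nan,
        NSEI=pki / d.NPOL if d.NPOL > 0 else math.nan,
        NBEI=pki / d.NHEA,
        nBEI=pki + math.log10(d.NHEA),
        mBEI=pki + math.log10(d.MW),
    )


def classify_chem_space(
    d: DescriptorSet, poor_cut: float = POOR_CUT, good_cut: float = GOOD_CUT
) -> tuple[float, ChemSpaceBand]:
    """PSA/MW ratio and its drug-likeness band.

    High ratios (very polar for their size) are poor drug-like space, ratios
    near 0.2 acceptable, and low ratios (0.150–0.090 region) good.
    """
    if d.MW <= 0:
        raise ValueError("MW must be > 0")
    ratio = d.PSA / d.MW
    if ratio > poor_cut:
        band = ChemSpaceBand.POOR
    elif ratio > good_cut:
        band = ChemSpaceBand.ACCEPTABLE
    else:
        band = ChemSpaceBand.GOOD
    return ratio, band
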