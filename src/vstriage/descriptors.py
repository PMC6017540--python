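"""Physicochemical descriptors feeding the 16-parameter compound summary.

Conventions (these matter and are deliberate):

* **HBA** uses the Lipinski N+O count, so it equals **NPOL** (the number of
  nitrogen plus oxygen atoms) on every molecule.  **HBD** is the Lipinski
  OH+NH count.  These keep rule-of-five semantics canonical.
* **PSA** is the Ertl topological polar surface area (TPSA), the standard
  reading of "PSA" in library triage.
* **cLogP** is the Crippen atom-contribution estimate; **cLogS** is an
  ESOL-type aqueous-solubility regression (log mol/L).  Both are
  model-dependent estimates and the summary schema records the method names.
* **Rotatable bonds** use the strict definition: non-ring single bonds
  between non-terminal heavy atoms, amide C–N excluded.
* **MW** uses average atomic masses.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .ligands import LigandRecord

#: Method names for the model-dependent descriptors, recorded in summaries.
DESCRIPTOR_METHODS = {
    "PSA": "TPSA (Ertl)",
    "cLogP": "Crippen atom contributions",
    "cLogS": "ESOL (Delaney) regression",
}

#: Elements covered by the Crippen/TPSA parameterisations used here.
_PARAMETERISED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

#: Canonical rule-of-five thresholds.
LIPINSKI_RULES = (
    ("MW", 500.0),
    ("cLogP", 5.0),
    ("HBD", 5),
    ("HBA", 10),
)


class DescriptorError(ValueError):
    pass


@dataclass(frozen=True)
class DescriptorSet:
    MW: float  # Da, average atomic masses
    cLogS: float
    cLogP: float
    HBD: int
    HBA: int  # Lipinski N+O convention; equals NPOL
    PSA: float  # Å², topological
    rotatable_bonds: int
    NHEA: int  # non-hydrogen (heavy) atoms
    NPOL: int  # nitrogen + oxygen atoms

    def __post_init__(self) -> None:
        if self.MW <= 0:
            raise DescriptorError(f"MW must be > 0, got {self.MW}")
        if self.NHEA < 1:
            raise DescriptorError("NHEA must be >= 1")
        if min(self.HBD, self.HBA, self.rotatable_bonds, self.NPOL) < 0 or self.PSA < 0:
            raise DescriptorError("counts and PSA must be non-negative")
        if self.NPOL > self.NHEA or self.HBA > self.NHEA:
            raise DescriptorError("NPOL/HBA cannot exceed heavy-atom count")


def esol_logs(mw: float, clogp: float, rotatable: int, aromatic_proportion: float) -> float:
    """ESOL estimated aqueous solubility, log10 of molar solubility.

    Delaney's four-term regression on logP, MW, rotatable-bond count and the
    aromatic proportion (aromatic heavy atoms / heavy atoms).
    """
    return 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rotatable - 0.74 * aromatic_proportion


def compute_descriptors(ligand: LigandRecord | Chem.Mol) -> DescriptorSet:
    """Compute the descriptor block for one compound.

    Deterministic, independent of atom ordering and of 3-D coordinates
    (all descriptors are topological).  Raises :class:`DescriptorError`
    naming the element when the molecule contains an element outside the
    Crippen/TPSA parameterisation.
    """
    mol = ligand.mol if isinstance(ligand, LigandRecord) else ligand
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in _PARAMETERISED_ELEMENTS:
            raise DescriptorError(
                f"element {atom.GetSymbol()!r} is outside the descriptor parameterisation"
            )
    if mol.GetNumHeavyAtoms() < 1:
        raise DescriptorError("molecule has no heavy atoms")

    mw = Descriptors.MolWt(mol)
    clogp = Crippen.MolLogP(mol)
    rotatable = rdMolDescriptors.CalcNumRotatableBonds(
        mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
    )
    nhea = mol.GetNumHeavyAtoms()
    npol = sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic() and a.GetAtomicNum() > 1)
    return DescriptorSet(
        MW=mw,
        cLogS=esol_logs(mw, clogp, rotatable, aromatic / nhea),
        cLogP=clogp,
        HBD=Lipinski.NHOHCount(mol),
        HBA=Lipinski.NOCount(mol),
        PSA=rdMolDescriptors.CalcTPSA(mol),
        rotatable_bonds=rotatable,
        NHEA=nhea,
        NPOL=npol,
    )


def lipinski_pass(d: DescriptorSet, max_violations: int = 0) -> tuple[bool, list[str]]:
    """Rule-of-five check: MW ≤ 500, cLogP ≤ 5, HBD ≤ 5, HBA ≤ 10.

    Returns ``(pass, violations)`` where ``pass`` is true iff at most
    ``max_violations`` rules fail; ``violations`` always lists the failed
    rule names.
    """
    violations = [name for name, limit in LIPINSKI_RULES if getattr(d, name) > limit]
    return len(violations) <= max_violations, violations
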