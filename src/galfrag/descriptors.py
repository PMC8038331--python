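"""Physicochemical descriptors: formula, mass, H-bond counts, TPSA, logP.

Formula handling and mass fractions are computed from packaged atomic
weights so that reported values reproduce classical elemental-analysis
calculators to two decimals.  Topological polar surface area uses Ertl's
fragment contributions and logP the Wildman–Crippen atomic scheme, both
via RDKit.  Hydrogen-bond donors/acceptors follow the Lipinski
definitions: a donor is an N or O bearing at least one hydrogen, an
acceptor is any N or O atom.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors

__all__ = [
    "ATOMIC_WEIGHTS",
    "DescriptorSet",
    "DescriptorError",
    "parse_formula",
    "molecular_formula",
    "molecular_weight",
    "elemental_percents",
    "count_hbd_hba",
    "compute_descriptors",
]

#: Conventional atomic weights (CIAAW conventional/abridged values as used
#: by elemental-analysis calculators), g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.00794,
    "B": 10.811,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "F": 18.9984032,
    "Na": 22.98976928,
    "Mg": 24.3050,
    "Si": 28.0855,
    "P": 30.973762,
    "S": 32.065,
    "Cl": 35.453,
    "K": 39.0983,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.90447,
}


class DescriptorError(ValueError):
    """Raised for unparseable structures or malformed formulas."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Counter:
    """Parse a Hill-notation formula (no charges, no parentheses) into
    element → count."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise DescriptorError(f"malformed formula {formula!r}")
    counts: Counter = Counter()
    for sym, num in _FORMULA_TOKEN.findall(formula):
        if not sym:
            continue
        counts[sym] += int(num) if num else 1
    return counts


def _as_mol(mol: "Chem.Mol | str") -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    parsed = Chem.MolFromSmiles(mol)
    if parsed is None:
        raise DescriptorError(f"structure does not parse: {mol!r}")
    return parsed


def molecular_formula(mol: "Chem.Mol | str") -> str:
    """Hill-notation molecular formula (C first, H second, rest
    alphabetical) with implicit hydrogens resolved."""
    m = _as_mol(mol)
    if m.GetNumAtoms() == 0:
        raise DescriptorError("empty molecule has no formula")
    return rdMolDescriptors.CalcMolFormula(m)


def molecular_weight(formula: str) -> float:
    """Average molecular mass (Da) of a Hill formula, full precision.

    Round to two decimals at reporting time; internal consumers keep the
    full value.
    """
    counts = parse_formula(formula)
    mw = 0.0
    for sym, n in counts.items():
        try:
            mw += n * ATOMIC_WEIGHTS[sym]
        except KeyError:
            raise DescriptorError(f"unknown element symbol {sym!r}") from None
    return mw


def elemental_percents(formula: str, decimals: int | None = 2) -> dict[str, float]:
    """Calculated elemental-analysis mass percents of a formula.

    percent(E) = 100 · n_E · w_E / MW.  With ``decimals=None`` the full
    precision values are returned (they sum to exactly 100); the default
    two-decimal rounding matches how the values are conventionally printed.
    """
    counts = parse_formula(formula)
    mw = molecular_weight(formula)
    out = {}
    for sym, n in counts.items():
        pct = 100.0 * n * ATOMIC_WEIGHTS[sym] / mw
        out[sym] = round(pct, decimals) if decimals is not None else pct
    return out


def count_hbd_hba(mol: "Chem.Mol | str") -> tuple[int, int]:
    """Lipinski hydrogen-bond donor and acceptor counts.

    Donors: N/O atoms carrying at least one hydrogen.  Acceptors: every
    N and O atom.
    """
    m = _as_mol(mol)
    hbd = 0
    hba = 0
    for atom in m.GetAtoms():
        if atom.GetAtomicNum() in (7, 8):
            hba += 1
            if atom.GetTotalNumHs() > 0:
                hbd += 1
    return hbd, hba


@dataclass
class DescriptorSet:
    """The descriptor profile reported for a candidate molecule."""

    formula: str
    mw: float
    hbd: int
    hba: int
    tpsa: float
    logp: float
    elemental: dict[str, float] = field(default_factory=dict)
    annotations: dict[str, float] = field(default_factory=dict)  # e.g. measured pKa/logD pass-through

    def as_row(self) -> dict:
        row = {
            "formula": self.formula,
            "mw": round(self.mw, 2),
            "hbd": self.hbd,
            "hba": self.hba,
            "tpsa": round(self.tpsa, 2),
            "logp": round(self.logp, 2),
        }
        for sym, pct in self.elemental.items():
            row[f"pct_{sym}"] = pct
        row.update(self.annotations)
        return row


def compute_descriptors(
    mol: "Chem.Mol | str",
    annotations: dict[str, float] | None = None,
) -> DescriptorSet:
    """Full descriptor profile of one molecule.

    TPSA is the Ertl topological polar surface area (Å²) and logP the
    Wildman–Crippen atomic-contribution estimate; both are computed on the
    neutral structure as given (no microspecies enumeration).
    """
    m = _as_mol(mol)
    if m.GetNumAtoms() == 0:
        raise DescriptorError("empty molecule")
    formula = molecular_formula(m)
    hbd, hba = count_hbd_hba(m)
    return DescriptorSet(
        formula=formula,
        mw=molecular_weight(formula),
        hbd=hbd,
        hba=hba,
        tpsa=rdMolDescriptors.CalcTPSA(m),
        logp=Crippen.MolLogP(m),
        elemental=elemental_percents(formula),
        annotations=dict(annotations or {}),
    )


def descriptor_report(candidates) -> "pd.DataFrame":
    """Descriptor CSV rows for assembled candidates (structure required)."""
    import pandas as pd

    rows = []
    for cand in candidates:
        if cand.structure is None:
            raise DescriptorError(
                f"{cand.candidate_id}: no structure (counting-mode candidate)"
            )
        ds = compute_descriptors(cand.structure)
        row = {"candidate_id": cand.candidate_id}
        row.update(ds.as_row())
        rows.append(row)
    return pd.DataFrame(rows)
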