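"""Molecular-formula arithmetic for negative-mode LC-HRMS validation.

Parses Hill-style element-count strings (``C42H72O14``), computes exact
monoisotopic masses, derives deprotonated and formate-adduct m/z values,
and expresses mass accuracy as a signed ppm error.

Adduct arithmetic follows the proton-mass convention: the m/z of
[M-H]- is M minus the mass of a proton (1.00727646 Da); the ~0.5 mDa
electron mass is neglected, which is standard practice at the precision
LC-HRMS instruments print.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator, Mapping

__all__ = [
    "MolecularFormula",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "round_half_away",
    "PROTON_MASS",
    "FORMIC_ACID_MASS",
    "MONOISOTOPIC_MASSES",
]

#: Monoisotopic masses of the most abundant isotope (Da), CODATA/IUPAC.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
}

PROTON_MASS = 1.00727646
#: Neutral formic acid, HCOOH.
FORMIC_ACID_MASS = 46.00548

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparsable or mass-less molecular formulas."""


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> count multiset, e.g. ``{C: 42, H: 72, O: 14}``."""

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        if not counts:
            raise FormulaError("formula must contain at least one atom")
        for elem, n in counts.items():
            if n < 1:
                raise FormulaError(f"count for {elem} must be >= 1, got {n}")
        object.__setattr__(self, "element_counts", counts)

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.element_counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = Counter(self.element_counts)
        merged.update(other.element_counts)
        return MolecularFormula(dict(merged))

    def to_string(self) -> str:
        """Hill order: C first, H second, then alphabetical."""
        counts = dict(self.element_counts)
        ordered = []
        for elem in ("C", "H"):
            if elem in counts:
                ordered.append((elem, counts.pop(elem)))
        ordered.extend(sorted(counts.items()))
        return "".join(f"{e}{n if n != 1 else ''}" for e, n in ordered)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_formula(text: str) -> MolecularFormula:
    """Parse ``C42H72O14``-style text into a :class:`MolecularFormula`.

    A bare element symbol carries an implicit count of 1 (``H2O`` ->
    ``{H: 2, O: 1}``). Repeated symbols accumulate. Raises
    :class:`FormulaError` on empty input, unknown element symbols, or
    stray characters.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Counter[str] = Counter()
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"unparsable formula {text!r} at position {pos}")
        elem, digits = match.groups()
        if elem not in MONOISOTOPIC_MASSES:
            raise FormulaError(f"unknown element symbol {elem!r} in {text!r}")
        counts[elem] += int(digits) if digits else 1
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"unparsable formula {text!r} at position {pos}")
    return MolecularFormula(dict(counts))


def monoisotopic_mass(f: MolecularFormula | str) -> float:
    """Exact mass (Da) of the all-most-abundant-isotope species."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(MONOISOTOPIC_MASSES[e] * n for e, n in f.element_counts.items())


#: Adduct label -> additive mass shift applied to the neutral mass.
_ADDUCT_SHIFTS = {
    "[M-H]-": -PROTON_MASS,
    "[M-H+FA]-": FORMIC_ACID_MASS - PROTON_MASS,
}


def _normalize_adduct(adduct: str) -> str:
    # tolerate unicode minus signs and superscript charge markup
    cleaned = (
        adduct.replace("−", "-")
        .replace("–", "-")
        .replace("^-^", "-")
        .replace(" ", "")
    )
    return cleaned


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged negative-mode adduct.

    Supported: ``[M-H]-`` (deprotonation) and ``[M-H+FA]-`` (formate,
    i.e. attachment of HCOO-).
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    key = _normalize_adduct(adduct)
    if key not in _ADDUCT_SHIFTS:
        raise ValueError(f"unknown adduct {adduct!r}; supported: {sorted(_ADDUCT_SHIFTS)}")
    return neutral_mass + _ADDUCT_SHIFTS[key]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error: 1e6 * (observed - theoretical) / theoretical."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (1.25 -> 1.3, -1.25 -> -1.3).

    Instrument software prints ppm columns with this convention rather
    than banker's rounding.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
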