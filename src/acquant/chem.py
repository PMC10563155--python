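"""Elemental compositions and monoisotopic masses.

Masses of peptides and fixed modifications are computed from hard-coded
monoisotopic atomic masses (IUPAC values, six decimals) so that results are
reproducible constants independent of any runtime lookup.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from typing import Iterator

__all__ = [
    "ElementalComposition",
    "monoisotopic_mass",
    "peptide_composition",
    "peptide_mass",
    "CARBAMIDOMETHYL",
    "METHYLTHIO",
    "ACETYL",
    "WATER",
]

#: Monoisotopic masses of the most abundant isotope, in Da.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.007825,
    "C": 12.000000,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
    "P": 30.973762,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalComposition(Mapping):
    """Immutable multiset of chemical elements, e.g. ``C2H3NO``.

    Accepts either a mapping of element symbol to count or a Hill-style
    formula string. Compositions add with ``+`` and compare by content.
    """

    __slots__ = ("_counts",)

    def __init__(self, source: Mapping[str, int] | str | None = None, **counts: int):
        merged: dict[str, int] = {}
        if isinstance(source, str):
            merged.update(self._parse(source))
        elif source is not None:
            merged.update(source)
        merged.update(counts)
        for element, count in merged.items():
            if not isinstance(count, int) or count < 0:
                raise ValueError(f"count for element {element!r} must be a non-negative integer, got {count!r}")
        self._counts = {el: n for el, n in merged.items() if n > 0}

    @staticmethod
    def _parse(formula: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"malformed formula {formula!r} at position {pos}")
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(formula):
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        return counts

    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for element, n in other.items():
            counts[element] = counts.get(element, 0) + n
        return ElementalComposition(counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        body = "".join(f"{el}{n if n > 1 else ''}" for el, n in sorted(self._counts.items()))
        return f"ElementalComposition({body!r})"


#: Fixed cysteine modification used with standard reduction/alkylation.
CARBAMIDOMETHYL = ElementalComposition("C2H3NO")
#: Fixed cysteine modification left by MMTS-based alkylation.
METHYLTHIO = ElementalComposition("CH2S")
#: Mass added by acetylation of a lysine epsilon-amine.
ACETYL = ElementalComposition("C2H2O")
WATER = ElementalComposition("H2O")

#: Residue (in-chain) compositions of the 20 standard amino acids.
RESIDUE_COMPOSITION: dict[str, ElementalComposition] = {
    "G": ElementalComposition("C2H3NO"),
    "A": ElementalComposition("C3H5NO"),
    "S": ElementalComposition("C3H5NO2"),
    "P": ElementalComposition("C5H7NO"),
    "V": ElementalComposition("C5H9NO"),
    "T": ElementalComposition("C4H7NO2"),
    "C": ElementalComposition("C3H5NOS"),
    "L": ElementalComposition("C6H11NO"),
    "I": ElementalComposition("C6H11NO"),
    "N": ElementalComposition("C4H6N2O2"),
    "D": ElementalComposition("C4H5NO3"),
    "Q": ElementalComposition("C5H8N2O2"),
    "K": ElementalComposition("C6H12N2O"),
    "E": ElementalComposition("C5H7NO3"),
    "M": ElementalComposition("C5H9NOS"),
    "H": ElementalComposition("C6H7N3O"),
    "F": ElementalComposition("C9H9NO"),
    "R": ElementalComposition("C6H12N4O"),
    "Y": ElementalComposition("C9H9NO2"),
    "W": ElementalComposition("C11H10N2O"),
}


def monoisotopic_mass(composition: ElementalComposition | Mapping[str, int] | str) -> float:
    """Monoisotopic mass in Da of an elemental composition.

    Unknown element symbols raise ``ValueError``.
    """
    if not isinstance(composition, ElementalComposition):
        composition = ElementalComposition(composition)
    mass = 0.0
    for element, count in composition.items():
        try:
            mass += count * ATOMIC_MASS[element]
        except KeyError:
            raise ValueError(f"unknown element {element!r}") from None
    return mass


def peptide_composition(sequence: str, acetyl_count: int = 0) -> ElementalComposition:
    """Composition of a linear peptide: residue sum plus one water.

    ``acetyl_count`` adds that many acetyl groups (blocked lysines carried
    into the peptide).
    """
    comp = WATER
    for residue in sequence:
        try:
            comp = comp + RESIDUE_COMPOSITION[residue]
        except KeyError:
            raise ValueError(f"unknown amino acid {residue!r}") from None
    for _ in range(acetyl_count):
        comp = comp + ACETYL
    return comp


def peptide_mass(sequence: str, acetyl_count: int = 0) -> float:
    """Monoisotopic mass of a peptide in Da."""
    return monoisotopic_mass(peptide_composition(sequence, acetyl_count))
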