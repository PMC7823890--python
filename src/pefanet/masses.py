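"""Elemental-formula arithmetic and exact monoisotopic adduct masses.

Small, self-contained mass calculator for the elements occurring in
acetylated polyol esters of fatty acids (PEFAs) and their common
positive-mode adducts.  Two charge-carrier conventions are supported:

``ion-mass``
    The physically correct one: the m/z of a singly charged cation is the
    neutral mass plus the *ionic* mass of the charge carrier, i.e. the
    atomic mass minus one electron mass.

``atom-mass``
    The neutral-atom mass is added with no electron correction.  High-
    resolution values in the literature are frequently computed this way
    for protonated species, so the convention is selectable rather than
    hard-wired.

The two conventions differ by exactly one electron mass (~0.55 mDa),
which matters at the fourth decimal of an m/z value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Mapping

__all__ = [
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "AdductSpec",
    "formula_add",
    "monoisotopic_mass",
    "adduct_mz",
    "ACETIC_ACID_LOSS",
    "WATER",
]

#: Monoisotopic atomic masses (Da), CODATA/NIST values.
ATOMIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.9897692809,
}

#: Electron rest mass (Da).
ELECTRON_MASS: float = 0.0005485799

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An element → count map supporting exact-mass arithmetic.

    Counts must be non-negative and every element must be one of the
    supported set (C, H, N, O, Na).  Instances are immutable and
    hashable; arithmetic returns new instances.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for element, n in self.counts.items():
            if element not in ATOMIC_MASS:
                raise ValueError(f"unsupported element: {element!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"negative or non-integer count for {element}: {n!r}")
            if n:
                clean[element] = n
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``"C30H52O12"``."""
        counts: Dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for element, n in other.counts.items():
            counts[element] = counts.get(element, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for element, n in other.counts.items():
            new = counts.get(element, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative count for {element}: "
                    f"{counts.get(element, 0)} - {n}"
                )
            counts[element] = new
        return ElementalFormula(counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise ValueError(f"multiplier must be a non-negative integer, got {k!r}")
        return ElementalFormula({e: n * k for e, n in self.counts.items()})

    __rmul__ = __mul__

    def __hash__(self) -> int:
        return hash(tuple(self.counts.items()))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(self.counts, key=lambda e: {"C": "0", "H": "1"}.get(e, e))
        return "".join(
            f"{e}{self.counts[e]}" if self.counts[e] != 1 else e for e in order
        )

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged positive adduct and the mass convention to apply.

    ``name`` is ``"M+H"`` or ``"M+Na"``; ``convention`` is ``"ion-mass"``
    (default, subtracts the electron mass of the lost electron) or
    ``"atom-mass"`` (adds the neutral atom mass unchanged).
    """

    name: str = "M+Na"
    convention: str = "ion-mass"

    _CARRIERS = {"M+H": "H", "M+Na": "Na"}

    def __post_init__(self) -> None:
        if self.name not in self._CARRIERS:
            raise ValueError(f"unsupported adduct: {self.name!r}")
        if self.convention not in ("ion-mass", "atom-mass"):
            raise ValueError(f"unknown convention: {self.convention!r}")

    @property
    def carrier_mass(self) -> float:
        mass = ATOMIC_MASS[self._CARRIERS[self.name]]
        if self.convention == "ion-mass":
            mass -= ELECTRON_MASS
        return mass


def formula_add(a: ElementalFormula, b: ElementalFormula) -> ElementalFormula:
    """Element-wise sum of two formulas."""
    return a + b


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Exact monoisotopic mass (Da) of a neutral formula."""
    return sum(ATOMIC_MASS[e] * n for e, n in f.counts.items())


def adduct_mz(f: ElementalFormula, adduct: AdductSpec = AdductSpec()) -> float:
    """m/z of the singly charged adduct ion of neutral formula *f*.

    Full precision is returned; round half-even to 4 decimals for display
    to match the usual high-resolution reporting precision.
    """
    return monoisotopic_mass(f) + adduct.carrier_mass


# Frequently used neutral species.
WATER = ElementalFormula({"H": 2, "O": 1})
#: Acetic acid, the neutral lost per acetyloxy group (60.0211 Da).
ACETIC_ACID_LOSS = ElementalFormula({"C": 2, "H": 4, "O": 2})
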