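"""Combinatorial library of theoretical PEFA species and their MS/MS signatures.

A PEFA (polyol ester of fatty acid) is a sugar-alcohol head group —
mannitol or arabitol, carrying zero or more O-acetyl groups — esterified
to a fatty acid that is itself substituted at C-3 (hydroxy, acetoxy or
methoxy).  Because the building blocks combine freely, the observable
chemical space is a small Cartesian product, and every member's exact
neutral formula, sodiated precursor m/z and diagnostic fragments follow
from arithmetic:

* each acetyloxy group anywhere in the molecule can be lost as acetic
  acid (60.0211 Da), producing a descending fragment ladder from the
  precursor;
* loss of the intact fatty acid (as the free acid) leaves the sodiated
  acetylated-polyol "residual ion", which identifies the head group and
  its degree of acetylation at a glance.

Positional isomers (which hydroxyls carry the acetyl groups) are not
enumerated: they are isobaric and indistinguishable by these rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .masses import (
    ACETIC_ACID_LOSS,
    WATER,
    AdductSpec,
    ElementalFormula,
    adduct_mz,
    monoisotopic_mass,
)

__all__ = [
    "POLYOL_FORMULAS",
    "MAX_POLYOL_ACETYLS",
    "PefaSpecies",
    "FragmentPrediction",
    "LibraryConfig",
    "LibraryEntry",
    "species_formula",
    "fatty_acid_formula",
    "predict_fragments",
    "enumerate_library",
    "residual_ion_table",
    "library_to_frame",
]

POLYOL_FORMULAS: Dict[str, ElementalFormula] = {
    "mannitol": ElementalFormula.parse("C6H14O6"),
    "arabitol": ElementalFormula.parse("C5H12O5"),
}

# One hydroxyl is consumed by the ester bond to the fatty acid, so a
# hexitol can carry at most 5 acetyls and a pentitol at most 4.
MAX_POLYOL_ACETYLS: Dict[str, int] = {"mannitol": 5, "arabitol": 4}

_ACETYL = ElementalFormula({"C": 2, "H": 2, "O": 1})  # net +C2H2O per O-acetylation
_C3_MODIFICATION: Dict[str, ElementalFormula] = {
    "hydroxy": ElementalFormula({"O": 1}),
    "acetoxy": ElementalFormula({"C": 2, "H": 2, "O": 2}),
    "methoxy": ElementalFormula({"C": 1, "H": 2, "O": 1}),
}


@dataclass(frozen=True)
class PefaSpecies:
    """Structural descriptor of one theoretical PEFA.

    Parameters
    ----------
    polyol:
        Head group, ``"mannitol"`` or ``"arabitol"``.
    polyol_acetyl_count:
        Number of O-acetyl groups on the polyol (0–5 for mannitol,
        0–4 for arabitol).
    chain_length:
        Carbon count of the base fatty acid (even).
    c3_substituent:
        Substituent at C-3 of the fatty acid: ``"hydroxy"``,
        ``"acetoxy"`` or ``"methoxy"``.
    """

    polyol: str
    polyol_acetyl_count: int
    chain_length: int
    c3_substituent: str

    def __post_init__(self) -> None:
        if self.polyol not in POLYOL_FORMULAS:
            raise ValueError(f"unknown polyol: {self.polyol!r}")
        if not 0 <= self.polyol_acetyl_count <= MAX_POLYOL_ACETYLS[self.polyol]:
            raise ValueError(
                f"{self.polyol} supports 0–{MAX_POLYOL_ACETYLS[self.polyol]} "
                f"acetyls, got {self.polyol_acetyl_count}"
            )
        if self.chain_length < 2 or self.chain_length % 2:
            raise ValueError(f"chain_length must be a positive even integer, got {self.chain_length}")
        if self.c3_substituent not in _C3_MODIFICATION:
            raise ValueError(f"unknown C-3 substituent: {self.c3_substituent!r}")

    @property
    def total_acetyl_count(self) -> int:
        """Acetyl groups in the whole molecule (polyol + C-3 acetoxy)."""
        return self.polyol_acetyl_count + (1 if self.c3_substituent == "acetoxy" else 0)

    def label(self) -> str:
        return (
            f"{self.polyol}-{self.polyol_acetyl_count}Ac-"
            f"C{self.chain_length}-3{self.c3_substituent}"
        )


@dataclass(frozen=True)
class FragmentPrediction:
    """One predicted diagnostic fragment of a PEFA adduct ion."""

    mz: float
    rationale: str  # e.g. "acetyl-loss x2", "fatty-acid loss", "fatty-acid loss + 1 acetyl"
    neutral_loss_formula: ElementalFormula


def fatty_acid_formula(s: PefaSpecies) -> ElementalFormula:
    """Neutral formula of the species' intact free fatty acid.

    The base acid CnH2nO2 plus the C-3 modification, e.g. 3-acetoxy-
    hexadecanoic acid C18H34O4 for (chain 16, acetoxy).
    """
    base = ElementalFormula({"C": s.chain_length, "H": 2 * s.chain_length, "O": 2})
    return base + _C3_MODIFICATION[s.c3_substituent]


def species_formula(s: PefaSpecies) -> ElementalFormula:
    """Neutral molecular formula of a PEFA species.

    Polyol + n acetyl increments + modified fatty acid − water for the
    ester bond.
    """
    return (
        POLYOL_FORMULAS[s.polyol]
        + s.polyol_acetyl_count * _ACETYL
        + fatty_acid_formula(s)
        - WATER
    )


def predict_fragments(
    s: PefaSpecies, adduct: AdductSpec = AdductSpec("M+Na")
) -> List[FragmentPrediction]:
    """Predicted diagnostic fragments of the adduct ion of species *s*.

    Three fragment classes, all as the sodiated (or protonated) ion:

    1. sequential acetic-acid losses from the precursor, one step per
       acetyl group in the whole molecule;
    2. loss of the intact free fatty acid, leaving the residual
       acetylated-polyol ion;
    3. further acetic-acid losses from that residual ion.
    """
    precursor = adduct_mz(species_formula(s), adduct)
    fragments: List[FragmentPrediction] = []

    for k in range(1, s.total_acetyl_count + 1):
        loss = k * ACETIC_ACID_LOSS
        fragments.append(
            FragmentPrediction(
                mz=precursor - monoisotopic_mass(loss),
                rationale=f"acetyl-loss x{k}",
                neutral_loss_formula=loss,
            )
        )

    fa = fatty_acid_formula(s)
    fa_mass = monoisotopic_mass(fa)
    fragments.append(
        FragmentPrediction(
            mz=precursor - fa_mass,
            rationale="fatty-acid loss",
            neutral_loss_formula=fa,
        )
    )
    for k in range(1, s.polyol_acetyl_count + 1):
        loss = fa + k * ACETIC_ACID_LOSS
        fragments.append(
            FragmentPrediction(
                mz=precursor - monoisotopic_mass(loss),
                rationale=f"fatty-acid loss + {k} acetyl",
                neutral_loss_formula=loss,
            )
        )
    return fragments


@dataclass(frozen=True)
class LibraryConfig:
    """Enumeration ranges for the theoretical PEFA library.

    Defaults cover both polyols, all allowed acetylation degrees, even
    chains C10–C20 and the 3-hydroxy/3-acetoxy substituents (132
    species).  3-methoxy species are rare and excluded by default;
    set ``include_methoxy=True`` to add them.
    """

    polyols: Tuple[str, ...] = ("mannitol", "arabitol")
    chain_lengths: Tuple[int, ...] = (10, 12, 14, 16, 18, 20)
    include_methoxy: bool = False
    adducts: Tuple[AdductSpec, ...] = (AdductSpec("M+Na"),)

    @property
    def substituents(self) -> Tuple[str, ...]:
        return ("hydroxy", "acetoxy") + (("methoxy",) if self.include_methoxy else ())


@dataclass(frozen=True)
class LibraryEntry:
    species: PefaSpecies
    formula: ElementalFormula
    precursor_mz: Dict[str, float]  # adduct name -> m/z

    def precursor(self, adduct_name: str = "M+Na") -> float:
        return self.precursor_mz[adduct_name]


def enumerate_library(cfg: LibraryConfig = LibraryConfig()) -> List[LibraryEntry]:
    """Full Cartesian product of the configured PEFA space.

    Deterministic ordering: polyol, acetyl count, chain length,
    substituent (in the configuration's stated orders).
    """
    if not cfg.chain_lengths:
        raise ValueError("chain_lengths must be non-empty")
    entries: List[LibraryEntry] = []
    for polyol in cfg.polyols:
        for n_acetyl in range(MAX_POLYOL_ACETYLS[polyol] + 1):
            for chain, subst in product(cfg.chain_lengths, cfg.substituents):
                species = PefaSpecies(polyol, n_acetyl, chain, subst)
                formula = species_formula(species)
                mzs = {a.name: adduct_mz(formula, a) for a in cfg.adducts}
                entries.append(LibraryEntry(species, formula, mzs))
    return entries


def residual_ion_table(
    adduct: AdductSpec = AdductSpec("M+Na"),
    polyols: Optional[Iterable[str]] = None,
) -> Dict[Tuple[str, int], float]:
    """m/z of the residual acetylated-polyol ion per (polyol, acetyl count).

    The residual ion is the polyol with its acetyl groups, minus the
    water lost to the ester bond, as the charged adduct — i.e. what
    remains after neutral loss of the intact fatty acid.
    """
    table: Dict[Tuple[str, int], float] = {}
    for polyol in polyols or POLYOL_FORMULAS:
        for a in range(MAX_POLYOL_ACETYLS[polyol] + 1):
            residual = POLYOL_FORMULAS[polyol] + a * _ACETYL - WATER
            table[(polyol, a)] = adduct_mz(residual, adduct)
    return table


def library_to_frame(entries: Sequence[LibraryEntry]) -> pd.DataFrame:
    """Flatten a library to a table for export/inspection."""
    rows = []
    for entry in entries:
        s = entry.species
        row = {
            "label": s.label(),
            "polyol": s.polyol,
            "polyol_acetyl_count": s.polyol_acetyl_count,
            "chain_length": s.chain_length,
            "c3_substituent": s.c3_substituent,
            "formula": str(entry.formula),
            "neutral_mass": monoisotopic_mass(entry.formula),
        }
        for name, mz in entry.precursor_mz.items():
            row[f"mz_{name.replace('+', '_')}"] = mz
        row["fragments"] = ";".join(
            f"{fp.mz:.4f}" for fp in predict_fragments(s, AdductSpec("M+Na"))
        )
        rows.append(row)
    return pd.DataFrame(rows)
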