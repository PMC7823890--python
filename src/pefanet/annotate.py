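"""Rule-based PEFA annotation of observed MS/MS features.

The identification logic mirrors how a mass spectrometrist reads a PEFA
spectrum by hand:

1. match the precursor against the theoretical library of exact adduct
   masses (head-group candidates);
2. count how many sequential 60.0211 Da (acetic acid) neutral losses
   descend from the precursor — each step is one acetyloxy group;
3. look for the residual acetylated-polyol ion left after loss of the
   intact fatty acid, which pins down the head group (mannitol vs
   arabitol) and its acetylation degree.

A candidate is retained only when both evidence types are consistent
with its structure; the confidence tier records how much evidence
supported the call.  Acetylation *positions* are not assigned — the
positional isomers are isobaric and fragment identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .library import (
    LibraryEntry,
    PefaSpecies,
    residual_ion_table,
)
from .masses import ACETIC_ACID_LOSS, AdductSpec, monoisotopic_mass
from .spectra import FragmentSpectrum

__all__ = [
    "ACETYL_STEP",
    "ResidualIonMatch",
    "Annotation",
    "count_acetyl_ladder",
    "assign_headgroup",
    "annotate_feature",
    "annotate_all",
    "annotations_to_frame",
]

#: Mass of one acetic-acid neutral loss (Da).
ACETYL_STEP: float = monoisotopic_mass(ACETIC_ACID_LOSS)


@dataclass(frozen=True)
class ResidualIonMatch:
    """An observed fragment matching a residual acetylated-polyol ion."""

    polyol: str
    acetyl_count: int
    observed_mz: float
    predicted_mz: float

    @property
    def delta(self) -> float:
        return self.observed_mz - self.predicted_mz


@dataclass
class Annotation:
    """Outcome of annotating one feature against the PEFA library.

    ``confidence`` is ``"full"`` when the precursor matched and at least
    one fragment-level evidence type (acetyl ladder or residual ion)
    supported it, ``"precursor-only"`` when only the precursor matched,
    and ``"none"`` otherwise.
    """

    feature_id: str
    matched_species: Optional[PefaSpecies]
    precursor_error_ppm: Optional[float]
    ladder_count: int
    residual_ion_match: Optional[ResidualIonMatch]
    confidence: str

    def __post_init__(self) -> None:
        if self.ladder_count < 0:
            raise ValueError("ladder_count must be >= 0")
        if self.confidence == "full" and not (
            self.matched_species is not None
            and (self.ladder_count >= 1 or self.residual_ion_match is not None)
        ):
            raise ValueError("confidence 'full' requires precursor and fragment evidence")


def count_acetyl_ladder(
    precursor_mz: float, fragment_mzs: Sequence[float], tol: float = 0.02
) -> int:
    """Length of the acetic-acid-loss ladder descending from the precursor.

    Starting at the precursor, repeatedly look for a fragment whose m/z
    sits within *tol* of the current anchor minus 60.0211 Da, stepping
    onto the closest such fragment.  Each fragment is used at most once;
    the count is the number of steps taken.  Order of the input list is
    irrelevant.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    remaining = sorted(float(m) for m in fragment_mzs)
    current = float(precursor_mz)
    count = 0
    while remaining:
        target = current - ACETYL_STEP
        deltas = [abs(m - target) for m in remaining]
        best = int(np.argmin(deltas))
        if deltas[best] > tol:
            break
        current = remaining.pop(best)
        count += 1
    return count


def assign_headgroup(
    fragment_mzs: Sequence[float],
    residual_table: Optional[Dict[Tuple[str, int], float]] = None,
    tol: float = 0.02,
) -> Optional[ResidualIonMatch]:
    """Identify the residual acetylated-polyol ion among the fragments.

    Returns the (polyol, acetyl count) whose predicted sodiated residual
    ion lies within *tol* of an observed fragment, breaking ties by the
    smallest absolute m/z error; ``None`` when nothing matches.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if residual_table is None:
        residual_table = residual_ion_table()
    best: Optional[ResidualIonMatch] = None
    for (polyol, n_acetyl), predicted in sorted(residual_table.items()):
        for observed in fragment_mzs:
            delta = abs(float(observed) - predicted)
            if delta <= tol and (best is None or delta < abs(best.delta)):
                best = ResidualIonMatch(polyol, n_acetyl, float(observed), predicted)
    return best


def annotate_feature(
    spectrum: FragmentSpectrum,
    library: Sequence[LibraryEntry],
    precursor_tol: float = 0.02,
    fragment_tol: float = 0.02,
    adduct_name: str = "M+Na",
    residual_table: Optional[Dict[Tuple[str, int], float]] = None,
) -> Annotation:
    """Annotate one feature spectrum against a theoretical PEFA library.

    Candidates are library species whose precursor m/z matches within
    ``precursor_tol``; fragment evidence (acetyl ladder, residual-polyol
    ion) is then required to be structurally consistent: the ladder
    cannot exceed the candidate's total acetyl count, and a residual-ion
    hit must agree with the candidate's head group and polyol
    acetylation degree.  Ties break by smallest precursor error, then by
    fewest acetyl groups.
    """
    if precursor_tol <= 0 or fragment_tol <= 0:
        raise ValueError("tolerances must be positive")
    if not library:
        raise ValueError("empty library")

    ladder = count_acetyl_ladder(spectrum.precursor_mz, spectrum.mz, fragment_tol)
    residual = assign_headgroup(spectrum.mz, residual_table, fragment_tol)

    candidates: List[Tuple[float, int, LibraryEntry]] = []
    for entry in library:
        predicted = entry.precursor_mz.get(adduct_name)
        if predicted is None:
            continue
        delta = spectrum.precursor_mz - predicted
        if abs(delta) > precursor_tol:
            continue
        s = entry.species
        if ladder > s.total_acetyl_count:
            continue
        if residual is not None and (
            residual.polyol != s.polyol
            or residual.acetyl_count != s.polyol_acetyl_count
        ):
            continue
        candidates.append((abs(delta), s.total_acetyl_count, entry))

    if not candidates:
        return Annotation(
            feature_id=spectrum.feature_id,
            matched_species=None,
            precursor_error_ppm=None,
            ladder_count=ladder,
            residual_ion_match=residual,
            confidence="none",
        )

    candidates.sort(key=lambda c: (c[0], c[1], c[2].species.label()))
    delta_abs, _, best = candidates[0]
    predicted = best.precursor_mz[adduct_name]
    ppm = (spectrum.precursor_mz - predicted) / predicted * 1e6
    confidence = "full" if (ladder >= 1 or residual is not None) else "precursor-only"
    return Annotation(
        feature_id=spectrum.feature_id,
        matched_species=best.species,
        precursor_error_ppm=ppm,
        ladder_count=ladder,
        residual_ion_match=residual,
        confidence=confidence,
    )


def annotate_all(
    spectra: Sequence[FragmentSpectrum],
    library: Sequence[LibraryEntry],
    precursor_tol: float = 0.02,
    fragment_tol: float = 0.02,
    adduct_name: str = "M+Na",
) -> List[Annotation]:
    """Annotate a collection of spectra (shared residual-ion table)."""
    table = residual_ion_table()
    return [
        annotate_feature(
            s, library, precursor_tol, fragment_tol, adduct_name, residual_table=table
        )
        for s in spectra
    ]


def annotations_to_frame(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """One row per feature with all evidence columns, for report export."""
    rows = []
    for a in annotations:
        s = a.matched_species
        r = a.residual_ion_match
        rows.append(
            {
                "feature_id": a.feature_id,
                "annotation": s.label() if s else "",
                "polyol": s.polyol if s else "",
                "polyol_acetyl_count": s.polyol_acetyl_count if s else pd.NA,
                "chain_length": s.chain_length if s else pd.NA,
                "c3_substituent": s.c3_substituent if s else "",
                "precursor_error_ppm": a.precursor_error_ppm,
                "ladder_count": a.ladder_count,
                "residual_ion_polyol": r.polyol if r else "",
                "residual_ion_acetyls": r.acetyl_count if r else pd.NA,
                "residual_ion_observed_mz": r.observed_mz if r else pd.NA,
                "residual_ion_delta_mda": r.delta * 1000 if r else pd.NA,
                "confidence": a.confidence,
            }
        )
    return pd.DataFrame(rows)
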