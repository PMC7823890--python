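"""Group-origin analysis of network nodes across culture conditions.

Answers the comparative-metabolomics questions: which growth medium or
solvent subextract did each feature come from, which features are
unique to a condition and which are shared, and how each molecular
family decomposes into unique/shared member counts.  Features detected
in blank (solvent/medium) samples are removed up front.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set

import pandas as pd

from .networking import MolecularFamily

__all__ = [
    "presence_matrix",
    "subtract_blanks",
    "node_group_origin",
    "cluster_composition",
]


def presence_matrix(q: pd.DataFrame, min_area: float = 0.0) -> pd.DataFrame:
    """Boolean feature x sample detection matrix: present <=> area > min_area."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    return q > min_area


def subtract_blanks(
    q: pd.DataFrame, blank_samples: Sequence[str], min_area: float = 0.0
) -> pd.DataFrame:
    """Drop features detected in any designated blank sample.

    Mirrors the usual preprocessing step of removing solvent/medium
    contaminant ions before comparative analysis; returns the table
    restricted to the surviving features, with blank columns removed.
    """
    blanks = [b for b in blank_samples if b in q.columns]
    if blanks:
        contaminant = (q[blanks] > min_area).any(axis=1)
        q = q.loc[~contaminant]
    return q.drop(columns=blanks)


def node_group_origin(
    presence: pd.DataFrame, metadata: pd.DataFrame, group_key: str
) -> Dict[str, Set[str]]:
    """Per-feature set of group labels where the feature is detected.

    ``metadata`` is indexed by sample id with one column per grouping
    variable (e.g. medium, subextract); a feature's origin set contains
    every label of ``group_key`` that has at least one sample where the
    feature is present.
    """
    if group_key not in metadata.columns:
        raise KeyError(f"unknown group key: {group_key!r}")
    missing = [s for s in presence.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    labels = metadata.loc[list(presence.columns), group_key]
    origins: Dict[str, Set[str]] = {}
    for feature_id, row in presence.iterrows():
        origins[str(feature_id)] = set(labels[row.to_numpy(dtype=bool)].unique())
    return origins


@dataclass(frozen=True)
class FamilyComposition:
    family_id: int
    total: int
    unique_counts: Dict[str, int]  # label -> nodes found only in that group
    shared: int  # nodes detected in more than one group
    undetected: int  # nodes with an empty origin set

    def as_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {
            "family_id": self.family_id,
            "total": self.total,
            "shared": self.shared,
            "undetected": self.undetected,
        }
        for label, n in sorted(self.unique_counts.items()):
            row[f"unique_{label}"] = n
        return row


def cluster_composition(
    families: Sequence[MolecularFamily], origins: Dict[str, Set[str]]
) -> pd.DataFrame:
    """Unique/shared node counts per molecular family.

    Every family node must have an origin entry.  Per family the
    single-label nodes are counted per group, multi-label nodes as
    shared, and empty-origin nodes as undetected; the counts always sum
    to the family size.
    """
    rows = []
    for fam in sorted(families, key=lambda f: f.family_id):
        missing = [n for n in fam.node_ids if n not in origins]
        if missing:
            raise ValueError(f"origins missing for nodes: {sorted(missing)}")
        unique: Dict[str, int] = {}
        shared = 0
        undetected = 0
        for node in fam.node_ids:
            labels = origins[node]
            if len(labels) == 0:
                undetected += 1
            elif len(labels) == 1:
                label = next(iter(labels))
                unique[label] = unique.get(label, 0) + 1
            else:
                shared += 1
        rows.append(
            FamilyComposition(fam.family_id, len(fam.node_ids), unique, shared, undetected).as_row()
        )
    return pd.DataFrame(rows).fillna(0) if rows else pd.DataFrame(
        columns=["family_id", "total", "shared", "undetected"]
    )
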