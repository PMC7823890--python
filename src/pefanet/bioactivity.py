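"""Bioactive molecular networking: correlating feature abundance with assays.

The quantification table (features x samples, chromatographic peak
areas) is scaled by total-ion-current (TIC) normalisation — every
sample's areas divided by that sample's total — and each feature's
normalised abundance across fractions is then Pearson-correlated with
the fractions' bioactivity level (e.g. % inhibition of a cancer cell
line).  Features whose abundance tracks activity (r above a strict
threshold, default 0.5) are flagged as candidate bioactive compounds
and the scores attached to the molecular network as node attributes,
where they are conventionally rendered as node sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .networking import MolecularNetwork

__all__ = [
    "BioactivityScore",
    "validate_quant_table",
    "tic_normalize",
    "bioactivity_scores",
    "flag_bioactive",
    "attach_scores_to_network",
    "scores_to_frame",
]


@dataclass
class BioactivityScore:
    """Per-feature correlation with the bioactivity profile.

    ``r`` is ``None`` when the correlation is undefined (zero variance
    across the shared samples); ``reason`` says why a feature was
    excluded from scoring.
    """

    feature_id: str
    r: Optional[float]
    n_samples_used: int
    flagged: bool = False
    reason: str = ""


def validate_quant_table(q: pd.DataFrame) -> pd.DataFrame:
    """Check quant-table invariants: unique ids, non-negative areas."""
    if q.index.duplicated().any():
        raise ValueError("duplicate feature ids in quant table")
    if q.columns.duplicated().any():
        raise ValueError("duplicate sample ids in quant table")
    if (q.values < 0).any():
        raise ValueError("negative peak area in quant table")
    return q


def tic_normalize(q: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample (column) by its total area.

    After normalisation every column sums to 1; a sample with zero
    total area is an error.  Idempotent up to floating point on
    already-normalised tables.
    """
    validate_quant_table(q)
    totals = q.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total area: {list(zero.index)}")
    return q / totals


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom)


def bioactivity_scores(
    q: pd.DataFrame,
    activity: pd.Series,
    min_samples: int = 3,
) -> List[BioactivityScore]:
    """Pearson correlation of each feature's areas with the activity level.

    Only samples present in both the quant table and the activity
    profile are used (at least ``min_samples`` required).  Zeros are
    data: a feature absent from a fraction contributes area 0.
    Features with zero variance across the shared samples are excluded
    with a recorded reason rather than given an arbitrary score.
    """
    shared = [s for s in q.columns if s in activity.index]
    if len(shared) < min_samples:
        raise ValueError(
            f"only {len(shared)} samples shared between quant table and "
            f"bioactivity profile; need >= {min_samples}"
        )
    y = activity.loc[shared].to_numpy(dtype=float)
    y_constant = np.ptp(y) == 0
    scores: List[BioactivityScore] = []
    for feature_id, row in q.loc[:, shared].iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            scores.append(
                BioactivityScore(str(feature_id), None, len(shared), reason="zero variance")
            )
        elif y_constant:
            scores.append(
                BioactivityScore(
                    str(feature_id), None, len(shared), reason="constant activity"
                )
            )
        else:
            scores.append(
                BioactivityScore(str(feature_id), _pearson(x, y), len(shared))
            )
    return scores


def flag_bioactive(
    scores: Sequence[BioactivityScore], threshold: float = 0.5
) -> List[BioactivityScore]:
    """Flag features with r strictly greater than *threshold*."""
    for s in scores:
        s.flagged = s.r is not None and s.r > threshold
    return list(scores)


def attach_scores_to_network(
    network: MolecularNetwork, scores: Sequence[BioactivityScore]
) -> MolecularNetwork:
    """Write r and the bioactive flag onto network nodes.

    Nodes without a score are annotated as missing so downstream
    viewers can distinguish 'not scored' from 'not bioactive'.
    """
    by_id = {s.feature_id: s for s in scores}
    for node in network.node_ids:
        s = by_id.get(node)
        if s is None or s.r is None:
            network.set_attribute(node, "bioactivity_r", None)
            network.set_attribute(node, "bioactive", False)
            network.set_attribute(node, "bioactivity_missing", True)
        else:
            network.set_attribute(node, "bioactivity_r", s.r)
            network.set_attribute(node, "bioactive", s.flagged)
            network.set_attribute(node, "bioactivity_missing", False)
    return network


def scores_to_frame(scores: Sequence[BioactivityScore]) -> pd.DataFrame:
    """Node-attribute table (id, r, flagged) for viewer import."""
    return pd.DataFrame(
        [
            {
                "feature_id": s.feature_id,
                "r": np.nan if s.r is None else s.r,
                "n_samples_used": s.n_samples_used,
                "flagged": s.flagged,
                "reason": s.reason,
            }
            for s in scores
        ],
        columns=["feature_id", "r", "n_samples_used", "flagged", "reason"],
    )
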