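"""Feature-based molecular networking.

Spectra are cleaned (precursor-window exclusion, top-K-per-window peak
filtering), compared all-vs-all with the modified cosine — a cosine
similarity whose peak matching also admits pairs offset by the two
precursors' mass difference, so that structural analogs differing by one
substituent still align — and assembled into a graph.  Edges must pass a
score and matched-peak threshold and a mutual top-K rule, and connected
components ("molecular families") are capped by removing their weakest
edges.  Defaults follow common feature-based molecular networking
practice: cosine > 0.7, >= 6 matched peaks, top 10 neighbours, family
cap 100.

Peak matching is solved as an exact maximum-weight one-to-one assignment
over the candidate pairs (Hungarian algorithm); spectra here carry at
most a few dozen peaks after filtering, so exactness costs nothing and
keeps the score well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .spectra import FragmentSpectrum

__all__ = [
    "NetworkEdge",
    "MolecularFamily",
    "MolecularNetwork",
    "LibraryHit",
    "filter_spectrum",
    "modified_cosine",
    "build_network",
    "library_search",
]


@dataclass(frozen=True)
class NetworkEdge:
    """A scored similarity edge between two features (ids sorted)."""

    node_a: str
    node_b: str
    cosine: float
    matched_peaks: int
    mass_shift: float  # precursor(node_a) - precursor(node_b)

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError("self-edges are not allowed")
        if not -1e-9 <= self.cosine <= 1 + 1e-9:
            raise ValueError(f"cosine out of range: {self.cosine}")

    @property
    def key(self) -> Tuple[str, str]:
        return (self.node_a, self.node_b)


@dataclass(frozen=True)
class MolecularFamily:
    """A connected component of size >= 2."""

    family_id: int
    node_ids: FrozenSet[str]


@dataclass
class MolecularNetwork:
    """Nodes, scored edges, families and per-node attributes."""

    edges: List[NetworkEdge]
    families: List[MolecularFamily]
    singletons: List[str]
    node_attributes: Dict[str, Dict[str, object]] = field(default_factory=dict)

    @property
    def node_ids(self) -> List[str]:
        ids = {n for f in self.families for n in f.node_ids}
        ids.update(self.singletons)
        return sorted(ids)

    def family_of(self, node_id: str) -> Optional[int]:
        for fam in self.families:
            if node_id in fam.node_ids:
                return fam.family_id
        return None

    def set_attribute(self, node_id: str, key: str, value: object) -> None:
        self.node_attributes.setdefault(node_id, {})[key] = value

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for e in self.edges:
            g.add_edge(
                e.node_a,
                e.node_b,
                cosine=e.cosine,
                matched_peaks=e.matched_peaks,
                mass_shift=e.mass_shift,
            )
        for fam in self.families:
            for n in fam.node_ids:
                g.nodes[n]["family"] = fam.family_id
        for n in self.singletons:
            g.nodes[n]["family"] = -1
        for node, attrs in self.node_attributes.items():
            if node in g:
                for k, v in attrs.items():
                    if v is not None:
                        g.nodes[node][k] = v
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def edges_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "node_a": e.node_a,
                    "node_b": e.node_b,
                    "cosine": e.cosine,
                    "matched_peaks": e.matched_peaks,
                    "mass_shift": e.mass_shift,
                }
                for e in self.edges
            ],
            columns=["node_a", "node_b", "cosine", "matched_peaks", "mass_shift"],
        )

    def nodes_to_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.node_ids:
            row = {"feature_id": n, "family": self.family_of(n) if self.family_of(n) is not None else -1}
            row.update(self.node_attributes.get(n, {}))
            rows.append(row)
        return pd.DataFrame(rows)


def filter_spectrum(
    s: FragmentSpectrum,
    precursor_exclusion: float = 17.0,
    window: float = 50.0,
    top_k: int = 6,
) -> FragmentSpectrum:
    """Clean one spectrum before similarity scoring.

    Removes every fragment within ``precursor_exclusion`` Da of the
    precursor m/z, then keeps a peak only if it ranks among the
    ``top_k`` most intense peaks inside the ±``window`` Da interval
    centred on its own m/z (ties broken toward the lower-m/z peak).
    """
    if precursor_exclusion <= 0 or window <= 0 or top_k <= 0:
        raise ValueError("filter parameters must be positive")
    mz, inten = s.mz, s.intensity
    keep_mask = np.abs(mz - s.precursor_mz) > precursor_exclusion
    mz, inten = mz[keep_mask], inten[keep_mask]

    keep = np.zeros(mz.size, dtype=bool)
    for i in range(mz.size):
        in_window = np.abs(mz - mz[i]) <= window
        # rank within window: higher intensity first, lower m/z wins ties
        better = (inten[in_window] > inten[i]) | (
            (inten[in_window] == inten[i]) & (mz[in_window] < mz[i])
        )
        keep[i] = int(better.sum()) < top_k
    return FragmentSpectrum(
        feature_id=s.feature_id,
        precursor_mz=s.precursor_mz,
        charge=s.charge,
        retention_time=s.retention_time,
        mz=mz[keep],
        intensity=inten[keep],
        title=s.title,
    )


def _candidate_mask(a: FragmentSpectrum, b: FragmentSpectrum, tol: float) -> np.ndarray:
    diff = a.mz[:, None] - b.mz[None, :]
    shift = a.precursor_mz - b.precursor_mz
    return (np.abs(diff) <= tol) | (np.abs(diff - shift) <= tol)


def modified_cosine(
    a: FragmentSpectrum, b: FragmentSpectrum, fragment_tol: float = 0.02
) -> Tuple[float, int]:
    """Modified cosine similarity between two spectra.

    Peak weights are square-root intensities, Euclidean-normalised per
    spectrum.  A peak pair is a match candidate when the m/z values
    agree directly within ``fragment_tol`` or when their difference
    agrees with the precursor mass difference; the score is the maximum
    total weight product over one-to-one assignments of candidate
    pairs.  Returns ``(score, matched_pair_count)``; empty spectra give
    ``(0.0, 0)``.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0, 0
    wa = np.sqrt(a.intensity)
    wb = np.sqrt(b.intensity)
    norm_a = np.linalg.norm(wa)
    norm_b = np.linalg.norm(wb)
    if norm_a == 0 or norm_b == 0:
        return 0.0, 0
    wa, wb = wa / norm_a, wb / norm_b

    mask = _candidate_mask(a, b, fragment_tol)
    if not mask.any():
        return 0.0, 0
    scores = np.where(mask, wa[:, None] * wb[None, :], 0.0)
    rows, cols = linear_sum_assignment(scores, maximize=True)
    assigned = mask[rows, cols]
    score = float(scores[rows, cols].sum())
    return min(score, 1.0), int(assigned.sum())


def _mutual_top_k(edges: List[NetworkEdge], top_k: int) -> List[NetworkEdge]:
    """Keep an edge only if each endpoint ranks it within the other's top K."""
    by_node: Dict[str, List[NetworkEdge]] = {}
    for e in edges:
        by_node.setdefault(e.node_a, []).append(e)
        by_node.setdefault(e.node_b, []).append(e)
    top: Dict[str, set] = {}
    for node, incident in by_node.items():
        incident.sort(key=lambda e: (-e.cosine, e.key))
        top[node] = {e.key for e in incident[:top_k]}
    return [e for e in edges if e.key in top[e.node_a] and e.key in top[e.node_b]]


def _cap_families(
    graph: nx.Graph, edges: Dict[Tuple[str, str], NetworkEdge], cap: int
) -> None:
    """Remove lowest-cosine edges from oversized components until all fit."""
    while True:
        oversized = [c for c in nx.connected_components(graph) if len(c) > cap]
        if not oversized:
            return
        component = oversized[0]
        component_edges = [
            edges[tuple(sorted((u, v)))] for u, v in graph.subgraph(component).edges
        ]
        worst = min(component_edges, key=lambda e: (e.cosine, e.key))
        graph.remove_edge(worst.node_a, worst.node_b)
        del edges[worst.key]


def build_network(
    spectra: Sequence[FragmentSpectrum],
    cosine_min: float = 0.7,
    min_matched: int = 6,
    top_k: int = 10,
    max_family_size: int = 100,
    fragment_tol: float = 0.02,
    prefilter: bool = True,
) -> MolecularNetwork:
    """Construct the molecular network from feature spectra.

    Steps: (1) optional spectrum cleaning, (2) all-pairs modified
    cosine, (3) threshold on score and matched peaks, (4) mutual top-K
    pruning, (5) family-size capping by discarding the lowest-scoring
    edges of oversized components (ties: lexicographically smallest node
    pair first).  Components of size >= 2 become molecular families.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    ids = [s.feature_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids")
    prepared = [filter_spectrum(s) if prefilter else s for s in spectra]

    edges: List[NetworkEdge] = []
    for i in range(len(prepared)):
        for j in range(i + 1, len(prepared)):
            a, b = prepared[i], prepared[j]
            score, matched = modified_cosine(a, b, fragment_tol)
            if score > cosine_min and matched >= min_matched:
                na, nb = sorted((a.feature_id, b.feature_id))
                prec = {a.feature_id: a.precursor_mz, b.feature_id: b.precursor_mz}
                edges.append(
                    NetworkEdge(na, nb, score, matched, prec[na] - prec[nb])
                )

    edges = _mutual_top_k(edges, top_k)

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    edge_map = {e.key: e for e in edges}
    for e in edges:
        graph.add_edge(e.node_a, e.node_b)
    _cap_families(graph, edge_map, max_family_size)

    kept_edges = sorted(edge_map.values(), key=lambda e: e.key)
    families: List[MolecularFamily] = []
    singletons: List[str] = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    fam_id = 0
    for component in components:
        if len(component) >= 2:
            families.append(MolecularFamily(fam_id, frozenset(component)))
            fam_id += 1
        else:
            singletons.extend(component)
    return MolecularNetwork(kept_edges, families, sorted(singletons))


@dataclass(frozen=True)
class LibraryHit:
    """A reference-library match for a query spectrum."""

    reference_id: str
    score: float
    matched_peaks: int
    reference_title: Optional[str] = None


def library_search(
    query: FragmentSpectrum,
    reference: Sequence[FragmentSpectrum],
    score_min: float = 0.7,
    min_matched: int = 6,
    fragment_tol: float = 0.02,
    prefilter: bool = True,
) -> List[LibraryHit]:
    """Match one query spectrum against an annotated reference library.

    Reference spectra are filtered in the same manner as the input
    data; hits must exceed the score threshold and reach the matched-
    peak minimum, and are returned ranked by descending score.
    """
    if not reference:
        raise ValueError("reference library is empty")
    q = filter_spectrum(query) if prefilter else query
    hits: List[LibraryHit] = []
    for ref in reference:
        r = filter_spectrum(ref) if prefilter else ref
        score, matched = modified_cosine(q, r, fragment_tol)
        if score > score_min and matched >= min_matched:
            hits.append(LibraryHit(ref.feature_id, score, matched, ref.title))
    hits.sort(key=lambda h: (-h.score, h.reference_id))
    return hits
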