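"""End-to-end workflows binding the analysis stages together.

Two workflows mirror how such a study is actually run: comparative
networking (network + group-origin analysis of the crude subextracts)
and bioactive networking (network + annotation + bioactivity scoring of
a fraction series).  :func:`run_pipeline` executes whichever stages the
provided inputs support, writes all result tables, and records a run
manifest (configuration hash, package version) so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_all, annotations_to_frame
from .bioactivity import (
    attach_scores_to_network,
    bioactivity_scores,
    flag_bioactive,
    scores_to_frame,
    tic_normalize,
    validate_quant_table,
)
from .comparative import (
    cluster_composition,
    node_group_origin,
    presence_matrix,
    subtract_blanks,
)
from .library import LibraryConfig, enumerate_library
from .networking import build_network
from .spectra import read_mgf

logger = logging.getLogger("pefanet")

__all__ = ["PipelineConfig", "run_pipeline", "load_quant_table", "load_metadata", "load_bioactivity"]


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, with field-standard defaults.

    The defaults are the parameters of a typical feature-based
    molecular networking run on high-resolution QToF data: 0.02 Da
    precursor and fragment tolerances, cosine > 0.7 with >= 6 matched
    peaks, mutual top-10 neighbours, family cap 100, ±17 Da precursor
    exclusion, top-6 peaks per ±50 Da window, and a Pearson r > 0.5
    bioactivity flag.
    """

    mgf: Optional[str] = None
    quant: Optional[str] = None
    metadata: Optional[str] = None
    bioactivity: Optional[str] = None
    outdir: str = "pefanet_results"

    precursor_tol: float = 0.02
    fragment_tol: float = 0.02
    cosine_min: float = 0.7
    min_matched: int = 6
    top_k: int = 10
    max_family_size: int = 100
    precursor_exclusion: float = 17.0
    window: float = 50.0
    window_top_k: int = 6
    r_threshold: float = 0.5
    min_samples: int = 3
    min_area: float = 0.0
    group_key: str = "medium"
    adduct_convention: str = "ion-mass"
    assay: Optional[str] = None  # bioactivity column; default: first

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_quant_table(path) -> pd.DataFrame:
    q = pd.read_csv(path, sep="\t", index_col=0)
    q.index = q.index.map(str)
    return validate_quant_table(q)


def load_metadata(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.map(str)
    return m


def load_bioactivity(path, assay: Optional[str] = None) -> pd.Series:
    b = pd.read_csv(path, sep="\t", index_col=0)
    b.index = b.index.map(str)
    column = assay if assay is not None else b.columns[0]
    if column not in b.columns:
        raise ValueError(f"assay column {column!r} not in bioactivity table")
    return b[column].astype(float)


def _check_samples(quant: pd.DataFrame, metadata: Optional[pd.DataFrame]) -> None:
    if metadata is None:
        return
    missing = [s for s in quant.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"quant-table sample(s) missing from metadata: {missing}")


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Run every stage the configured inputs support; write all outputs.

    Returns a results bundle with the in-memory objects and the paths
    written.  Deterministic for fixed inputs and configuration.
    """
    if not cfg.mgf:
        raise ValueError("an MGF of feature spectra is required")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    spectra = read_mgf(cfg.mgf)
    logger.info("read %d spectra from %s", len(spectra), cfg.mgf)
    quant = load_quant_table(cfg.quant) if cfg.quant else None
    metadata = load_metadata(cfg.metadata) if cfg.metadata else None
    if quant is not None:
        _check_samples(quant, metadata)

    # blank subtraction when metadata designates blanks
    if quant is not None and metadata is not None and "is_blank" in metadata.columns:
        blank_samples = [str(s) for s in metadata.index[metadata["is_blank"].astype(bool)]]
        before = len(quant)
        quant = subtract_blanks(quant, blank_samples, cfg.min_area)
        logger.info("blank subtraction: %d -> %d features", before, len(quant))
        spectra = [s for s in spectra if s.feature_id in set(quant.index)]

    network = build_network(
        spectra,
        cosine_min=cfg.cosine_min,
        min_matched=cfg.min_matched,
        top_k=cfg.top_k,
        max_family_size=cfg.max_family_size,
        fragment_tol=cfg.fragment_tol,
    )
    logger.info(
        "network: %d edges, %d families, %d singletons",
        len(network.edges), len(network.families), len(network.singletons),
    )

    library = enumerate_library(LibraryConfig())
    annotations = annotate_all(
        spectra, library, cfg.precursor_tol, cfg.fragment_tol
    )
    for a in annotations:
        if a.matched_species is not None:
            network.set_attribute(a.feature_id, "annotation", a.matched_species.label())
            network.set_attribute(a.feature_id, "annotation_confidence", a.confidence)
    n_pefa = sum(a.matched_species is not None for a in annotations)
    logger.info("annotation: %d/%d features matched a PEFA", n_pefa, len(annotations))

    results: Dict[str, object] = {
        "network": network,
        "annotations": annotations,
        "scores": None,
        "composition": None,
    }

    if quant is not None and cfg.bioactivity:
        activity = load_bioactivity(cfg.bioactivity, cfg.assay)
        normalized = tic_normalize(quant)
        scores = flag_bioactive(
            bioactivity_scores(normalized, activity, cfg.min_samples), cfg.r_threshold
        )
        attach_scores_to_network(network, scores)
        results["scores"] = scores
        logger.info("bioactivity: %d features flagged at r > %g",
                    sum(s.flagged for s in scores), cfg.r_threshold)
        scores_to_frame(scores).to_csv(outdir / "bioactivity_scores.tsv", sep="\t", index=False)

    if quant is not None and metadata is not None and cfg.group_key in metadata.columns:
        presence = presence_matrix(quant, cfg.min_area)
        origins = node_group_origin(
            presence, metadata.loc[[s for s in quant.columns]], cfg.group_key
        )
        for fid, labels in origins.items():
            network.set_attribute(fid, "origin", "|".join(sorted(labels)))
        composition = cluster_composition(network.families, {
            n: origins.get(n, set()) for f in network.families for n in f.node_ids
        })
        composition.to_csv(outdir / "family_composition.tsv", sep="\t", index=False)
        results["composition"] = composition

    annotations_to_frame(annotations).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    network.edges_to_frame().to_csv(outdir / "edges.tsv", sep="\t", index=False)
    network.nodes_to_frame().to_csv(outdir / "nodes.tsv", sep="\t", index=False)
    network.write_graphml(outdir / "network.graphml")

    manifest = {
        "pefanet_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "n_spectra": len(spectra),
        "n_edges": len(network.edges),
        "n_families": len(network.families),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["outdir"] = outdir
    return results
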