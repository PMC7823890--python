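"""Seeded generator of complete synthetic PEFA metabolomics experiments.

Produces everything the analysis pipeline consumes — an MGF of MS/MS
spectra, a feature quantification table, sample metadata, a bioactivity
table — together with a ground-truth manifest, so that every stage
(networking, annotation, bioactivity scoring, comparative analysis) can
be validated without any external download.

What is emulated
----------------
* PEFA feature spectra: sodiated precursor at the species' exact adduct
  mass, the sequential 60.0211 Da acetic-acid-loss ladder, the residual
  acetylated-polyol fragment and its sub-ladder, Gaussian m/z jitter,
  and uniform-random noise peaks.
* Decoy features: random precursors kept away from every theoretical
  PEFA mass, with unstructured random peak lists.
* Abundance: each feature elutes in a contiguous block of fractions
  with log-normal peak areas (a chromatography analog); a designated
  bioactive subset instead follows the bioactivity profile (area
  proportional to activity plus Gaussian noise), so its Pearson
  correlation with activity is high by construction.
* Blanks: a designated contaminant subset of the decoys appears in the
  blank samples (and across fractions), ready for blank subtraction.

Everything is deterministic given the master seed: each output stream
draws from its own child generator spawned from the seed, and files are
written with fixed numeric formatting, so identical configurations give
byte-identical files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .library import (
    LibraryConfig,
    LibraryEntry,
    PefaSpecies,
    enumerate_library,
    predict_fragments,
)
from .masses import AdductSpec
from .spectra import FragmentSpectrum, write_mgf

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "default_activity_profile",
    "make_pefa_spectrum",
    "generate_dataset",
    "write_reference_library",
]


def default_activity_profile(n_fractions: int = 31) -> np.ndarray:
    """Bioactivity (% inhibition) across fractions: a late active block.

    Low baseline everywhere with a ramp over four consecutive fractions
    near the end (the classic pattern of non-polar bioactive fractions
    in a reversed-phase fractionation).
    """
    profile = np.full(n_fractions, 2.0)
    block = [40.0, 75.0, 90.0, 60.0]
    start = max(0, min(n_fractions - len(block), int(n_fractions * 0.65)))
    profile[start : start + len(block)] = block[: n_fractions - start]
    return profile


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic experiment.

    Defaults model a realistic QToF acquisition over a 31-fraction
    separation: ~5 mDa mass jitter, a handful of low-level noise peaks
    per spectrum, and 22 truly activity-driven features.
    """

    seed: int = 0
    n_pefa_species: int = 40
    n_decoy_features: int = 20
    n_fractions: int = 31
    n_blanks: int = 2
    mz_jitter_sd: float = 0.005
    noise_peaks_per_spectrum: int = 5
    noise_intensity_frac: float = 0.05
    bioactive_fraction_profile: Optional[np.ndarray] = None
    bioactive_feature_count: int = 22
    bioactive_noise_sd: float = 0.05
    contaminant_fraction: float = 0.3  # share of decoys present in blanks
    library_config: LibraryConfig = field(default_factory=LibraryConfig)

    def activity(self) -> np.ndarray:
        if self.bioactive_fraction_profile is not None:
            profile = np.asarray(self.bioactive_fraction_profile, dtype=float)
            if profile.size != self.n_fractions:
                raise ValueError("bioactive_fraction_profile length != n_fractions")
            return profile
        return default_activity_profile(self.n_fractions)

    def validate(self, library_size: int) -> None:
        for name in (
            "n_pefa_species",
            "n_decoy_features",
            "n_fractions",
            "n_blanks",
            "noise_peaks_per_spectrum",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mz_jitter_sd < 0 or self.noise_intensity_frac < 0 or self.bioactive_noise_sd < 0:
            raise ValueError("jitter and noise parameters must be >= 0")
        if self.n_pefa_species > library_size:
            raise ValueError(
                f"n_pefa_species={self.n_pefa_species} exceeds library size {library_size}"
            )
        if self.bioactive_feature_count > self.n_pefa_species:
            raise ValueError(
                "bioactive_feature_count exceeds the number of PEFA features"
            )


@dataclass
class SyntheticDataset:
    """All outputs of one synthetic experiment plus the ground truth."""

    spectra: List[FragmentSpectrum]
    quant: pd.DataFrame  # features x samples
    metadata: pd.DataFrame  # indexed by sample id
    bioactivity: pd.Series  # sample -> activity level
    manifest: Dict[str, object]

    def write(self, outdir) -> Dict[str, Path]:
        """Write all files (MGF, TSVs, manifest JSON) deterministically."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mgf": outdir / "spectra.mgf",
            "quant": outdir / "quant.tsv",
            "metadata": outdir / "metadata.tsv",
            "bioactivity": outdir / "bioactivity.tsv",
            "manifest": outdir / "manifest.json",
        }
        write_mgf(self.spectra, paths["mgf"])
        self.quant.round(4).to_csv(paths["quant"], sep="\t", index_label="feature_id")
        self.metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
        self.bioactivity.round(4).to_frame("activity").to_csv(
            paths["bioactivity"], sep="\t", index_label="sample_id"
        )
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return paths


def make_pefa_spectrum(
    species: PefaSpecies,
    feature_id: str,
    rng: Optional[np.random.Generator] = None,
    mz_jitter_sd: float = 0.0,
    noise_peaks: int = 0,
    noise_intensity_frac: float = 0.05,
    adduct: AdductSpec = AdductSpec("M+Na"),
    retention_time: float = 0.0,
) -> FragmentSpectrum:
    """Simulate the MS/MS spectrum of one PEFA species.

    The residual-polyol ion and the first acetyl loss are the base
    peaks (their diagnostic prominence is what makes the rule-based
    identification work); other fragments get log-uniform relative
    intensities in [0.1, 1].  The intensity profile is a deterministic
    property of the species (derived from its descriptor), the way a
    compound's fragmentation pattern is reproducible on an instrument;
    the passed generator only drives m/z jitter and noise peaks.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    predictions = predict_fragments(species, adduct)
    from .masses import adduct_mz
    from .library import species_formula

    intensity_rng = np.random.default_rng(zlib.crc32(species.label().encode()))
    precursor = adduct_mz(species_formula(species), adduct)
    mzs: List[float] = []
    intensities: List[float] = []
    for p in predictions:
        if p.rationale in ("fatty-acid loss", "acetyl-loss x1"):
            inten = 1.0
        else:
            inten = float(np.exp(intensity_rng.uniform(np.log(0.1), np.log(1.0))))
        mzs.append(p.mz + (rng.normal(0.0, mz_jitter_sd) if mz_jitter_sd > 0 else 0.0))
        intensities.append(inten)
    for _ in range(noise_peaks):
        mzs.append(float(rng.uniform(80.0, max(100.0, precursor - 20.0))))
        intensities.append(noise_intensity_frac)
    precursor_obs = precursor + (rng.normal(0.0, mz_jitter_sd) if mz_jitter_sd > 0 else 0.0)
    return FragmentSpectrum(
        feature_id=feature_id,
        precursor_mz=precursor_obs,
        charge=1,
        retention_time=retention_time,
        mz=np.array(mzs),
        intensity=np.array(intensities),
        title=f"{feature_id} {species.label()}",
    )


def _decoy_spectrum(
    feature_id: str,
    rng: np.random.Generator,
    library_mzs: np.ndarray,
    retention_time: float,
    n_peaks: int = 8,
) -> FragmentSpectrum:
    while True:
        precursor = float(rng.uniform(300.0, 800.0))
        if np.min(np.abs(library_mzs - precursor)) > 0.05:
            break
    mzs = rng.uniform(80.0, precursor - 20.0, size=n_peaks)
    intensities = rng.uniform(0.1, 1.0, size=n_peaks)
    return FragmentSpectrum(
        feature_id=feature_id,
        precursor_mz=precursor,
        charge=1,
        retention_time=retention_time,
        mz=mzs,
        intensity=intensities,
        title=f"{feature_id} decoy",
    )


def generate_dataset(cfg: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Generate one complete synthetic experiment.

    Deterministic given ``cfg.seed``; see the module docstring for what
    each output emulates.
    """
    library = enumerate_library(cfg.library_config)
    cfg.validate(len(library))
    seq = np.random.SeedSequence(cfg.seed)
    rng_select, rng_spec, rng_quant, rng_rt = [
        np.random.default_rng(s) for s in seq.spawn(4)
    ]

    activity = cfg.activity()
    fractions = [f"F{i + 1:02d}" for i in range(cfg.n_fractions)]
    blanks = [f"B{i + 1:02d}" for i in range(cfg.n_blanks)]
    samples = fractions + blanks

    # --- pick species and feature roles -------------------------------
    chosen_idx = rng_select.choice(len(library), size=cfg.n_pefa_species, replace=False)
    chosen: List[LibraryEntry] = [library[int(i)] for i in chosen_idx]
    pefa_ids = [f"P{i + 1:04d}" for i in range(cfg.n_pefa_species)]
    decoy_ids = [f"D{i + 1:04d}" for i in range(cfg.n_decoy_features)]
    feature_ids = pefa_ids + decoy_ids

    order = rng_select.permutation(len(pefa_ids))
    bioactive_set = {pefa_ids[int(i)] for i in order[: cfg.bioactive_feature_count]}
    n_contam = int(round(cfg.contaminant_fraction * cfg.n_decoy_features))
    contaminant_set = set(decoy_ids[:n_contam])

    # --- spectra ------------------------------------------------------
    library_mzs = np.array([e.precursor("M+Na") for e in library])
    rts = {fid: float(rng_rt.uniform(1.0, 12.0)) for fid in feature_ids}
    spectra: List[FragmentSpectrum] = []
    for fid, entry in zip(pefa_ids, chosen):
        spectra.append(
            make_pefa_spectrum(
                entry.species,
                fid,
                rng=rng_spec,
                mz_jitter_sd=cfg.mz_jitter_sd,
                noise_peaks=cfg.noise_peaks_per_spectrum,
                noise_intensity_frac=cfg.noise_intensity_frac,
                retention_time=rts[fid],
            )
        )
    for fid in decoy_ids:
        spectra.append(_decoy_spectrum(fid, rng_spec, library_mzs, rts[fid]))

    # --- quantification table -----------------------------------------
    quant = pd.DataFrame(0.0, index=feature_ids, columns=samples)
    for fid in feature_ids:
        scale = float(np.exp(rng_quant.normal(np.log(1e5), 0.8)))
        if fid in bioactive_set:
            areas = scale * activity + rng_quant.normal(
                0.0, cfg.bioactive_noise_sd * scale, size=cfg.n_fractions
            )
            quant.loc[fid, fractions] = np.clip(areas, 0.0, None)
        elif fid in contaminant_set:
            quant.loc[fid, samples] = np.exp(
                rng_quant.normal(np.log(scale), 0.5, size=len(samples))
            )
        else:
            width = int(rng_quant.integers(2, 7))
            start = int(rng_quant.integers(0, max(1, cfg.n_fractions - width + 1)))
            window = fractions[start : start + width]
            quant.loc[fid, window] = np.exp(
                rng_quant.normal(np.log(scale), 0.5, size=len(window))
            )

    # --- metadata and bioactivity -------------------------------------
    media = ["PDA" if i < cfg.n_fractions / 2 else "WSP-30" for i in range(cfg.n_fractions)]
    subextracts = [["K-MeOH", "K-DCM", "K-hexane"][i % 3] for i in range(cfg.n_fractions)]
    metadata = pd.DataFrame(
        {
            "medium": media + ["blank"] * cfg.n_blanks,
            "subextract": subextracts + ["blank"] * cfg.n_blanks,
            "is_blank": [False] * cfg.n_fractions + [True] * cfg.n_blanks,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    bioactivity = pd.Series(activity, index=pd.Index(fractions, name="sample_id"), name="activity")

    # --- ground-truth manifest ----------------------------------------
    presence = quant.loc[:, fractions] > 0
    med = metadata.loc[fractions, "medium"]
    features_manifest: Dict[str, Dict[str, object]] = {}
    for fid in feature_ids:
        entry_species = (
            chosen[pefa_ids.index(fid)].species.label() if fid in set(pefa_ids) else None
        )
        origin = sorted(med[presence.loc[fid].to_numpy(dtype=bool)].unique())
        features_manifest[fid] = {
            "kind": "pefa" if fid in set(pefa_ids) else "decoy",
            "species": entry_species,
            "bioactive": fid in bioactive_set,
            "contaminant": fid in contaminant_set,
            "origin_medium": origin,
        }
    manifest: Dict[str, object] = {
        "config": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(cfg).items()
            if k != "library_config"
        },
        "samples": {"fractions": fractions, "blanks": blanks},
        "features": features_manifest,
    }
    return SyntheticDataset(spectra, quant, metadata, bioactivity, manifest)


def write_reference_library(
    species: Sequence[PefaSpecies],
    path,
    adduct: AdductSpec = AdductSpec("M+Na"),
) -> List[FragmentSpectrum]:
    """Write noiseless annotated spectra for a species subset to MGF.

    Each entry's title carries the species label, making the file a
    local spectral reference library for :func:`~pefanet.networking.library_search`.
    """
    if not species:
        raise ValueError("species subset is empty")
    rng = np.random.default_rng(0)
    spectra = [
        make_pefa_spectrum(s, f"REF{i + 1:03d}", rng=rng, adduct=adduct)
        for i, s in enumerate(species)
    ]
    write_mgf(spectra, path)
    return spectra
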