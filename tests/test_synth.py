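"""Synthetic-experiment generator: determinism, consistency, recoverability."""

import numpy as np
import pytest

from pefanet import (
    GeneratorConfig,
    LibraryConfig,
    annotate_all,
    enumerate_library,
    generate_dataset,
    library_search,
    make_pefa_spectrum,
    read_mgf,
    write_reference_library,
)
from pefanet.synth import default_activity_profile


def file_bytes(paths):
    return {name: path.read_bytes() for name, path in paths.items()}


class TestGeneratorConfig:
    def test_infeasible_bioactive_count(self):
        cfg = GeneratorConfig(n_pefa_species=3, n_decoy_features=1, bioactive_feature_count=10)
        with pytest.raises(ValueError, match="bioactive_feature_count"):
            generate_dataset(cfg)

    def test_species_count_capped_by_library(self):
        cfg = GeneratorConfig(n_pefa_species=500)
        with pytest.raises(ValueError, match="library size"):
            generate_dataset(cfg)

    def test_activity_profile_has_active_block(self):
        profile = default_activity_profile(31)
        assert profile.max() == 90.0
        assert (profile == 2.0).sum() > 20


class TestGenerateDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(seed=7, n_pefa_species=10, n_decoy_features=5,
                              bioactive_feature_count=5)
        first = file_bytes(generate_dataset(cfg).write(tmp_path / "a"))
        second = file_bytes(generate_dataset(cfg).write(tmp_path / "b"))
        assert first == second

    def test_different_seed_differs(self, tmp_path):
        base = dict(n_pefa_species=10, n_decoy_features=5, bioactive_feature_count=5)
        a = file_bytes(generate_dataset(GeneratorConfig(seed=1, **base)).write(tmp_path / "a"))
        b = file_bytes(generate_dataset(GeneratorConfig(seed=2, **base)).write(tmp_path / "b"))
        assert a["mgf"] != b["mgf"]

    def test_manifest_covers_every_feature_once(self):
        dataset = generate_dataset(GeneratorConfig(seed=5, n_pefa_species=12, n_decoy_features=6, bioactive_feature_count=6))
        manifest_ids = set(dataset.manifest["features"])
        spectra_ids = {s.feature_id for s in dataset.spectra}
        assert manifest_ids == spectra_ids == set(dataset.quant.index)
        kinds = [v["kind"] for v in dataset.manifest["features"].values()]
        assert kinds.count("pefa") == 12 and kinds.count("decoy") == 6

    def test_mgf_roundtrip(self, tmp_path):
        dataset = generate_dataset(GeneratorConfig(seed=5, n_pefa_species=6, n_decoy_features=2, bioactive_feature_count=3))
        paths = dataset.write(tmp_path)
        back = read_mgf(paths["mgf"])
        assert [s.feature_id for s in back] == [s.feature_id for s in dataset.spectra]
        for orig, rt in zip(dataset.spectra, back):
            assert rt.mz == pytest.approx(orig.mz, abs=1e-5)
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-5)

    def test_noiseless_dataset_fully_annotatable(self, default_library):
        cfg = GeneratorConfig(
            seed=9, n_pefa_species=25, n_decoy_features=10,
            bioactive_feature_count=10,
            mz_jitter_sd=0.0, noise_peaks_per_spectrum=0,
        )
        dataset = generate_dataset(cfg)
        annotations = annotate_all(dataset.spectra, default_library)
        by_id = {a.feature_id: a for a in annotations}
        for feature_id, truth in dataset.manifest["features"].items():
            annotation = by_id[feature_id]
            if truth["kind"] == "pefa":
                assert annotation.matched_species is not None
                assert annotation.matched_species.label() == truth["species"]
                assert annotation.confidence == "full"
            else:
                assert annotation.matched_species is None

    def test_accuracy_degrades_with_jitter(self, default_library):
        """Average annotation accuracy is monotone non-increasing in jitter."""
        accuracies = []
        for jitter in (0.0, 0.01, 0.05):
            correct = total = 0
            for seed in range(5):
                cfg = GeneratorConfig(
                    seed=seed, n_pefa_species=20, n_decoy_features=0,
                    bioactive_feature_count=10,
                    mz_jitter_sd=jitter, noise_peaks_per_spectrum=0,
                )
                dataset = generate_dataset(cfg)
                annotations = annotate_all(dataset.spectra, default_library)
                truth = dataset.manifest["features"]
                for a in annotations:
                    total += 1
                    if (
                        a.matched_species is not None
                        and a.matched_species.label() == truth[a.feature_id]["species"]
                    ):
                        correct += 1
            accuracies.append(correct / total)
        assert accuracies[0] == 1.0
        assert accuracies[0] >= accuracies[1] >= accuracies[2]


class TestReferenceLibrary:
    def test_written_entries_self_match(self, tmp_path):
        # acetyl-rich species give spectra with enough distinct peaks
        species = [
            e.species
            for e in enumerate_library(LibraryConfig())
            if e.species.total_acetyl_count >= 3
        ][:5]
        path = tmp_path / "reference.mgf"
        spectra = write_reference_library(species, path)
        assert len(spectra) == 5
        back = read_mgf(path)
        for orig, rt in zip(spectra, back):
            assert rt.mz == pytest.approx(orig.mz, abs=1e-5)
            hits = library_search(rt, back, prefilter=False, min_matched=min(6, rt.n_peaks))
            assert hits[0].reference_id == orig.feature_id
            assert hits[0].score == pytest.approx(1.0, abs=1e-6)

    def test_species_label_in_title(self, tmp_path):
        species = [e.species for e in enumerate_library(LibraryConfig())[:2]]
        write_reference_library(species, tmp_path / "ref.mgf")
        back = read_mgf(tmp_path / "ref.mgf")
        assert species[0].label() in back[0].title

    def test_empty_subset_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_reference_library([], tmp_path / "ref.mgf")

    def test_jittered_copy_finds_own_species(self, tmp_path):
        rng = np.random.default_rng(21)
        entries = enumerate_library(LibraryConfig())
        # pick well-fragmented species (many acetyls -> many peaks)
        species = [e.species for e in entries if e.species.total_acetyl_count >= 4][:8]
        reference = write_reference_library(species, tmp_path / "ref.mgf")
        for i, s in enumerate(species):
            query = make_pefa_spectrum(
                s, "q", rng=rng, mz_jitter_sd=0.005, noise_peaks=2
            )
            hits = library_search(
                query, reference, prefilter=False, min_matched=5, score_min=0.5
            )
            assert hits and hits[0].reference_id == reference[i].feature_id
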