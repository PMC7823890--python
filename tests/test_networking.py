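"""Spectrum filtering, modified cosine and network assembly."""

from itertools import combinations

import numpy as np
import pytest

from pefanet import FragmentSpectrum, build_network, filter_spectrum, library_search, modified_cosine
from pefanet.networking import NetworkEdge, _cap_families, _mutual_top_k

from conftest import random_spectrum


def brute_force_modified_cosine(a, b, tol=0.02):
    """Independent oracle: exhaustive max over one-to-one candidate matchings."""
    wa = np.sqrt(a.intensity)
    wb = np.sqrt(b.intensity)
    na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
    if na == 0 or nb == 0 or a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0
    wa, wb = wa / na, wb / nb
    shift = a.precursor_mz - b.precursor_mz
    candidates = [
        (i, j)
        for i in range(a.n_peaks)
        for j in range(b.n_peaks)
        if abs(a.mz[i] - b.mz[j]) <= tol or abs(a.mz[i] - b.mz[j] - shift) <= tol
    ]

    best = 0.0

    def recurse(idx, used_a, used_b, total):
        nonlocal best
        best = max(best, total)
        for k in range(idx, len(candidates)):
            i, j = candidates[k]
            if i in used_a or j in used_b:
                continue
            recurse(k + 1, used_a | {i}, used_b | {j}, total + wa[i] * wb[j])

    recurse(0, frozenset(), frozenset(), 0.0)
    return best


def brute_force_window_filter(s, precursor_exclusion=17.0, window=50.0, top_k=6):
    """Independent oracle for the peak-cleaning rules."""
    peaks = [
        (mz, inten)
        for mz, inten in zip(s.mz, s.intensity)
        if abs(mz - s.precursor_mz) > precursor_exclusion
    ]
    kept = []
    for mz, inten in peaks:
        neighbours = [(m, i) for m, i in peaks if abs(m - mz) <= window]
        neighbours.sort(key=lambda p: (-p[1], p[0]))
        if (mz, inten) in neighbours[:top_k]:
            kept.append((mz, inten))
    return kept


class TestFilterSpectrum:
    def test_precursor_window_removed(self):
        s = FragmentSpectrum("x", 500.0, mz=np.array([490.0, 300.0]), intensity=np.array([1.0, 1.0]))
        filtered = filter_spectrum(s)
        assert filtered.mz.tolist() == [300.0]

    def test_seven_equal_spaced_peaks_least_intense_dropped(self):
        mz = 100 + 5 * np.arange(7.0)
        intensity = np.array([7, 3, 6, 1, 5, 4, 2], dtype=float)
        s = FragmentSpectrum("x", 500.0, mz=mz, intensity=intensity)
        filtered = filter_spectrum(s)
        assert filtered.n_peaks == 6
        assert 115.0 not in filtered.mz  # the intensity-1 peak

    def test_empty_spectrum(self):
        s = FragmentSpectrum("x", 500.0)
        assert filter_spectrum(s).n_peaks == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            s = random_spectrum(rng, int(rng.integers(1, 20)))
            expected = brute_force_window_filter(s)
            got = filter_spectrum(s)
            assert got.peaks() == pytest.approx(expected)

    def test_invalid_parameters(self):
        s = FragmentSpectrum("x", 500.0)
        with pytest.raises(ValueError):
            filter_spectrum(s, top_k=0)


class TestModifiedCosine:
    def test_self_similarity(self):
        rng = np.random.default_rng(0)
        s = random_spectrum(rng, 8)
        score, matched = modified_cosine(s, s)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert matched == 8

    def test_no_candidate_pairs(self):
        a = FragmentSpectrum("a", 500.0, mz=np.array([100.0]), intensity=np.array([1.0]))
        b = FragmentSpectrum("b", 500.0, mz=np.array([200.0]), intensity=np.array([1.0]))
        assert modified_cosine(a, b) == (0.0, 0)

    def test_empty_spectrum(self):
        a = FragmentSpectrum("a", 500.0)
        b = FragmentSpectrum("b", 500.0, mz=np.array([100.0]), intensity=np.array([1.0]))
        assert modified_cosine(a, b) == (0.0, 0)

    def test_shifted_analog_match(self):
        # b is a +42.0106 analog: all fragments shifted with the precursor
        mz = np.array([150.0, 220.0, 300.0])
        a = FragmentSpectrum("a", 500.0, mz=mz, intensity=np.array([1.0, 0.5, 0.2]))
        b = FragmentSpectrum("b", 542.0106, mz=mz + 42.0106, intensity=np.array([1.0, 0.5, 0.2]))
        score, matched = modified_cosine(a, b)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert matched == 3

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = random_spectrum(rng, int(rng.integers(1, 6)), "a")
            b = random_spectrum(rng, int(rng.integers(1, 6)), "b", precursor=a.precursor_mz + float(rng.uniform(-60, 60)))
            ab, _ = modified_cosine(a, b)
            ba, _ = modified_cosine(b, a)
            assert ab == pytest.approx(ba, abs=1e-9)

    def test_equals_brute_force_on_small_spectra(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = random_spectrum(rng, int(rng.integers(1, 6)), "a")
            shift = float(rng.uniform(-50, 50))
            # b mixes direct copies, shifted copies and fresh peaks of a
            mz_b = []
            for _ in range(int(rng.integers(1, 6))):
                source = rng.random()
                peak = float(a.mz[rng.integers(0, a.n_peaks)])
                if source < 0.4:
                    mz_b.append(peak)
                elif source < 0.8:
                    mz_b.append(peak + shift)
                else:
                    mz_b.append(float(rng.uniform(80, 700)))
            b = FragmentSpectrum(
                "b",
                a.precursor_mz + shift,
                mz=np.array(mz_b),
                intensity=rng.uniform(0.1, 1, size=len(mz_b)),
            )
            score, _ = modified_cosine(a, b)
            assert score == pytest.approx(brute_force_modified_cosine(a, b), abs=1e-9)

    def test_agrees_with_matchms(self):
        """Independent cross-check against the matchms implementation.

        matchms weights peaks by raw intensity, so it is fed the squares
        of our square-root-weighted intensities.
        """
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(20):
            a = random_spectrum(rng, 5, "a")
            b = FragmentSpectrum(
                "b",
                a.precursor_mz + 30.0,
                mz=np.sort(np.concatenate([a.mz[:3] + 30.0, a.mz[3:]])),
                intensity=rng.uniform(0.1, 1, size=5),
            )
            ours, _ = modified_cosine(a, b)
            ref = ModifiedCosine(tolerance=0.02).pair(
                matchms.Spectrum(
                    mz=a.mz, intensities=np.sqrt(a.intensity), metadata={"precursor_mz": a.precursor_mz}
                ),
                matchms.Spectrum(
                    mz=b.mz, intensities=np.sqrt(b.intensity), metadata={"precursor_mz": b.precursor_mz}
                ),
            )
            # matchms matches greedily; only compare when it found the optimum
            if ref["score"] <= ours + 1e-9:
                assert ours == pytest.approx(ref["score"], abs=1e-6)
                checked += 1
        assert checked >= 15


class TestBuildNetwork:
    def test_low_cosine_pair_stays_singleton(self):
        rng = np.random.default_rng(5)
        a = random_spectrum(rng, 10, "a")
        b = random_spectrum(rng, 10, "b")
        network = build_network([a, b], prefilter=False)
        assert network.edges == []
        assert sorted(network.singletons) == ["a", "b"]

    def test_identical_triplet_forms_family(self):
        rng = np.random.default_rng(6)
        base = random_spectrum(rng, 8, "a")
        spectra = [
            FragmentSpectrum(fid, base.precursor_mz, mz=base.mz, intensity=base.intensity)
            for fid in ("a", "b", "c")
        ]
        network = build_network(spectra, prefilter=False)
        assert len(network.families) == 1
        assert network.families[0].node_ids == frozenset({"a", "b", "c"})
        assert all(e.cosine == pytest.approx(1.0, abs=1e-9) for e in network.edges)

    def test_mutual_top_k_subset(self):
        edges = [
            NetworkEdge("a", "b", 0.9, 7, 0.0),
            NetworkEdge("a", "c", 0.8, 7, 0.0),
            NetworkEdge("b", "c", 0.75, 7, 0.0),
        ]
        kept = _mutual_top_k(edges, top_k=1)
        assert set(e.key for e in kept) <= set(e.key for e in edges)
        assert [e.key for e in kept] == [("a", "b")]

    def test_chain_capping_removes_lowest_edges_in_order(self):
        """120-node chain with monotone scores, capped at 100."""
        import networkx as nx

        nodes = [f"n{i:03d}" for i in range(120)]
        edges = {}
        graph = nx.Graph()
        graph.add_nodes_from(nodes)
        for i in range(119):
            e = NetworkEdge(*sorted((nodes[i], nodes[i + 1])), 0.70 + 0.002 * i, 7, 0.0)
            edges[e.key] = e
            graph.add_edge(e.node_a, e.node_b)
        before = dict(edges)
        _cap_families(graph, edges, cap=100)
        components = list(nx.connected_components(graph))
        assert max(len(c) for c in components) <= 100
        removed = sorted(set(before) - set(edges))
        # exactly the 20 lowest-scoring edges go, in ascending order
        expected = sorted(before.values(), key=lambda e: e.cosine)[:20]
        assert removed == sorted(e.key for e in expected)

    def test_duplicate_ids_rejected(self):
        rng = np.random.default_rng(8)
        s = random_spectrum(rng, 5, "a")
        with pytest.raises(ValueError):
            build_network([s, s])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_network([])


class TestLibrarySearch:
    def test_identical_query_ranks_first(self):
        rng = np.random.default_rng(9)
        reference = [random_spectrum(rng, 10, f"ref{i}") for i in range(5)]
        hits = library_search(reference[2], reference, prefilter=False)
        assert hits and hits[0].reference_id == "ref2"
        assert hits[0].score == pytest.approx(1.0, abs=1e-9)

    def test_no_hits_below_threshold(self):
        rng = np.random.default_rng(10)
        reference = [random_spectrum(rng, 10, "ref0")]
        query = random_spectrum(rng, 10, "q")
        assert library_search(query, reference, prefilter=False) == []

    def test_noisy_query_same_top_hit(self):
        rng = np.random.default_rng(12)
        reference = [random_spectrum(rng, 10, f"ref{i}") for i in range(5)]
        clean = reference[1]
        noisy = FragmentSpectrum(
            "q",
            clean.precursor_mz,
            mz=clean.mz,
            intensity=clean.intensity * (1 + rng.normal(0, 0.1, clean.n_peaks)).clip(0.1),
        )
        hits = library_search(noisy, reference, prefilter=False)
        assert hits and hits[0].reference_id == "ref1"

    def test_empty_reference_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            library_search(random_spectrum(rng, 5), [])
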