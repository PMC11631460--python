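import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from heron.calling import make_calls
from heron.segmentation import (
    SKATER_EXACT_MAX,
    average_silhouette,
    candidate_regions,
    find_runs,
    interval_diameters,
    probe_distance,
    segment_hclust,
    segment_skater,
    segment_unique,
)
from heron.types import Epitope, PValueTable, parse_epitope_id

from conftest import build_dataset, region_of
from oracles import best_contiguous_partition, brute_silhouette, epitope_cuts


def calls_dataset(calls_bool, **kw):
    """Dataset + CallMatrix with the given probe x positive-sample calls."""
    n_probes, n_samples = calls_bool.shape
    data = build_dataset(
        np.zeros((n_probes, 2 + n_samples)) + np.arange(2 + n_samples),
        n_negative=2,
        **kw,
    )
    adjusted = PValueTable(
        "adjusted",
        pd.DataFrame(
            np.where(calls_bool, 0.001, 0.9),
            index=data.probe_ids,
            columns=data.positive_samples,
        ),
    )
    return data, make_calls(adjusted, 0.05)


class TestRunExtraction:
    def test_single_run_with_gap_splits(self):
        calls_bool = np.zeros((5, 2), dtype=bool)
        calls_bool[[1, 2, 3], 0] = True  # sample P1: probes 2..4 (starts 2,3,4)
        calls_bool[[0, 1, 3, 4], 1] = True  # sample P2: gap at rank 2
        data, calls = calls_dataset(calls_bool, starts=[1, 2, 3, 4, 5])
        runs1 = find_runs(calls, data, "P1")
        assert [e.epitope_id for e in runs1] == ["PROT1_2_4"]
        runs2 = find_runs(calls, data, "P2")
        assert [e.epitope_id for e in runs2] == ["PROT1_1_2", "PROT1_4_5"]
        assert find_runs(calls, data, "P1")[0].member_probes == ("pr001", "pr002", "pr003")

    def test_no_calls_no_runs(self):
        data, calls = calls_dataset(np.zeros((4, 2), dtype=bool))
        assert find_runs(calls, data, "P1") == []

    def test_unique_keeps_overlapping_blocks(self):
        calls_bool = np.zeros((5, 2), dtype=bool)
        calls_bool[[1, 2, 3], 0] = True  # P_2_4
        calls_bool[[2, 3, 4], 1] = True  # P_3_5
        data, calls = calls_dataset(calls_bool, starts=[1, 2, 3, 4, 5])
        ids = [e.epitope_id for e in segment_unique(calls, data)]
        assert ids == ["PROT1_2_4", "PROT1_3_5"]

    def test_unique_deduplicates_identical_runs(self):
        calls_bool = np.zeros((5, 2), dtype=bool)
        calls_bool[[1, 2, 3], :] = True
        data, calls = calls_dataset(calls_bool, starts=[1, 2, 3, 4, 5])
        assert [e.epitope_id for e in segment_unique(calls, data)] == ["PROT1_2_4"]

    def test_candidate_regions_take_or_across_samples(self):
        calls_bool = np.zeros((5, 2), dtype=bool)
        calls_bool[[1, 2], 0] = True
        calls_bool[[2, 3], 1] = True
        data, calls = calls_dataset(calls_bool, starts=[1, 2, 3, 4, 5])
        assert [e.epitope_id for e in candidate_regions(calls, data)] == ["PROT1_2_4"]

    def test_candidate_singletons(self):
        calls_bool = np.zeros((5, 2), dtype=bool)
        calls_bool[0, 0] = calls_bool[4, 1] = True
        data, calls = calls_dataset(calls_bool, starts=[1, 2, 3, 4, 5])
        ids = [e.epitope_id for e in candidate_regions(calls, data)]
        assert ids == ["PROT1_1_1", "PROT1_5_5"]


class TestDistances:
    def test_binary_hamming_counts_disagreements(self):
        calls_bool = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 0]], dtype=bool)
        data, calls = calls_dataset(calls_bool)
        region = Epitope("PROT1", 1, 3, tuple(data.probe_ids))
        d = probe_distance(region, calls=calls, distance="binary_hamming")
        assert d[0, 1] == 1.0
        assert d[0, 2] == 0.0
        assert (np.diag(d) == 0).all() and (d == d.T).all()

    def test_zscore_distance_zero_for_equal_pvalues(self):
        data, calls = calls_dataset(np.zeros((2, 2), dtype=bool))
        p = PValueTable(
            "combined",
            pd.DataFrame(0.5, index=data.probe_ids, columns=data.positive_samples),
        )
        region = Epitope("PROT1", 1, 2, tuple(data.probe_ids))
        d = probe_distance(region, pvalues=p, distance="zscore_euclidean")
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zscore_clipping_keeps_distances_finite(self):
        data, calls = calls_dataset(np.zeros((2, 2), dtype=bool))
        p = PValueTable(
            "combined",
            pd.DataFrame(
                [[0.0, 0.0], [1.0, 1.0]],
                index=data.probe_ids,
                columns=data.positive_samples,
            ),
        )
        region = Epitope("PROT1", 1, 2, tuple(data.probe_ids))
        d = probe_distance(region, pvalues=p, distance="zscore_euclidean")
        assert np.isfinite(d).all()
        assert d[0, 1] == pytest.approx(np.sqrt(2) * 2 * 8.2, rel=0.01)


class TestSilhouette:
    def test_perfectly_separated_pairs(self):
        d = np.array(
            [
                [0, 0, 1, 1],
                [0, 0, 1, 1],
                [1, 1, 0, 0],
                [1, 1, 0, 0],
            ],
            dtype=float,
        )
        assert average_silhouette(d, np.array([0, 0, 1, 1])) == pytest.approx(1.0)

    def test_equidistant_points_score_nonpositive(self):
        d = np.ones((4, 4)) - np.eye(4)
        assert average_silhouette(d, np.array([0, 0, 1, 1])) <= 0

    def test_all_singletons_convention(self):
        d = np.ones((3, 3)) - np.eye(3)
        assert average_silhouette(d, np.array([0, 1, 2])) == 0.0

    def test_requires_two_clusters(self):
        with pytest.raises(ValueError):
            average_silhouette(np.zeros((3, 3)), np.array([0, 0, 0]))

    def test_matches_textbook_silhouette(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            m = rng.integers(4, 9)
            d = squareform(pdist(rng.normal(size=(m, 3))))
            labels = rng.integers(0, 3, size=m)
            if len(np.unique(labels)) < 2:
                continue
            assert average_silhouette(d, labels) == pytest.approx(
                brute_silhouette(d, labels), abs=1e-12
            )


class TestIntervalDiameters:
    def test_running_max_over_intervals(self):
        rng = np.random.default_rng(2)
        d = squareform(pdist(rng.normal(size=(6, 2))))
        diam = interval_diameters(d)
        for i in range(6):
            for j in range(i + 1, 6):
                expect = max(
                    d[a, b] for a in range(i, j + 1) for b in range(a + 1, j + 1)
                )
                assert diam[i, j] == pytest.approx(expect)


def two_pattern_region(m_left=2, m_right=2, n_samples=2):
    """Region whose left probes are called only in sample 0 and right only in 1."""
    m = m_left + m_right
    calls = np.zeros((m, n_samples), dtype=bool)
    calls[:m_left, 0] = True
    calls[m_left:, 1] = True
    d = squareform(pdist(calls.astype(float), metric="hamming") * n_samples)
    region, carrier = region_of(m)
    return region, carrier, d, m_left


class TestHclust:
    def test_splits_two_consistent_patterns(self):
        region, carrier, d, m_left = two_pattern_region()
        parts = segment_hclust(region, d, carrier)
        assert [e.epitope_id for e in parts] == ["P_1_2", "P_3_4"]

    def test_identical_patterns_stay_whole(self):
        region, carrier = region_of(5)
        d = np.zeros((5, 5))
        assert segment_hclust(region, d, carrier) == [region]

    def test_two_probe_region_unsplit(self):
        region, carrier = region_of(2)
        d = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert segment_hclust(region, d, carrier) == [region]

    def test_partition_property(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            m = rng.integers(3, 10)
            calls = rng.random((m, 4)) < 0.5
            d = squareform(pdist(calls.astype(float), metric="hamming") * 4)
            region, carrier = region_of(int(m))
            parts = segment_hclust(region, d, carrier)
            recovered = tuple(p for e in parts for p in e.member_probes)
            assert recovered == region.member_probes  # exact partition, in order


class TestSkater:
    def test_splits_two_consistent_patterns(self):
        region, carrier, d, _ = two_pattern_region()
        parts = segment_skater(region, d, carrier)
        assert [e.epitope_id for e in parts] == ["P_1_2", "P_3_4"]

    def test_uniform_region_unsplit(self):
        region, carrier = region_of(6)
        assert segment_skater(region, np.zeros((6, 6)), carrier) == [region]

    def test_equal_scoring_cuts_are_both_taken(self):
        # three perfectly separated pairs: both boundary cuts score 1.0
        d = np.ones((6, 6))
        for i in (0, 2, 4):
            d[i : i + 2, i : i + 2] = 0.0
        region, carrier = region_of(6)
        parts = segment_skater(region, d, carrier)
        assert [e.n_probes for e in parts] == [2, 2, 2]

    def test_greedy_fallback_finds_clean_boundary(self):
        m = SKATER_EXACT_MAX + 4
        half = m // 2
        calls = np.zeros((m, 2), dtype=bool)
        calls[:half, 0] = True
        calls[half:, 1] = True
        d = squareform(pdist(calls.astype(float), metric="hamming") * 2)
        region, carrier = region_of(m)
        parts = segment_skater(region, d, carrier)
        assert [e.n_probes for e in parts] == [half, m - half]

    def test_matches_exhaustive_partition_search(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            m = int(rng.integers(3, 8))
            calls = rng.random((m, 4)) < rng.uniform(0.2, 0.8)
            d = squareform(pdist(calls.astype(float), metric="hamming") * 4)
            region, carrier = region_of(m)
            assert epitope_cuts(segment_skater(region, d, carrier)) == (
                best_contiguous_partition(d)
            )


class TestEpitopeIds:
    @pytest.mark.parametrize(
        "protein, first, last",
        [("P", 2, 4), ("sp|Q8K4R4|N4BP1", 17, 331), ("A_B_C", 1, 1)],
    )
    def test_round_trip(self, protein, first, last):
        epi = Epitope(protein, first, last, ("x",))
        assert parse_epitope_id(epi.epitope_id) == (protein, first, last)

    def test_covered_interval_extends_by_peptide_length(self):
        epi = Epitope("P", 10, 30, ("a", "b"))
        assert epi.covered_interval == (10, 45)
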