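"""Jaccard similarity, track weighting and the weighted consensus call."""

import numpy as np
import pytest

from conftest import mkpeak, mktrack, random_track
from enhcons import (
    SimilarityMatrix,
    TrackWeights,
    build_consensus,
    jaccard,
    similarity_matrix,
    track_weights,
)

TT = ("Histone", "DHS", "P300", "TF-binding", "POLR2A", "FAIRE")


def jaccard_oracle(a, b, **_):
    """Brute-force merged-region enumeration, independent of the sweep.

    Clusters the pooled peaks by all-pairs >=1 bp overlap tests and
    union-find (single linkage); the index is (clusters containing peaks
    of both tracks) / (all clusters). Book-ended peaks share no base pair
    and stay in separate clusters.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    peaks = [(p.chrom, p.start, p.end, 0) for p in a.peaks] + [
        (p.chrom, p.start, p.end, 1) for p in b.peaks
    ]
    if not a.peaks or not b.peaks:
        return 0.0
    chroms = np.array([hash(c) for c, _, _, _ in peaks])
    starts = np.array([s for _, s, _, _ in peaks])
    ends = np.array([e for _, _, e, _ in peaks])
    src = np.array([t for _, _, _, t in peaks])
    adj = (
        (chroms[:, None] == chroms[None, :])
        & (starts[:, None] < ends[None, :])
        & (starts[None, :] < ends[:, None])
    )
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    n_both = sum(
        1 for k in range(n_comp) if len(set(src[labels == k])) == 2
    )
    return n_both / n_comp


def uniform_weights(types):
    return TrackWeights(weights={t: 1.0 / len(types) for t in types})


class TestJaccard:
    def test_hand_computed_region_counts(self):
        a = mktrack([mkpeak("chr1", 0, 10), mkpeak("chr1", 20, 30)], "Histone")
        b = mktrack([mkpeak("chr1", 5, 15)], "DHS")
        # union regions {[0,15), [20,30)}; only the first holds both tracks
        assert jaccard(a, b) == pytest.approx(0.5)

    def test_identical_tracks_give_one(self):
        peaks = [mkpeak("chr1", 0, 100), mkpeak("chr2", 50, 80)]
        assert jaccard(mktrack(peaks, "Histone"), mktrack(peaks, "DHS")) == 1.0

    def test_disjoint_tracks_give_zero(self):
        a = mktrack([mkpeak("chr1", 0, 10)], "Histone")
        b = mktrack([mkpeak("chr1", 100, 110)], "DHS")
        assert jaccard(a, b) == 0.0

    def test_empty_track_gives_zero(self):
        a = mktrack([], "Histone")
        b = mktrack([mkpeak("chr1", 0, 10)], "DHS")
        assert jaccard(a, b) == 0.0
        assert jaccard(a, mktrack([], "DHS")) == 0.0

    def test_symmetric_and_bounded_random(self, rng):
        for _ in range(30):
            a = random_track(rng, "Histone")
            b = random_track(rng, "DHS")
            j1, j2 = jaccard(a, b), jaccard(b, a)
            assert j1 == j2
            assert 0.0 <= j1 <= 1.0

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(100):
            a = random_track(rng, "Histone", max_peaks=100, coord_bound=20_000)
            b = random_track(rng, "DHS", max_peaks=100, coord_bound=20_000)
            assert jaccard(a, b) == pytest.approx(
                jaccard_oracle(a, b, bound=25_000)
            )

    def test_bp_mode_is_coverage_iou(self):
        a = mktrack([mkpeak("chr1", 0, 100)], "Histone")
        b = mktrack([mkpeak("chr1", 50, 150)], "DHS")
        assert jaccard(a, b, mode="bp") == pytest.approx(50 / 150)
        assert jaccard(a, b, mode="regions") == 1.0


class TestSimilarityMatrix:
    def test_identical_tracks_all_ones(self):
        peaks = [mkpeak("chr1", 0, 100)]
        tracks = [mktrack(peaks, t) for t in TT[:3]]
        S = similarity_matrix(tracks)
        assert np.allclose(S.J, 1.0)

    def test_disjoint_pair_is_identity(self):
        a = mktrack([mkpeak("chr1", 0, 10)], "Histone")
        b = mktrack([mkpeak("chr1", 100, 110)], "DHS")
        S = similarity_matrix([a, b])
        assert np.allclose(S.J, np.eye(2))

    def test_matches_pairwise_jaccard(self, rng):
        tracks = [random_track(rng, t) for t in TT[:4]]
        S = similarity_matrix(tracks)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert S.J[i, j] == pytest.approx(
                        jaccard(tracks[i], tracks[j])
                    )
        assert np.allclose(S.J, S.J.T)

    def test_single_track_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            similarity_matrix([mktrack([mkpeak("chr1", 0, 10)], "DHS")])


class TestTrackWeights:
    def test_identical_tracks_uniform(self):
        for m in (2, 4, 7):
            S = SimilarityMatrix(track_ids=[f"t{i}" for i in range(m)],
                                 J=np.ones((m, m)))
            W = track_weights(S)
            assert list(W.weights.values()) == pytest.approx([1 / m] * m)

    def test_hand_computed_three_track_case(self):
        J = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.4], [0.2, 0.4, 1.0]])
        S = SimilarityMatrix(track_ids=["Histone", "DHS", "P300"], J=J)
        W = track_weights(S)
        # numerators {0.8, 1.0, 0.6}, denominator 2.4
        assert W["Histone"] == pytest.approx(1 / 3)
        assert W["DHS"] == pytest.approx(5 / 12)
        assert W["P300"] == pytest.approx(1 / 4)

    def test_two_tracks_always_half_half(self):
        for j in (0.1, 0.5, 0.99):
            S = SimilarityMatrix(
                track_ids=["Histone", "DHS"],
                J=np.array([[1.0, j], [j, 1.0]]),
            )
            W = track_weights(S)
            assert list(W.weights.values()) == pytest.approx([0.5, 0.5])

    def test_zero_offdiagonal_falls_back_to_uniform(self):
        S = SimilarityMatrix(track_ids=["Histone", "DHS", "P300"], J=np.eye(3))
        W = track_weights(S)
        assert list(W.weights.values()) == pytest.approx([1 / 3] * 3)

    def test_weights_sum_to_one_random(self, rng):
        for _ in range(50):
            m = int(rng.integers(2, 13))
            U = rng.uniform(0, 1, size=(m, m))
            J = (U + U.T) / 2
            np.fill_diagonal(J, 1.0)
            S = SimilarityMatrix(
                track_ids=[f"{TT[i % len(TT)]}" for i in range(m)]
                if m <= len(TT) else [str(i) for i in range(m)],
                J=J,
            )
            W = track_weights(S)
            assert sum(W.weights.values()) == pytest.approx(1.0, abs=1e-9)


class TestBuildConsensus:
    def test_hand_computed_two_track_score(self):
        t1 = mktrack([mkpeak("chr1", 0, 100, 2.0)], "Histone")
        t2 = mktrack([mkpeak("chr1", 50, 150, 4.0)], "DHS")
        W = uniform_weights(["Histone", "DHS"])
        ct = build_consensus([t1, t2], W)
        (p,) = ct.peaks
        assert (p.start, p.end) == (0, 150)
        assert p.supporting_tracks == {"Histone", "DHS"}
        # (0.5*100*2 + 0.5*100*4) / 150
        assert p.score == pytest.approx(2.0)

    def test_two_tracks_require_both(self):
        t1 = mktrack([mkpeak("chr1", 0, 100, 2.0),
                      mkpeak("chr1", 1000, 1100, 1.0)], "Histone")
        t2 = mktrack([mkpeak("chr1", 50, 150, 4.0)], "DHS")
        ct = build_consensus([t1, t2], uniform_weights(["Histone", "DHS"]))
        assert len(ct) == 1
        assert ct.peaks[0].start == 0

    def test_identical_tracks_recover_shared_score(self):
        for m in range(2, 7):
            types = TT[:m]
            tracks = [mktrack([mkpeak("chr1", 0, 100, 3.7)], t) for t in types]
            ct = build_consensus(tracks, uniform_weights(types))
            (p,) = ct.peaks
            assert p.score == pytest.approx(3.7, abs=1e-9)

    def test_majority_rule_two_of_three(self):
        t1 = mktrack([mkpeak("chr1", 0, 100, 1.0)], "Histone")
        t2 = mktrack([mkpeak("chr1", 50, 150, 1.0)], "DHS")
        t3 = mktrack([mkpeak("chr1", 10_000, 10_100, 1.0)], "P300")
        ct = build_consensus(
            [t1, t2, t3], uniform_weights(["Histone", "DHS", "P300"])
        )
        # region A supported by 2/3 kept; region B by 1/3 dropped
        assert len(ct) == 1
        assert ct.peaks[0].supporting_tracks == {"Histone", "DHS"}

    def test_all_tracks_empty_gives_empty_consensus(self):
        tracks = [mktrack([], "Histone"), mktrack([], "DHS")]
        ct = build_consensus(tracks, uniform_weights(["Histone", "DHS"]))
        assert len(ct) == 0

    def test_score_matches_formula_on_contributing_peaks(self, rng):
        tracks = [random_track(rng, t, max_peaks=60) for t in TT[:4]]
        S = similarity_matrix(tracks)
        W = track_weights(S)
        ct = build_consensus(tracks, W, similarity=S)
        assert len(ct) > 0
        for p in ct.peaks:
            expected = sum(
                W[t] * length * score
                for t, length, score in p.contributing_peaks
            ) / p.interval.length
            assert p.score == pytest.approx(expected, abs=1e-9)

    def test_consensus_peaks_non_overlapping(self, rng):
        tracks = [random_track(rng, t, max_peaks=80) for t in TT[:4]]
        ct = build_consensus(tracks, uniform_weights(TT[:4]))
        for a, b in zip(ct.peaks, ct.peaks[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start

    def test_support_monotone_under_added_peak(self, rng):
        """Adding a peak to one track never removes consensus coverage."""
        for _ in range(10):
            tracks = [random_track(rng, t, max_peaks=40) for t in TT[:4]]
            W = uniform_weights(TT[:4])
            before = build_consensus(tracks, W)
            s = int(rng.integers(0, 10_000))
            extra = mkpeak("chr1", s, s + int(rng.integers(1, 300)))
            tracks2 = list(tracks)
            tracks2[0] = mktrack(list(tracks[0].peaks) + [extra], TT[0])
            after = build_consensus(tracks2, W)
            cov_before = {
                (p.chrom, x) for p in before.peaks
                for x in range(p.start, p.end)
            }
            cov_after = {
                (p.chrom, x) for p in after.peaks
                for x in range(p.start, p.end)
            }
            assert cov_before <= cov_after

    def test_support_fraction_sweep(self, rng):
        tracks = [random_track(rng, t, max_peaks=60) for t in TT[:4]]
        W = uniform_weights(TT[:4])
        full = build_consensus(tracks, W, min_support_fraction=1e-9)
        strict = build_consensus(tracks, W, min_support_fraction=1.0)
        from enhcons.core import merge_intervals
        all_regions = merge_intervals(
            (p.chrom, p.start, p.end) for t in tracks for p in t.peaks
        )
        # vanishing threshold: every merged union region is a consensus peak
        assert len(full) == len(all_regions)
        # unanimity: every consensus peak overlaps all four tracks
        for p in strict.peaks:
            assert len(p.supporting_tracks) == 4

    def test_mismatched_weights_rejected(self):
        t1 = mktrack([mkpeak("chr1", 0, 10)], "Histone")
        t2 = mktrack([mkpeak("chr1", 5, 15)], "DHS")
        with pytest.raises(ValueError, match="do not match"):
            build_consensus([t1, t2], uniform_weights(["Histone", "P300"]))

    def test_single_track_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            build_consensus(
                [mktrack([mkpeak("chr1", 0, 10)], "DHS")],
                uniform_weights(["DHS"]),
            )
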