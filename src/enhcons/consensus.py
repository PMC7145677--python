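"""Track similarity, track weighting and the weighted consensus call.

Given ``m`` assembled evidence tracks for one tissue/cell type the
consensus is built in three steps:

1. **Similarity.** Every unordered pair of tracks gets a Jaccard index.
   In the default "regions" mode the union of the two tracks' peaks is
   single-linkage merged; the index is the number of merged regions that
   contain at least one peak from *both* tracks divided by the total
   number of merged regions. A base-pair mode (intersection bp over union
   bp) is available for sensitivity analysis.

2. **Weights.** Track ``t`` is weighted by how much it agrees with the
   other tracks: ``w_t`` is its off-diagonal row sum of the similarity
   matrix divided by the sum of all off-diagonal entries, so the weights
   sum to 1. A track corroborated by many assays counts for more than an
   outlier. When no two tracks overlap at all, weights fall back to
   uniform ``1/m``.

3. **Consensus.** All tracks' peaks are pooled and single-linkage merged
   into candidate regions. A candidate is kept when at least 50% of the
   tracks (``ceil(m/2)``; both tracks when ``m == 2``) contribute at least
   one overlapping peak. The consensus interval is the span of the
   supporting tracks' member peaks, and its combined score is::

       Score_combined = sum_t( w_t * L_t * Score_t ) / L_combined

   summing over every contributing peak, where ``L_t`` is the peak's
   length, ``Score_t`` its normalized signal and ``L_combined`` the
   consensus interval's length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import GenomicInterval, Track, merge_intervals

logger = logging.getLogger(__name__)

JaccardMode = Literal["regions", "bp"]


@dataclass
class SimilarityMatrix:
    """Pairwise Jaccard indices between tracks, symmetric with unit diagonal."""

    track_ids: list[str]
    J: np.ndarray

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        m = len(self.track_ids)
        if self.J.shape != (m, m):
            raise ValueError("similarity matrix shape does not match tracks")


@dataclass
class TrackWeights:
    """Per-track weights ``w_t`` summing to 1."""

    weights: dict[str, float]

    @property
    def m(self) -> int:
        return len(self.weights)

    def __getitem__(self, track_id: str) -> float:
        return self.weights[track_id]


@dataclass(frozen=True)
class ConsensusPeak:
    """One consensus enhancer with its provenance.

    ``contributing_peaks`` lists ``(track_type, peak_length, normalized
    score)`` for every peak of a supporting track that fell in this
    region.
    """

    interval: GenomicInterval
    score: float
    supporting_tracks: frozenset[str]
    contributing_peaks: tuple[tuple[str, int, float], ...] = ()

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class ConsensusTrack:
    """The consensus enhancer set for one tissue/cell type."""

    cell_type: str
    peaks: list[ConsensusPeak]
    weights: TrackWeights
    similarity: SimilarityMatrix

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.chrom, p.start, p.end)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def _regions_hit(
    regions: list[tuple[str, int, int]], track: Track
) -> np.ndarray:
    """Boolean mask: which merged regions contain >= 1 peak of ``track``.

    ``regions`` must be sorted and disjoint; peaks are sorted, so a single
    linear sweep suffices.
    """
    hit = np.zeros(len(regions), dtype=bool)
    i = 0
    for p in track.peaks:
        key = (p.chrom, p.start)
        while i < len(regions) and (regions[i][0], regions[i][2]) <= key:
            i += 1
        if i < len(regions):
            c, s, e = regions[i]
            if c == p.chrom and s < p.end and p.start < e:
                hit[i] = True
    return hit


def jaccard(a: Track, b: Track, mode: JaccardMode = "regions") -> float:
    """Jaccard similarity between two tracks.

    ``regions`` mode (default): merge the union of both tracks' peaks and
    return (regions containing peaks of both) / (all merged regions).
    ``bp`` mode: intersection base pairs over union base pairs. Returns 0
    when either track is empty.
    """
    if not a.peaks or not b.peaks:
        return 0.0
    if mode == "bp":
        union = merge_intervals(
            [(p.chrom, p.start, p.end) for t in (a, b) for p in t.peaks]
        )
        union_bp = sum(e - s for _, s, e in union)
        cov_a = merge_intervals((p.chrom, p.start, p.end) for p in a.peaks)
        cov_b = merge_intervals((p.chrom, p.start, p.end) for p in b.peaks)
        inter_bp = _intersection_bp(cov_a, cov_b)
        return inter_bp / union_bp if union_bp else 0.0
    regions = merge_intervals(
        [(p.chrom, p.start, p.end) for t in (a, b) for p in t.peaks]
    )
    both = _regions_hit(regions, a) & _regions_hit(regions, b)
    return float(both.sum()) / len(regions)


def _intersection_bp(
    a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]
) -> int:
    """Total overlap bp between two sorted disjoint interval lists."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        ca, sa, ea = a[i]
        cb, sb, eb = b[j]
        if ca < cb:
            i += 1
        elif cb < ca:
            j += 1
        else:
            lo, hi = max(sa, sb), min(ea, eb)
            if lo < hi:
                total += hi - lo
            if ea <= eb:
                i += 1
            else:
                j += 1
    return total


def similarity_matrix(
    tracks: Sequence[Track], mode: JaccardMode = "regions"
) -> SimilarityMatrix:
    """All pairwise Jaccard indices, computed once per unordered pair."""
    m = len(tracks)
    if m < 2:
        raise ValueError("consensus requires >= 2 tracks")
    J = np.eye(m)
    for i in range(m):
        if not tracks[i].peaks:
            J[i, i] = 0.0
        for j in range(i + 1, m):
            J[i, j] = J[j, i] = jaccard(tracks[i], tracks[j], mode=mode)
    return SimilarityMatrix(track_ids=[t.track_type for t in tracks], J=J)


def track_weights(S: SimilarityMatrix) -> TrackWeights:
    """Weight each track by its total similarity to the other tracks.

    ``w_t = sum_{j != t} J[t,j] / sum_k sum_{j != k} J[k,j]``; the
    denominator is the sum of all off-diagonal entries, which makes the
    weights sum to exactly 1. A matrix with zero off-diagonal mass (no
    track overlaps any other) yields uniform weights with a warning.
    """
    m = len(S.track_ids)
    if m < 2:
        raise ValueError("track weighting requires >= 2 tracks")
    off = S.J - np.diag(np.diag(S.J))
    numerators = off.sum(axis=1)
    denom = off.sum()
    if denom <= 0:
        logger.warning(
            "no off-diagonal similarity between any tracks; "
            "falling back to uniform weights 1/%d", m
        )
        w = np.full(m, 1.0 / m)
    else:
        w = numerators / denom
    return TrackWeights(weights=dict(zip(S.track_ids, w.tolist())))


def _support_threshold(m: int, min_support_fraction: float) -> int:
    """Minimum number of supporting tracks for a candidate region.

    ``ceil(min_support_fraction * m)``, except that with exactly two
    tracks and a threshold of 50% or more, support by *both* tracks is
    required — a lone track's evidence is never enough for a consensus
    call.
    """
    k = math.ceil(min_support_fraction * m)
    if m == 2 and min_support_fraction >= 0.5:
        k = 2
    return max(k, 1) if min_support_fraction > 0 else 1


def build_consensus(
    tracks: Sequence[Track],
    W: TrackWeights,
    min_support_fraction: float = 0.5,
    cell_type: str = "consensus",
    similarity: SimilarityMatrix | None = None,
    score_overlap: Literal["full", "clipped"] = "full",
) -> ConsensusTrack:
    """Call consensus enhancers from weighted evidence tracks.

    See the module docstring for the algorithm. ``score_overlap`` chooses
    whether a contributing peak enters the score numerator with its full
    length (default, the literal formula) or clipped to the consensus
    interval.
    """
    m = len(tracks)
    if m < 2:
        raise ValueError("consensus requires >= 2 tracks")
    if set(W.weights) != {t.track_type for t in tracks}:
        raise ValueError("weights do not match the given tracks")

    tagged = [
        (p.chrom, p.start, p.end, t.track_type, p.signal)
        for t in tracks
        for p in t.peaks
    ]
    regions = merge_intervals((c, s, e) for c, s, e, _, _ in tagged)
    # bucket every peak into its (unique) containing merged region
    members: list[list[tuple[str, int, int, str, float]]] = [
        [] for _ in regions
    ]
    i = 0
    for rec in sorted(tagged):
        c, s, e = rec[0], rec[1], rec[2]
        while i < len(regions) and (regions[i][0], regions[i][2]) <= (c, s):
            i += 1
        members[i].append(rec)

    k_min = _support_threshold(m, min_support_fraction)
    out: list[ConsensusPeak] = []
    for region, recs in zip(regions, members):
        supporting = {t for _, _, _, t, _ in recs}
        if len(supporting) < k_min:
            continue
        chrom = region[0]
        start = min(s for _, s, _, _, _ in recs)
        end = max(e for _, _, e, _, _ in recs)
        iv = GenomicInterval(chrom, start, end)
        contrib: list[tuple[str, int, float]] = []
        num = 0.0
        for _, s, e, t, sig in recs:
            if score_overlap == "clipped":
                length = min(e, iv.end) - max(s, iv.start)
            else:
                length = e - s
            contrib.append((t, length, sig))
            num += W[t] * length * sig
        out.append(
            ConsensusPeak(
                interval=iv,
                score=num / iv.length,
                supporting_tracks=frozenset(supporting),
                contributing_peaks=tuple(contrib),
            )
        )
    if similarity is None:
        similarity = SimilarityMatrix(
            track_ids=list(W.weights),
            J=np.eye(len(W.weights)),
        )
    return ConsensusTrack(
        cell_type=cell_type, peaks=out, weights=W, similarity=similarity
    )
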