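"""Jaccard similarity and track weights on three hand-built tracks.

Histone and DHS peaks mostly co-locate; the P300 track only partially
agrees. The region-count Jaccard index scores each pair, and each track's
weight is its share of the total pairwise agreement — so the outlier
track votes with less weight in the consensus.
"""

from enhcons import (
    GenomicInterval,
    Peak,
    Track,
    similarity_matrix,
    track_weights,
)


def track(track_type, coords):
    return Track(
        track_type=track_type,
        peaks=[Peak(GenomicInterval("chr1", s, e)) for s, e in coords],
    )


tracks = [
    track("Histone", [(100, 600), (2_000, 2_500), (5_000, 5_400), (8_000, 8_300)]),
    track("DHS", [(150, 500), (2_100, 2_400), (5_100, 5_300), (9_000, 9_200)]),
    track("P300", [(120, 450), (40_000, 40_200), (50_000, 50_300)]),
]

S = similarity_matrix(tracks)
print("Jaccard similarity matrix (region counts):")
for tid, row in zip(S.track_ids, S.J):
    print(f"  {tid:>8}  " + "  ".join(f"{v:.3f}" for v in row))

W = track_weights(S)
print("track weights (sum to 1; agreement earns weight):")
for tid, w in W.weights.items():
    print(f"  {tid:>8}  w = {w:.4f}")
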