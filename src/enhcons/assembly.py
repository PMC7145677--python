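"""Within-track merging of multiple datasets by the average-summit /
average-width (ASW) rule.

When one evidence track holds several experiments (e.g. many TF ChIP-seq
datasets on the TF-binding track), their peaks are pooled and partitioned
into clusters of transitively overlapping peaks (single linkage, >= 1 bp).
Each cluster is replaced by one peak centered at the arithmetic mean of
the member summits, as wide as the arithmetic mean of the member lengths,
carrying the arithmetic mean of the member normalized signals. A summit is
the narrowPeak summit when present, else the interval midpoint.

Because averaged widths can exceed a cluster's span, adjacent merged peaks
may newly overlap; merging is therefore iterated to a fixed point (in
practice one extra pass, hard-capped at 10).
"""

from __future__ import annotations

import math
from typing import Sequence

from .core import GenomicInterval, Peak, PeakDataset, Track, sort_peaks

_MAX_PASSES = 10


def _asw_merge_cluster(cluster: Sequence[Peak]) -> Peak:
    """Collapse one overlap cluster into its average-summit/width peak."""
    if len(cluster) == 1:
        return cluster[0]
    center = sum(p.summit_pos for p in cluster) / len(cluster)
    # half-up rounding, not banker's: merged geometry must not depend on
    # the parity of neighbouring integers
    width = max(1, math.floor(sum(p.length for p in cluster) / len(cluster) + 0.5))
    signal = sum(p.signal for p in cluster) / len(cluster)
    start = max(0, math.floor(center - width / 2 + 0.5))
    return Peak(
        GenomicInterval(cluster[0].chrom, start, start + width),
        signal=signal,
    )


def _one_pass(peaks: list[Peak]) -> list[Peak]:
    """One single-linkage clustering + ASW collapse sweep over sorted peaks."""
    out: list[Peak] = []
    cluster: list[Peak] = []
    cluster_end = -1
    cluster_chrom = None
    for p in sort_peaks(peaks):
        if cluster and p.chrom == cluster_chrom and p.start < cluster_end:
            cluster.append(p)
            cluster_end = max(cluster_end, p.end)
        else:
            if cluster:
                out.append(_asw_merge_cluster(cluster))
            cluster = [p]
            cluster_chrom = p.chrom
            cluster_end = p.end
    if cluster:
        out.append(_asw_merge_cluster(cluster))
    return out


def assemble_track(datasets: Sequence[PeakDataset]) -> Track:
    """Merge normalized datasets of one evidence type into a single track.

    A single dataset passes through unchanged. Multiple datasets are
    ASW-merged as described in the module docstring. Raises ``ValueError``
    on an empty list, mixed track types, or unnormalized input.
    """
    if not datasets:
        raise ValueError("assemble_track requires at least one dataset")
    track_type = datasets[0].track_type
    if any(d.track_type != track_type for d in datasets):
        types = sorted({d.track_type for d in datasets})
        raise ValueError(f"mixed track types in one track: {types}")
    if any(not d.normalized for d in datasets):
        raise ValueError("all datasets must be normalized before assembly")

    if len(datasets) == 1:
        return Track(
            track_type=track_type,
            peaks=list(datasets[0].peaks),
            source_count=1,
        )

    peaks = [p for d in datasets for p in d.peaks]
    for _ in range(_MAX_PASSES):
        merged = _one_pass(peaks)
        if len(merged) == len(peaks):
            return Track(
                track_type=track_type,
                peaks=merged,
                source_count=len(datasets),
            )
        peaks = merged
    raise RuntimeError(
        f"ASW merging did not converge within {_MAX_PASSES} passes "
        f"for track {track_type}"
    )
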