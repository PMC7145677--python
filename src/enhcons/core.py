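"""Core interval and peak containers shared by every stage of the pipeline.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers positions ``start .. end-1`` and its length is
``end - start``. Two intervals overlap iff they share at least one base
pair; book-ended intervals (``[0,10)`` and ``[10,20)``) do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

#: The twelve evidence classes whose peaks can vote for an enhancer.
TRACK_TYPES: tuple[str, ...] = (
    "P300",
    "POLR2A",
    "Histone",
    "TF-binding",
    "DHS",
    "FAIRE",
    "MNase",
    "GRO",
    "CAGE",
    "MPRA",
    "STARR",
    "ChIA-PET",
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """One peak call: an interval with a fold-enrichment signal.

    ``summit`` is the offset of the signal maximum from ``start`` (narrowPeak
    column 10 convention); ``None`` when the caller did not report one, in
    which case downstream code falls back to the interval midpoint.
    """

    interval: GenomicInterval
    signal: float = 1.0
    summit: Optional[int] = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"negative signal: {self.signal}")
        if self.summit is not None and not (0 <= self.summit < self.length):
            raise ValueError(
                f"summit offset {self.summit} outside peak of length {self.length}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def summit_pos(self) -> int:
        """Absolute summit position; interval midpoint when no summit."""
        if self.summit is not None:
            return self.start + self.summit
        return self.interval.midpoint


def sort_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    """Stable sort by (chrom, start, end); ties keep input order."""
    return sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))


@dataclass
class PeakDataset:
    """One experiment's peak calls, assigned to an evidence track type."""

    name: str
    track_type: str
    peaks: list[Peak] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.track_type not in TRACK_TYPES:
            raise ValueError(
                f"unknown track type {self.track_type!r}; "
                f"expected one of {', '.join(TRACK_TYPES)}"
            )
        self.peaks = sort_peaks(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def with_peaks(self, peaks: Sequence[Peak], **kw) -> "PeakDataset":
        """Copy of this dataset with a new (re-sorted) peak list."""
        out = replace(self, peaks=sort_peaks(peaks), **kw)
        return out

    def coverage(self) -> int:
        """Total merged base-pair coverage of the dataset's peaks."""
        return sum(e - s for _, s, e in merge_intervals(
            (p.chrom, p.start, p.end) for p in self.peaks
        ))


@dataclass
class Track:
    """One evidence type after within-track merging of its datasets."""

    track_type: str
    peaks: list[Peak]
    source_count: int = 1

    def __post_init__(self) -> None:
        self.peaks = sort_peaks(self.peaks)
        if self.source_count < 1:
            raise ValueError("source_count must be >= 1")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)


@dataclass
class AnnotationSet:
    """Promoter / exon / CTCF-insulator intervals used to blacklist peaks.

    Each collection is stored sorted and internally merged, so no two
    intervals within one collection overlap.
    """

    promoters: list[GenomicInterval] = field(default_factory=list)
    exons: list[GenomicInterval] = field(default_factory=list)
    insulators: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.promoters = _merge_to_intervals(self.promoters)
        self.exons = _merge_to_intervals(self.exons)
        self.insulators = _merge_to_intervals(self.insulators)

    def all_intervals(self) -> list[GenomicInterval]:
        return _merge_to_intervals(
            self.promoters + self.exons + self.insulators
        )

    def is_empty(self) -> bool:
        return not (self.promoters or self.exons or self.insulators)


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Single-linkage merge of half-open intervals sharing >= 1 bp.

    Book-ended intervals stay separate. Returns sorted merged tuples.
    """
    ivs = sorted(intervals)
    merged: list[list] = []
    for chrom, start, end in ivs:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [(c, s, e) for c, s, e in merged]


def _merge_to_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    return [
        GenomicInterval(c, s, e)
        for c, s, e in merge_intervals((iv.chrom, iv.start, iv.end) for iv in intervals)
    ]


def overlaps_any(
    peak_iv: GenomicInterval, merged: Sequence[GenomicInterval]
) -> bool:
    """Binary-search test of >=1 bp overlap against a sorted merged list."""
    import bisect

    # merged is sorted by (chrom, start, end); find candidates on the chrom
    keys = [(iv.chrom, iv.start) for iv in merged]
    i = bisect.bisect_right(keys, (peak_iv.chrom, peak_iv.start))
    # the interval starting at or before peak start may still reach into it
    for j in (i - 1, i):
        if 0 <= j < len(merged) and merged[j].overlaps(peak_iv):
            return True
    return False
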