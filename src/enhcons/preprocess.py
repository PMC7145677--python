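"""Dataset-level and peak-level filters plus per-dataset signal normalization.

The pipeline applies, in this fixed order:

1. length cap — drop peaks longer than 2500 bp;
2. annotation exclusion — drop peaks sharing >= 1 bp with any promoter,
   exon or CTCF-defined insulator interval (whole-peak removal, never
   truncation);
3. size gate — drop whole datasets whose merged peak coverage falls below
   5 kb or above 10 Mb, a guard against degenerate experiments with far
   too few or too many peaks;
4. signal normalization — divide every fold enrichment by the dataset's
   length-weighted mean signal, so the length-weighted mean of the
   normalized signals is exactly 1 and datasets become comparable.

Normalization runs last on purpose: peaks removed by the filters must not
contribute to the normalizing denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core import (
    AnnotationSet,
    GenomicInterval,
    Peak,
    PeakDataset,
    overlaps_any,
)

logger = logging.getLogger(__name__)

MAX_PEAK_LENGTH = 2500  # bp; peaks strictly longer are discarded
MIN_DATASET_COVERAGE = 5_000  # bp
MAX_DATASET_COVERAGE = 10_000_000  # bp


@dataclass
class FilterReport:
    """Audit trail of what each filter removed from one dataset."""

    dataset: str
    peaks_in: int = 0
    removed_length: int = 0
    removed_annotation: int = 0
    dataset_dropped: bool = False
    drop_reason: Optional[str] = None

    @property
    def peaks_out(self) -> int:
        return self.peaks_in - self.removed_length - self.removed_annotation

    def merge(self, other: "FilterReport") -> "FilterReport":
        """Combine reports from successive filter stages on one dataset."""
        assert self.dataset == other.dataset
        return FilterReport(
            dataset=self.dataset,
            peaks_in=self.peaks_in,
            removed_length=self.removed_length + other.removed_length,
            removed_annotation=self.removed_annotation + other.removed_annotation,
            dataset_dropped=self.dataset_dropped or other.dataset_dropped,
            drop_reason=self.drop_reason or other.drop_reason,
        )


def filter_peak_length(
    dataset: PeakDataset, max_len: int = MAX_PEAK_LENGTH
) -> tuple[PeakDataset, FilterReport]:
    """Drop peaks with length strictly over ``max_len`` bp (default 2500)."""
    kept = [p for p in dataset.peaks if p.length <= max_len]
    report = FilterReport(
        dataset=dataset.name,
        peaks_in=len(dataset.peaks),
        removed_length=len(dataset.peaks) - len(kept),
    )
    if not kept:
        logger.warning("dataset %s: all peaks removed by length cap", dataset.name)
    return dataset.with_peaks(kept), report


def gate_dataset_size(
    dataset: PeakDataset,
    min_cov: int = MIN_DATASET_COVERAGE,
    max_cov: int = MAX_DATASET_COVERAGE,
) -> tuple[bool, FilterReport]:
    """Decide whether a dataset passes the coverage gate.

    "Size" is the total merged base-pair coverage of the dataset's peaks.
    Returns ``(keep, report)``; ``keep`` is False when coverage < ``min_cov``
    or > ``max_cov``.
    """
    cov = dataset.coverage()
    report = FilterReport(dataset=dataset.name, peaks_in=len(dataset.peaks))
    if cov < min_cov:
        report.dataset_dropped = True
        report.drop_reason = f"coverage {cov} bp below {min_cov} bp"
    elif cov > max_cov:
        report.dataset_dropped = True
        report.drop_reason = f"coverage {cov} bp above {max_cov} bp"
    if report.dataset_dropped:
        logger.info("dropping dataset %s: %s", dataset.name, report.drop_reason)
    return not report.dataset_dropped, report


def exclude_annotated(
    dataset: PeakDataset, annotations: AnnotationSet
) -> tuple[PeakDataset, FilterReport]:
    """Remove peaks overlapping any promoter, exon or insulator interval.

    A peak is removed iff it shares >= 1 bp with any annotation interval;
    peaks are never truncated. Book-ended peaks (peak end == annotation
    start) are kept.
    """
    blacklist = annotations.all_intervals()
    if not blacklist:
        report = FilterReport(dataset=dataset.name, peaks_in=len(dataset.peaks))
        return dataset, report
    kept = [
        p for p in dataset.peaks if not overlaps_any(p.interval, blacklist)
    ]
    report = FilterReport(
        dataset=dataset.name,
        peaks_in=len(dataset.peaks),
        removed_annotation=len(dataset.peaks) - len(kept),
    )
    return dataset.with_peaks(kept), report


def normalize_signals(dataset: PeakDataset) -> PeakDataset:
    """Divide signals by the dataset's length-weighted mean signal.

    For peaks with fold enrichments ``s_i`` and lengths ``l_i``::

        s'_i = s_i / ( sum_i(s_i * l_i) / sum_i(l_i) )

    so the length-weighted mean of the normalized signals equals 1. Raises
    ``ValueError`` on an empty or all-zero-signal dataset.
    """
    if not dataset.peaks:
        raise ValueError(f"cannot normalize empty dataset {dataset.name!r}")
    num = sum(p.signal * p.length for p in dataset.peaks)
    den = sum(p.length for p in dataset.peaks)
    mean = num / den
    if mean == 0:
        raise ValueError(
            f"cannot normalize zero-signal dataset {dataset.name!r}"
        )
    new_peaks = [
        Peak(p.interval, signal=p.signal / mean, summit=p.summit)
        for p in dataset.peaks
    ]
    return dataset.with_peaks(new_peaks, normalized=True)


def preprocess_dataset(
    dataset: PeakDataset,
    annotations: Optional[AnnotationSet] = None,
    max_len: int = MAX_PEAK_LENGTH,
    min_cov: int = MIN_DATASET_COVERAGE,
    max_cov: int = MAX_DATASET_COVERAGE,
) -> tuple[Optional[PeakDataset], FilterReport]:
    """Run the full filter chain on one dataset.

    Returns ``(dataset, report)`` with the dataset normalized, or
    ``(None, report)`` when the dataset was dropped by the size gate or
    emptied by the peak-level filters.
    """
    ds, rep_len = filter_peak_length(dataset, max_len=max_len)
    if annotations is not None:
        ds, rep_ann = exclude_annotated(ds, annotations)
    else:
        rep_ann = FilterReport(dataset=ds.name)
    keep, rep_gate = gate_dataset_size(ds, min_cov=min_cov, max_cov=max_cov)
    report = rep_len.merge(rep_ann).merge(rep_gate)
    report.peaks_in = len(dataset.peaks)
    if not keep or not ds.peaks:
        if not report.dataset_dropped:
            report.dataset_dropped = True
            report.drop_reason = "no peaks survived filtering"
        return None, report
    return normalize_signals(ds), report


def chiapet_anchor_enhancers(
    anchors: PeakDataset,
    genes: Sequence[GenomicInterval] = (),
    promoters: Sequence[GenomicInterval] = (),
) -> PeakDataset:
    """Keep interaction anchors outside every gene body and promoter.

    Surviving anchors become candidate enhancers on the ChIA-PET evidence
    track; anchors sharing >= 1 bp with a gene or promoter are removed.
    """
    from .core import _merge_to_intervals

    blacklist = _merge_to_intervals(list(genes) + list(promoters))
    kept = [
        p for p in anchors.peaks if not overlaps_any(p.interval, blacklist)
    ]
    return anchors.with_peaks(kept, track_type="ChIA-PET")


def reports_to_rows(reports: Iterable[FilterReport]) -> list[dict]:
    """Flatten filter reports for TSV/DataFrame export."""
    return [
        {
            "dataset": r.dataset,
            "peaks_in": r.peaks_in,
            "removed_length": r.removed_length,
            "removed_annotation": r.removed_annotation,
            "peaks_out": r.peaks_out if not r.dataset_dropped else 0,
            "dropped": r.dataset_dropped,
            "reason": r.drop_reason or "",
        }
        for r in reports
    ]
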