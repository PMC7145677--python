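"""Preprocess one peak dataset: length cap, blacklist exclusion, signal
normalization.

Builds a six-peak H3K27ac-style dataset by hand, removes the over-long
peak and the promoter-overlapping peak, and normalizes the surviving fold
enrichments so their length-weighted mean is 1 — the scale on which
datasets from different assays become comparable.
"""

from enhcons import (
    AnnotationSet,
    GenomicInterval,
    Peak,
    PeakDataset,
    exclude_annotated,
    filter_peak_length,
    normalize_signals,
)

peaks = [
    Peak(GenomicInterval("chr1", 1_000, 1_800), signal=6.0),
    Peak(GenomicInterval("chr1", 5_000, 5_400), signal=12.0),
    Peak(GenomicInterval("chr1", 9_000, 12_000), signal=3.0),   # 3000 bp: too long
    Peak(GenomicInterval("chr1", 20_000, 20_600), signal=8.0),  # in a promoter
    Peak(GenomicInterval("chr1", 30_000, 31_000), signal=2.0),
    Peak(GenomicInterval("chr2", 100, 900), signal=4.0),
]
dataset = PeakDataset(name="H3K27ac_rep1", track_type="Histone", peaks=peaks)
annotations = AnnotationSet(
    promoters=[GenomicInterval("chr1", 20_500, 21_500)],
)

dataset, length_report = filter_peak_length(dataset)
dataset, annot_report = exclude_annotated(dataset, annotations)
dataset = normalize_signals(dataset)

print(f"peaks in: {length_report.peaks_in}")
print(f"removed by 2500 bp cap: {length_report.removed_length}")
print(f"removed by annotation overlap: {annot_report.removed_annotation}")
print("normalized signals (length-weighted mean is 1):")
for p in dataset.peaks:
    print(f"  {p.chrom}:{p.start}-{p.end}  s' = {p.signal:.4f}")
lw = sum(p.signal * p.length for p in dataset) / sum(p.length for p in dataset)
print(f"length-weighted mean of s': {lw:.12f}")
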