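"""Synthetic multi-track peak data with known ground truth.

The generator emulates the situation the consensus method is built for:
several independent assays (tracks) each observe the same underlying set
of enhancers imperfectly — an enhancer shows up in a given track with some
sensitivity, its position and width are jittered, its fold enrichment is
drawn from a skewed (log-normal) law — and each assay additionally calls
spurious peaks at locations independent across tracks. Because the noise
is independent while the signal is shared, the >=50%-support rule is
exactly the mechanism that should separate them.

Reproducibility discipline: one master seed spawns independent child
streams per (track, dataset) via ``numpy.random.SeedSequence``, so the
same scenario always yields byte-identical outputs and changing one
track's parameters does not perturb the others' draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as eio
from .consensus import ConsensusTrack
from .core import (
    AnnotationSet,
    GenomicInterval,
    Peak,
    PeakDataset,
    merge_intervals,
)

logger = logging.getLogger(__name__)

#: Track types assigned to synthetic tracks, in order.
_DEFAULT_TRACKS = ("Histone", "DHS", "P300", "TF-binding", "POLR2A", "FAIRE",
                   "GRO", "CAGE", "MNase", "STARR", "MPRA", "ChIA-PET")


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic multi-track experiment.

    Defaults describe a genome of 50 Mb over two chromosomes carrying 300
    planted enhancers of 200-1000 bp, observed by 4 tracks with per-track
    sensitivity 0.8, ~50 bp positional and width jitter, log-normal fold
    enrichments and one noise peak per true peak per dataset.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 30_000_000),
        ("chr2", 20_000_000),
    )
    n_true: int = 300
    true_len_range: tuple[int, int] = (200, 1000)
    n_tracks: int = 4
    sensitivity: float = 0.8
    jitter_sd: float = 50.0
    width_jitter_sd: float = 50.0
    noise_rate: float = 1.0
    signal_law: tuple[float, float] = (1.0, 0.5)  # log-normal (mu, sigma)
    n_datasets_per_track: int = 1
    n_promoters: int = 60
    n_exons: int = 60
    n_insulators: int = 30
    annotation_len_range: tuple[int, int] = (500, 2000)

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError("sensitivity must be in [0, 1]")
        if self.true_len_range[0] <= 0:
            raise ValueError("enhancer lengths must be positive")
        if self.n_tracks < 1 or self.n_tracks > len(_DEFAULT_TRACKS):
            raise ValueError(f"n_tracks must be in [1, {len(_DEFAULT_TRACKS)}]")


def _place_disjoint(
    rng: np.random.Generator,
    genome: tuple[tuple[str, int], ...],
    n: int,
    len_range: tuple[int, int],
    min_gap: int = 1000,
) -> list[GenomicInterval]:
    """Place n disjoint intervals uniformly, >= min_gap bp apart.

    Counts are split across chromosomes proportionally to length; within
    a chromosome the classic gap construction (sorted uniform starts in
    the slack space, then offset by cumulative lengths) guarantees
    disjointness with exact uniformity over valid configurations.
    """
    total = sum(l for _, l in genome)
    out: list[GenomicInterval] = []
    remaining = n
    for idx, (chrom, chrom_len) in enumerate(genome):
        if idx == len(genome) - 1:
            n_here = remaining
        else:
            n_here = int(round(n * chrom_len / total))
            n_here = min(n_here, remaining)
        remaining -= n_here
        if n_here == 0:
            continue
        lengths = rng.integers(len_range[0], len_range[1] + 1, size=n_here)
        slack = chrom_len - int(lengths.sum()) - min_gap * n_here
        if slack < 0:
            raise ValueError(
                f"chromosome {chrom} ({chrom_len} bp) too small for "
                f"{n_here} intervals of up to {len_range[1]} bp"
            )
        gaps = np.sort(rng.integers(0, slack + 1, size=n_here))
        starts = gaps + np.cumsum(lengths) - lengths + min_gap * np.arange(n_here)
        for s, l in zip(starts.tolist(), lengths.tolist()):
            out.append(GenomicInterval(chrom, int(s), int(s + l)))
    return out


def _footprint(intervals: list[GenomicInterval]) -> dict[str, np.ndarray]:
    """Per-chromosome merged, sorted (start, end) arrays for overlap tests."""
    merged = merge_intervals((iv.chrom, iv.start, iv.end) for iv in intervals)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in merged:
        by_chrom.setdefault(chrom, []).append((start, end))
    return {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}


def _hits_footprint(
    chrom: str, start: int, end: int, fp: dict[str, np.ndarray],
    margin: int = 0,
) -> bool:
    arr = fp.get(chrom)
    if arr is None or len(arr) == 0:
        return False
    i = int(np.searchsorted(arr[:, 0], end + margin))
    return i > 0 and arr[i - 1, 1] + margin > start


def generate_scenario(
    scenario: SyntheticScenario,
) -> tuple[PeakDataset, dict[str, PeakDataset], AnnotationSet]:
    """Generate truth enhancers, per-track datasets and annotations.

    Returns ``(truth, datasets, annotations)`` where ``datasets`` maps
    dataset name -> :class:`PeakDataset`. Fully determined by
    ``scenario.seed``.
    """
    ss = np.random.SeedSequence(scenario.seed)
    children = ss.spawn(2 + scenario.n_tracks)
    rng_truth = np.random.default_rng(children[0])
    rng_annot = np.random.default_rng(children[1])
    track_streams = children[2:]

    truth_ivs = _place_disjoint(
        rng_truth, scenario.genome, scenario.n_true, scenario.true_len_range
    )
    truth = PeakDataset(
        name="truth",
        track_type="Histone",
        peaks=[Peak(iv, signal=1.0) for iv in truth_ivs],
    )
    truth_fp = _footprint(truth_ivs)

    annotations = _plant_annotations(rng_annot, scenario, truth_fp)
    annot_fp = _footprint(annotations.all_intervals())

    mu, sigma = scenario.signal_law
    datasets: dict[str, PeakDataset] = {}
    for ti in range(scenario.n_tracks):
        track_type = _DEFAULT_TRACKS[ti]
        ds_streams = track_streams[ti].spawn(scenario.n_datasets_per_track)
        for di in range(scenario.n_datasets_per_track):
            rng = np.random.default_rng(ds_streams[di])
            peaks: list[Peak] = []
            # imperfect observation of each planted enhancer
            for iv in truth_ivs:
                if rng.random() > scenario.sensitivity:
                    continue
                center = (iv.start + iv.end) / 2 + rng.normal(
                    0.0, scenario.jitter_sd
                )
                width = max(
                    50,
                    round(iv.length + rng.normal(0.0, scenario.width_jitter_sd)),
                )
                start = max(0, round(center - width / 2))
                peaks.append(
                    Peak(
                        GenomicInterval(iv.chrom, start, start + width),
                        signal=float(rng.lognormal(mu, sigma)),
                    )
                )
            # track-independent spurious calls in intergenic space
            n_noise = int(rng.poisson(scenario.noise_rate * scenario.n_true))
            peaks.extend(
                _noise_peaks(rng, scenario, n_noise, truth_fp, mu, sigma)
            )
            name = f"{track_type}_ds{di + 1}"
            datasets[name] = PeakDataset(
                name=name, track_type=track_type, peaks=peaks
            )
    return truth, datasets, annotations


def _plant_annotations(
    rng: np.random.Generator,
    scenario: SyntheticScenario,
    truth_fp: dict[str, np.ndarray],
) -> AnnotationSet:
    """Drop promoter/exon/insulator intervals clear of the truth set.

    A 2 kb margin keeps annotations from clipping jittered true peaks, so
    annotation exclusion removes only noise."""
    def sample(n: int) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        chroms = scenario.genome
        total = sum(l for _, l in chroms)
        attempts = 0
        while len(out) < n and attempts < 50 * n:
            attempts += 1
            r = rng.integers(0, total)
            for chrom, clen in chroms:
                if r < clen:
                    break
                r -= clen
            length = int(rng.integers(*scenario.annotation_len_range))
            start = int(min(r, clen - length))
            if _hits_footprint(chrom, start, start + length, truth_fp,
                               margin=2000):
                continue
            out.append(GenomicInterval(chrom, start, start + length))
        return out

    return AnnotationSet(
        promoters=sample(scenario.n_promoters),
        exons=sample(scenario.n_exons),
        insulators=sample(scenario.n_insulators),
    )


def _noise_peaks(
    rng: np.random.Generator,
    scenario: SyntheticScenario,
    n: int,
    truth_fp: dict[str, np.ndarray],
    mu: float,
    sigma: float,
) -> list[Peak]:
    out: list[Peak] = []
    chroms = scenario.genome
    total = sum(l for _, l in chroms)
    attempts = 0
    while len(out) < n and attempts < 50 * max(n, 1):
        attempts += 1
        r = int(rng.integers(0, total))
        for chrom, clen in chroms:
            if r < clen:
                break
            r -= clen
        length = int(rng.integers(*scenario.true_len_range))
        start = min(r, clen - length)
        if _hits_footprint(chrom, start, start + length, truth_fp):
            continue  # noise must stay noise: never overlap a true enhancer
        out.append(
            Peak(
                GenomicInterval(chrom, start, start + length),
                signal=float(rng.lognormal(mu, sigma)),
            )
        )
    return out


def score_against_truth(
    consensus: ConsensusTrack | PeakDataset,
    truth: PeakDataset,
) -> tuple[float, float]:
    """Precision and recall of a called set against planted enhancers.

    Recall = fraction of truth enhancers overlapped (>= 1 bp) by at least
    one called peak; precision = fraction of called peaks overlapping at
    least one truth enhancer. Empty truth yields NaN recall with a
    warning; an empty call set yields precision NaN by the same logic
    (0 calls, nothing to be wrong about) and recall 0.
    """
    called = [
        (p.interval.chrom, p.interval.start, p.interval.end)
        for p in consensus.peaks
    ]
    truth_ivs = [(p.chrom, p.start, p.end) for p in truth.peaks]
    if not truth_ivs:
        logger.warning("empty truth set: recall undefined")
        return (1.0 if not called else 0.0, float("nan"))
    called_fp = _footprint(
        [GenomicInterval(c, s, e) for c, s, e in called]
    )
    truth_fp = _footprint([GenomicInterval(c, s, e) for c, s, e in truth_ivs])
    recall_hits = sum(
        _hits_footprint(c, s, e, called_fp) for c, s, e in truth_ivs
    )
    recall = recall_hits / len(truth_ivs)
    if not called:
        return float("nan"), 0.0
    prec_hits = sum(
        _hits_footprint(c, s, e, truth_fp) for c, s, e in called
    )
    return prec_hits / len(called), recall


def write_scenario(
    scenario: SyntheticScenario, outdir: Path
) -> tuple[Path, Path]:
    """Materialize a scenario on disk: truth BED, dataset BEDs, manifest
    TSV and annotation BEDs. Returns (manifest path, truth path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, datasets, annotations = generate_scenario(scenario)
    truth_path = outdir / "truth.bed"
    eio.write_bed(truth, truth_path)
    manifest_lines = []
    for name, ds in datasets.items():
        p = outdir / f"{name}.bed"
        eio.write_bed(ds, p)
        manifest_lines.append(f"{p.name}\t{ds.track_type}\tbed")
    manifest_path = outdir / "manifest.tsv"
    manifest_path.write_text("\n".join(manifest_lines) + "\n")
    for attr in ("promoters", "exons", "insulators"):
        ivs = getattr(annotations, attr)
        ds = PeakDataset(
            name=attr, track_type="Histone",
            peaks=[Peak(iv) for iv in ivs],
        )
        eio.write_bed(ds, outdir / f"{attr}.bed")
    return manifest_path, truth_path
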