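"""End-to-end composition: filters -> normalization -> track assembly ->
similarity/weights -> consensus, with full audit output."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as eio
from .assembly import assemble_track
from .consensus import (
    ConsensusTrack,
    SimilarityMatrix,
    TrackWeights,
    build_consensus,
    similarity_matrix,
    track_weights,
)
from .core import AnnotationSet, PeakDataset, TRACK_TYPES, Track
from .preprocess import (
    FilterReport,
    MAX_DATASET_COVERAGE,
    MAX_PEAK_LENGTH,
    MIN_DATASET_COVERAGE,
    preprocess_dataset,
    reports_to_rows,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the consensus pipeline, mirroring the CLI flags."""

    max_peak_len: int = MAX_PEAK_LENGTH
    min_cov: int = MIN_DATASET_COVERAGE
    max_cov: int = MAX_DATASET_COVERAGE
    min_support_fraction: float = 0.5
    jaccard_mode: str = "regions"
    score_overlap: str = "full"
    cell_type: str = "consensus"


@dataclass
class PipelineResult:
    consensus: ConsensusTrack
    tracks: list[Track]
    reports: list[FilterReport]
    similarity: SimilarityMatrix
    weights: TrackWeights

    def summary(self) -> dict:
        return {
            "cell_type": self.consensus.cell_type,
            "n_tracks": len(self.tracks),
            "track_types": [t.track_type for t in self.tracks],
            "weights": self.weights.weights,
            "n_consensus_peaks": len(self.consensus),
            "n_datasets_in": len(self.reports),
            "n_datasets_dropped": sum(
                r.dataset_dropped for r in self.reports
            ),
        }


def run_pipeline(
    datasets: Sequence[PeakDataset],
    annotations: Optional[AnnotationSet] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full consensus pipeline on in-memory datasets.

    Datasets are filtered and normalized individually, grouped by
    ``track_type`` and ASW-merged into tracks; tracks emptied by filtering
    are dropped before ``m`` is counted. Requires >= 2 surviving tracks
    (>= 3 recommended; a warning is logged below that, and with exactly 2
    tracks every consensus enhancer must be supported by both).
    """
    config = config or PipelineConfig()
    reports: list[FilterReport] = []
    surviving: dict[str, list[PeakDataset]] = {}
    for ds in datasets:
        clean, report = preprocess_dataset(
            ds,
            annotations=annotations,
            max_len=config.max_peak_len,
            min_cov=config.min_cov,
            max_cov=config.max_cov,
        )
        reports.append(report)
        if clean is not None:
            surviving.setdefault(clean.track_type, []).append(clean)

    # deterministic track order: the canonical evidence-type order
    tracks = [
        assemble_track(surviving[t]) for t in TRACK_TYPES if t in surviving
    ]
    tracks = [t for t in tracks if t.peaks]
    m = len(tracks)
    if m < 2:
        raise ValueError(
            f"consensus requires >= 2 non-empty tracks after filtering, got {m}"
        )
    if m == 2:
        logger.warning(
            "only 2 tracks available: consensus enhancers must be "
            "supported by both tracks"
        )
    elif m < 3:
        logger.warning("fewer than 3 tracks; consensus may be unreliable")

    S = similarity_matrix(tracks, mode=config.jaccard_mode)
    W = track_weights(S)
    consensus = build_consensus(
        tracks,
        W,
        min_support_fraction=config.min_support_fraction,
        cell_type=config.cell_type,
        similarity=S,
        score_overlap=config.score_overlap,
    )
    logger.info(
        "consensus: %d enhancers from %d tracks (weights %s)",
        len(consensus), m,
        {k: round(v, 4) for k, v in W.weights.items()},
    )
    return PipelineResult(
        consensus=consensus,
        tracks=tracks,
        reports=reports,
        similarity=S,
        weights=W,
    )


def write_outputs(
    result: PipelineResult,
    outdir: Path,
    emit_intermediate: bool = False,
) -> None:
    """Write consensus BED, similarity TSV, weights TSV, filter-report TSV
    and a JSON run summary into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eio.write_bed(result.consensus, outdir / "consensus.bed")
    sim = pd.DataFrame(
        result.similarity.J,
        index=result.similarity.track_ids,
        columns=result.similarity.track_ids,
    )
    sim.to_csv(outdir / "similarity.tsv", sep="\t", float_format="%.6g")
    pd.Series(result.weights.weights, name="weight").rename_axis(
        "track"
    ).to_csv(outdir / "weights.tsv", sep="\t", float_format="%.6g")
    pd.DataFrame(reports_to_rows(result.reports)).to_csv(
        outdir / "filter_report.tsv", sep="\t", index=False
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if emit_intermediate:
        for t in result.tracks:
            ds = PeakDataset(
                name=t.track_type, track_type=t.track_type,
                peaks=list(t.peaks), normalized=True,
            )
            eio.write_bed(ds, outdir / f"track_{t.track_type}.bed")


def run_from_manifest(
    manifest_path: Path,
    annotations: Optional[AnnotationSet] = None,
    config: Optional[PipelineConfig] = None,
    signal_column: Optional[int] = 5,
) -> PipelineResult:
    """Load datasets listed in a manifest TSV and run the pipeline."""
    entries = eio.read_manifest(manifest_path)
    datasets = [
        eio.load_dataset(p, track_type=t, fmt=fmt)
        if fmt == "narrowpeak"
        else eio.read_bed(p, track_type=t, signal_column=signal_column)
        for p, t, fmt in entries
    ]
    return run_pipeline(datasets, annotations=annotations, config=config)
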