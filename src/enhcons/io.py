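"""Readers and writers for BED / narrowPeak interval files.

Every reader emits 0-based half-open coordinates, the native convention of
BED and narrowPeak. GFF-style 1-based inclusive input is handled only via
the explicit ``one_based=True`` flag of :func:`read_bed`, which shifts
starts by -1; nothing is converted silently. Files ending in ``.gz`` are
transparently decompressed.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import IO, Iterator, Optional, Union

from .core import GenomicInterval, Peak, PeakDataset, sort_peaks

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("#", "track", "browser")


class BedFormatError(ValueError):
    """A malformed line in a BED/narrowPeak file, with its line number."""


def _open_text(path: Union[str, Path]) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _data_lines(handle: IO[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith(_SKIP_PREFIXES):
            continue
        yield lineno, line.split("\t")


def _parse_coords(fields: list[str], lineno: int) -> GenomicInterval:
    try:
        start = int(fields[1])
        end = int(fields[2])
    except ValueError as exc:
        raise BedFormatError(
            f"line {lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
        ) from exc
    if start < 0:
        raise BedFormatError(f"line {lineno}: negative start {start}")
    if end <= start:
        raise BedFormatError(f"line {lineno}: end {end} <= start {start}")
    return GenomicInterval(fields[0], start, end)


def read_bed(
    path: Union[str, Path],
    name: Optional[str] = None,
    track_type: str = "Histone",
    signal_column: Optional[int] = 5,
    one_based: bool = False,
    chrom_prefix: Optional[str] = None,
) -> PeakDataset:
    """Read a BED3/BED5/BED6 file into a :class:`PeakDataset`.

    Parameters
    ----------
    signal_column
        1-based column index holding the per-peak fold enrichment
        (default 5, the BED "score" column). Rows lacking that column get
        signal 1.0. Pass ``None`` to force all signals to 1.0.
    one_based
        Treat coordinates as 1-based inclusive (GFF convention) and shift
        starts by -1. Off by default; BED input is never reinterpreted.
    chrom_prefix
        When given (e.g. ``"chr"``), prepend it to chromosome names that
        do not already carry it. Off by default.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 3:
                raise BedFormatError(
                    f"line {lineno}: expected >= 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            iv = _parse_coords(fields, lineno)
            if one_based:
                iv = GenomicInterval(iv.chrom, iv.start - 1, iv.end)
            if chrom_prefix and not iv.chrom.startswith(chrom_prefix):
                iv = GenomicInterval(chrom_prefix + iv.chrom, iv.start, iv.end)
            signal = 1.0
            if signal_column is not None and len(fields) >= signal_column:
                try:
                    signal = float(fields[signal_column - 1])
                except ValueError as exc:
                    raise BedFormatError(
                        f"line {lineno}: non-numeric signal in column "
                        f"{signal_column}: {fields[signal_column - 1]!r}"
                    ) from exc
            peaks.append(Peak(iv, signal=signal))
    if not peaks:
        logger.warning("BED file %s contains no data lines", path)
    return PeakDataset(name=name or path.stem, track_type=track_type, peaks=peaks)


def read_narrowpeak(
    path: Union[str, Path],
    name: Optional[str] = None,
    track_type: str = "Histone",
    chrom_prefix: Optional[str] = None,
) -> PeakDataset:
    """Read a 10-column ENCODE narrowPeak file.

    Signal is taken from column 7 (signalValue); the summit offset from
    column 10, with the conventional -1 meaning "no summit called".
    """
    path = Path(path)
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) != 10:
                raise BedFormatError(
                    f"line {lineno}: expected 10 columns, got {len(fields)}"
                )
            iv = _parse_coords(fields, lineno)
            if chrom_prefix and not iv.chrom.startswith(chrom_prefix):
                iv = GenomicInterval(chrom_prefix + iv.chrom, iv.start, iv.end)
            try:
                signal = float(fields[6])
                summit_raw = int(fields[9])
            except ValueError as exc:
                raise BedFormatError(
                    f"line {lineno}: non-numeric signalValue/peak column"
                ) from exc
            summit = summit_raw if summit_raw >= 0 else None
            peaks.append(Peak(iv, signal=signal, summit=summit))
    if not peaks:
        logger.warning("narrowPeak file %s contains no data lines", path)
    return PeakDataset(name=name or path.stem, track_type=track_type, peaks=peaks)


def _fmt_score(x: float) -> str:
    # 6 significant digits; stable under a write -> read -> write round trip
    return format(float(x), ".6g")


def write_bed(obj, path: Union[str, Path]) -> None:
    """Write a :class:`PeakDataset` or a consensus track as sorted BED.

    Peak datasets become BED5 (name column = running index, score column =
    signal). Consensus tracks put the comma-joined supporting-track list in
    column 4 and the combined score in column 5. Output is deterministic:
    writing the same object twice yields byte-identical files, and scores
    survive a read/write round trip to 6 significant digits.
    """
    path = Path(path)
    lines: list[str] = []
    # consensus tracks expose .peaks of ConsensusPeak with supporting_tracks
    peaks = getattr(obj, "peaks", obj)
    for i, p in enumerate(peaks):
        if hasattr(p, "supporting_tracks"):
            name_col = ",".join(sorted(p.supporting_tracks))
            score = p.score
        else:
            name_col = f"peak_{i + 1}"
            score = p.signal
        lines.append(
            f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
            f"\t{name_col}\t{_fmt_score(score)}"
        )
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for line in lines:
            fh.write(line + "\n")


def read_manifest(path: Union[str, Path]) -> list[tuple[Path, str, str]]:
    """Read a TSV manifest mapping dataset files to evidence tracks.

    Each line: ``<path>\t<track_type>[\t<format>]`` where format is
    ``bed`` (default) or ``narrowpeak``. Relative paths resolve against
    the manifest's directory. Comment lines start with ``#``.
    """
    path = Path(path)
    entries: list[tuple[Path, str, str]] = []
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 2:
                raise BedFormatError(
                    f"manifest line {lineno}: expected '<path>\\t<track_type>'"
                )
            fpath = Path(fields[0])
            if not fpath.is_absolute():
                fpath = path.parent / fpath
            fmt = fields[2].lower() if len(fields) >= 3 else "bed"
            if fmt not in ("bed", "narrowpeak"):
                raise BedFormatError(
                    f"manifest line {lineno}: unknown format {fmt!r}"
                )
            entries.append((fpath, fields[1], fmt))
    return entries


def load_dataset(path: Union[str, Path], track_type: str, fmt: str = "bed",
                 **kw) -> PeakDataset:
    """Dispatch to :func:`read_bed` or :func:`read_narrowpeak` by format."""
    if fmt == "narrowpeak":
        return read_narrowpeak(path, track_type=track_type, **kw)
    return read_bed(path, track_type=track_type, **kw)
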