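import numpy as np
import pytest
from hypothesis import settings

from enhcons import GenomicInterval, Peak, PeakDataset, Track

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def mkpeak(chrom, start, end, signal=1.0, summit=None):
    return Peak(GenomicInterval(chrom, start, end), signal=signal, summit=summit)


def mkds(peaks, name="ds", track_type="Histone", normalized=False):
    return PeakDataset(
        name=name, track_type=track_type, peaks=list(peaks),
        normalized=normalized,
    )


def mktrack(peaks, track_type="Histone"):
    return Track(track_type=track_type, peaks=list(peaks))


def random_track(rng, track_type="Histone", max_peaks=50, coord_bound=10_000):
    """A random (possibly internally overlapping) peak track."""
    n = int(rng.integers(0, max_peaks + 1))
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, coord_bound - 1))
        length = int(rng.integers(1, 200))
        peaks.append(mkpeak("chr1", start, start + length,
                            signal=float(rng.uniform(0.1, 5.0))))
    return mktrack(peaks, track_type=track_type)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
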