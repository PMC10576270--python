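import numpy as np
import pytest

from chromrecall.core import GenomicInterval, Peak
from chromrecall.simulate import SimConfig, simulate_dataset


def make_peak(chrom, start, end, summit=None, signal=0.0, source="", name=""):
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        summit=(start + end) // 2 if summit is None else summit,
        signal=signal,
        source=source,
        name=name,
    )


def random_peaks(rng, n, chroms=("chr1", "chr2", "chr3"), max_pos=100_000):
    peaks = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, 500))
        summit = start + int(rng.integers(width))
        peaks.append(
            make_peak(chrom, start, start + width, summit, float(rng.random()), name=f"p{i}")
        )
    return peaks


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset at the default study conditions."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """High-SNR variant: open loci at 10x threshold, closed at 0x."""
    cfg = SimConfig(seed=7, open_density_multiple=10.0, closed_density_multiple=0.0)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
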