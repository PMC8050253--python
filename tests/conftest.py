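import warnings

import numpy as np
import pytest

from episieve.core import GenomicInterval, Peak, PeakSet
from episieve.simulate import SimulationConfig, generate_dataset


def make_peakset(intervals, label="", chrom_default="chr1"):
    """PeakSet from (start, end) or (chrom, start, end) tuples."""
    peaks = []
    for iv in intervals:
        if len(iv) == 2:
            chrom, (start, end) = chrom_default, iv
        else:
            chrom, start, end = iv
        peaks.append(Peak(GenomicInterval(chrom, start, end)))
    return PeakSet(peaks, label=label)


def random_canonical(rng, n_max=50, coord_max=10_000, chroms=("chr1", "chr2")):
    """A random canonical peak set on a small genome."""
    intervals = []
    for chrom in chroms:
        n = int(rng.integers(0, n_max // len(chroms) + 1))
        if n == 0:
            continue
        cuts = np.sort(rng.choice(coord_max, size=2 * n, replace=False))
        for s, e in zip(cuts[0::2], cuts[1::2]):
            if e > s:
                intervals.append((chrom, int(s), int(e)))
    # enforce canonical by dropping overlapping/bookended successors
    kept, last_end = [], {}
    for chrom, s, e in sorted(intervals):
        if s > last_end.get(chrom, -1):
            kept.append((chrom, s, e))
            last_end[chrom] = e
    return kept


@pytest.fixture(scope="session")
def noise_free_dataset():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(SimulationConfig(seed=11).noise_free())


@pytest.fixture(scope="session")
def noisy_dataset():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(SimulationConfig(seed=11))
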