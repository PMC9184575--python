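"""Shared fixtures and independent brute-force oracles.

The oracles deliberately work at per-base resolution with plain loops and
never call the package's binned-coverage code paths.
"""

import numpy as np
import pandas as pd
import pytest

from promindex.coverage import CoverageTrack, NormalizedTrack
from promindex.genome_io import FragmentSet, GeneModel, GeneSet


def perbase_coverage(fragments: list[tuple[int, int]], length: int) -> np.ndarray:
    """Per-base fragment depth by direct accumulation."""
    d = np.zeros(length)
    for s, e in fragments:
        d[max(0, s) : min(length, e)] += 1
    return d


def perbase_mean(d: np.ndarray, start: float, end: float) -> float:
    """Mean of a per-base signal over [start, end), fractional ends allowed;
    positions outside the array contribute zero signal."""
    total = 0.0
    lo, hi = int(np.floor(start)), int(np.ceil(end))
    for p in range(lo, hi):
        if p < 0 or p >= d.size:
            continue
        frac = min(p + 1.0, end) - max(float(p), start)
        total += d[p] * frac
    return total / (end - start)


def constant_track(
    chromsizes: dict[str, int], density: float, binsize: int = 50
) -> NormalizedTrack:
    """Noise-free track with uniform per-base density everywhere."""
    data = {}
    for chrom, L in chromsizes.items():
        nbins = -(-L // binsize)
        widths = np.full(nbins, float(binsize))
        widths[-1] = L - (nbins - 1) * binsize
        data[chrom] = density * widths
    return NormalizedTrack(binsize, chromsizes, data)


def track_from_bin_values(
    values: np.ndarray, chrom: str = "chr1", binsize: int = 50
) -> NormalizedTrack:
    """Track whose bins hold the given fragment-base values directly."""
    L = len(values) * binsize
    return NormalizedTrack(binsize, {chrom: L}, {chrom: np.asarray(values, float)})


def fragset(
    intervals: list[tuple[int, int]],
    chrom: str = "chr1",
    n_spikein: int = 0,
    spike_chrom: str = "spikein_chr",
) -> FragmentSet:
    rows = [(chrom, s, e, "sample") for s, e in intervals]
    rows += [(spike_chrom, 10 * i, 10 * i + 100, "spikein") for i in range(n_spikein)]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "ref_class"])
    df["sample_id"] = ""
    return FragmentSet(df)


@pytest.fixture
def two_gene_set() -> GeneSet:
    return GeneSet(
        [
            GeneModel("geneA", "chr1", 10_000, 20_000, "+"),
            GeneModel("geneB", "chr1", 40_000, 46_000, "-"),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
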