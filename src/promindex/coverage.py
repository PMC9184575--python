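"""Binned fragment coverage and exogenous spike-in normalization.

A coverage track stores, per chromosome, the number of fragment-bases
falling in each fixed-width bin. Spike-in normalization rescales every bin
by ``constant / spikein_reads`` (reference-adjusted reads per million when
the constant is 1e6), making signal comparable between samples sequenced at
different depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .genome_io import FragmentSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleFactor",
    "CoverageTrack",
    "NormalizedTrack",
    "compute_scale_factor",
    "fragments_to_coverage",
    "normalize",
    "normalized_coverage",
]


@dataclass(frozen=True)
class ScaleFactor:
    """Spike-in scale factor: constant / spike-in read count."""

    spikein_reads: int
    constant: float = 1_000_000.0

    def __post_init__(self) -> None:
        if self.spikein_reads <= 0:
            raise ValueError(
                "spike-in read count must be positive; for libraries without "
                "spike-in material use the no-spike-in mode "
                "(normalized_coverage(..., no_spikein=True))"
            )

    @property
    def value(self) -> float:
        v = self.constant / self.spikein_reads
        if not np.isfinite(v) or v <= 0:
            raise ValueError("scale factor must be positive and finite")
        return v


def compute_scale_factor(spikein_reads: int, constant: float = 1_000_000.0) -> ScaleFactor:
    return ScaleFactor(spikein_reads=spikein_reads, constant=constant)


class CoverageTrack:
    """Per-chromosome binned fragment-base counts.

    Bin ``k`` of a chromosome covers ``[k*binsize, min((k+1)*binsize, L))``
    and stores the total number of fragment-bases overlapping it, so the sum
    over all bins equals the total clipped fragment length. The per-base
    *density* of a bin is its value divided by the bin width.
    """

    def __init__(
        self,
        binsize: int,
        chromsizes: Mapping[str, int],
        data: dict[str, np.ndarray] | None = None,
    ):
        if binsize < 1:
            raise ValueError("binsize must be >= 1")
        self.binsize = int(binsize)
        self.chromsizes = dict(chromsizes)
        self.data: dict[str, np.ndarray] = {}
        for chrom, length in self.chromsizes.items():
            nbins = -(-length // self.binsize)  # ceil
            if data is not None and chrom in data:
                arr = np.asarray(data[chrom], dtype=float)
                if arr.shape != (nbins,):
                    raise ValueError(
                        f"{chrom}: expected {nbins} bins, got {arr.shape}"
                    )
                self.data[chrom] = arr
            else:
                self.data[chrom] = np.zeros(nbins)
        self._cum: dict[str, np.ndarray] = {}

    # -- construction ------------------------------------------------------

    def add_fragments(self, starts: np.ndarray, ends: np.ndarray, chrom: str) -> None:
        """Accumulate fragment-base counts for intervals on one chromosome."""
        if chrom not in self.data:
            raise KeyError(f"fragment on unknown chromosome {chrom!r}")
        L = self.chromsizes[chrom]
        bs = self.binsize
        v = self.data[chrom]
        nbins = v.shape[0]
        s = np.clip(np.asarray(starts, dtype=np.int64), 0, L)
        e = np.clip(np.asarray(ends, dtype=np.int64), 0, L)
        keep = e > s
        s, e = s[keep], e[keep]
        if s.size == 0:
            return
        fb = s // bs
        lb = (e - 1) // bs
        same = fb == lb
        # fragments contained in a single bin
        v += np.bincount(fb[same], weights=(e[same] - s[same]), minlength=nbins)
        # fragments spanning several bins: partial first/last, full middles
        fs_, ls_, fb_, lb_ = s[~same], e[~same], fb[~same], lb[~same]
        if fs_.size:
            v += np.bincount(fb_, weights=(fb_ + 1) * bs - fs_, minlength=nbins)
            v += np.bincount(lb_, weights=ls_ - lb_ * bs, minlength=nbins)
            run = lb_ - fb_ > 1
            if run.any():
                d = np.bincount(
                    fb_[run] + 1, minlength=nbins + 1
                ) - np.bincount(lb_[run], minlength=nbins + 1)
                v += float(bs) * np.cumsum(d[:-1])
        self._cum.clear()

    # -- queries -----------------------------------------------------------

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def _bin_widths(self, chrom: str) -> np.ndarray:
        L = self.chromsizes[chrom]
        nbins = self.data[chrom].shape[0]
        w = np.full(nbins, float(self.binsize))
        w[-1] = L - (nbins - 1) * self.binsize
        return w

    def _cumulative(self, chrom: str) -> np.ndarray:
        if chrom not in self._cum:
            self._cum[chrom] = np.concatenate(
                ([0.0], np.cumsum(self.data[chrom]))
            )
        return self._cum[chrom]

    def _integral_upto(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Fragment-bases in [0, pos), treating each bin as uniform."""
        L = self.chromsizes[chrom]
        bs = self.binsize
        p = np.clip(np.asarray(pos, dtype=float), 0, L)
        cum = self._cumulative(chrom)
        v = self.data[chrom]
        w = self._bin_widths(chrom)
        k = np.minimum((p // bs).astype(np.int64), v.shape[0] - 1)
        frac = (p - k * bs) / w[k]
        return cum[k] + v[k] * frac

    def mean_density(self, chrom: str, start, end) -> np.ndarray | float:
        """Mean per-base signal over [start, end).

        Intervals extending past the chromosome contribute zero signal for
        the out-of-bounds part but the nominal width still divides, so a
        clipped flank reads as diluted rather than truncated.
        """
        if chrom not in self.data:
            raise KeyError(f"unknown chromosome {chrom!r}")
        a = np.asarray(start, dtype=float)
        b = np.asarray(end, dtype=float)
        if np.any(b <= a):
            raise ValueError("region end must exceed start")
        mass = self._integral_upto(chrom, b) - self._integral_upto(chrom, a)
        out = mass / (b - a)
        return out if out.shape else float(out)

    def densities(self) -> dict[str, np.ndarray]:
        """Per-base density per bin (value / bin width), by chromosome."""
        return {c: self.data[c] / self._bin_widths(c) for c in self.data}

    def iter_bedgraph(self) -> Iterator[tuple[str, int, int, float]]:
        """Yield (chrom, start, end, per-base density) rows, one per bin."""
        for chrom, v in self.data.items():
            L = self.chromsizes[chrom]
            w = self._bin_widths(chrom)
            for k in range(v.shape[0]):
                start = k * self.binsize
                yield chrom, start, min(start + self.binsize, L), v[k] / w[k]

    def _like(self, data: dict[str, np.ndarray]) -> "CoverageTrack":
        return type(self)(self.binsize, self.chromsizes, data)


class NormalizedTrack(CoverageTrack):
    """Coverage scaled by a spike-in factor (units: Norm. RRPM-like)."""

    def __init__(self, binsize, chromsizes, data=None, scale_factor: float = 1.0):
        super().__init__(binsize, chromsizes, data)
        self.scale_factor = float(scale_factor)


def fragments_to_coverage(
    fs: FragmentSet,
    chromsizes: Mapping[str, int],
    binsize: int = 50,
    sample_only: bool = True,
) -> CoverageTrack:
    """Bin sample fragments into a CoverageTrack over ``chromsizes``.

    Spike-in fragments are excluded by default: only the chromosomes in
    ``chromsizes`` are binned, and a sample fragment naming an unknown
    chromosome is an error.
    """
    track = CoverageTrack(binsize, chromsizes)
    df = fs.df
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    keep = (
        (df["ref_class"] == "sample").to_numpy()
        if sample_only
        else np.ones(len(df), dtype=bool)
    )
    chrom_col = df["chrom"]
    if isinstance(chrom_col.dtype, pd.CategoricalDtype):
        codes = chrom_col.cat.codes.to_numpy()
        cats = list(chrom_col.cat.categories)
    else:
        cats, codes = np.unique(chrom_col.to_numpy(), return_inverse=True)
        cats = list(cats)
    for k, chrom in enumerate(cats):
        mask = keep & (codes == k)
        if mask.any():
            track.add_fragments(starts[mask], ends[mask], str(chrom))
    return track


def normalize(track: CoverageTrack, factor: ScaleFactor | float) -> NormalizedTrack:
    """Scale every bin by the spike-in factor."""
    value = factor.value if isinstance(factor, ScaleFactor) else float(factor)
    if value <= 0:
        raise ValueError("scale factor must be positive")
    data = {c: v * value for c, v in track.data.items()}
    return NormalizedTrack(track.binsize, track.chromsizes, data, scale_factor=value)


def normalized_coverage(
    fs: FragmentSet,
    chromsizes: Mapping[str, int],
    binsize: int = 50,
    constant: float = 1_000_000.0,
    no_spikein: bool = False,
) -> NormalizedTrack:
    """Fragments → spike-in-normalized coverage in one step.

    With ``no_spikein=True`` the factor is constant / sample_reads instead,
    a guard against over-normalization when spike-in recovery is unreliable.
    """
    sample_reads, spikein_reads = fs.count_by_ref_class()
    if no_spikein:
        if sample_reads <= 0:
            raise ValueError("no sample fragments to normalize by")
        factor = constant / sample_reads
    else:
        factor = compute_scale_factor(spikein_reads, constant).value
    track = fragments_to_coverage(fs, chromsizes, binsize)
    logger.info(
        "normalized coverage: %d sample, %d spike-in fragments, factor %.6g",
        sample_reads,
        spikein_reads,
        factor,
    )
    return normalize(track, factor)
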