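"""Peak calling, peak-overlap testing, and occupancy/expression association.

The peak caller is a transparent quantile-threshold-and-merge procedure:
bins above a genome-wide signal quantile are merged across gaps up to
``merge_gap`` and runs shorter than ``min_width`` are dropped. It is
deliberately simple — every downstream operation also accepts externally
called peaks in BED form, so production peak callers can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .coverage import CoverageTrack
from .genome_io import Region

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "OverlapResult",
    "CorrelationResult",
    "call_peaks_simple",
    "read_peaks_bed",
    "overlap_test",
    "promoter_signal_table",
    "correlate",
    "delta_vs_occupancy",
    "rpkm",
    "de_genes",
]


@dataclass
class PeakSet:
    """Sorted, non-overlapping peak intervals with a mean-signal score."""

    df: pd.DataFrame  # columns: chrom, start, end, score
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def trees(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False, observed=True):
            out[str(chrom)] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"])
            )
        return out

    def to_bed(self, path) -> None:
        """BED6 with the score rescaled to 0-1000 in column 5 and the exact
        mean signal kept in column 7."""
        df = self.df.sort_values(["chrom", "start"]).reset_index(drop=True)
        smax = df["score"].max() if len(df) else 1.0
        scaled = (
            np.zeros(len(df), dtype=int)
            if not len(df) or smax <= 0
            else np.minimum(1000, (1000 * df["score"] / smax).round().astype(int))
        )
        with open(path, "w") as fh:
            for i, row in enumerate(df.itertuples(index=False)):
                fh.write(
                    f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\tpeak_{i+1}\t"
                    f"{scaled[i]}\t.\t{row.score:.10g}\n"
                )


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float
    slope_stderr: float


def call_peaks_simple(
    track: CoverageTrack,
    threshold_quantile: float = 0.99,
    min_width: int = 200,
    merge_gap: int = 150,
) -> PeakSet:
    """Quantile-threshold peak caller over a (normalized) coverage track.

    Bins with density strictly above the genome-wide ``threshold_quantile``
    are candidate peak bins; adjacent or nearby candidates (gap <=
    merge_gap bases) merge into one interval; intervals narrower than
    ``min_width`` are dropped. The peak score is the mean density over the
    interval. An all-zero track yields an empty PeakSet.
    """
    dens = track.densities()
    allvals = np.concatenate([v for v in dens.values()]) if dens else np.array([0.0])
    thr = float(np.quantile(allvals, threshold_quantile))
    bs = track.binsize
    records = []
    for chrom, d in dens.items():
        above = d > thr
        if not above.any():
            continue
        idx = np.flatnonzero(above)
        # group candidate bins whose gap is <= merge_gap bases
        breaks = np.flatnonzero((idx[1:] - idx[:-1] - 1) * bs > merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        L = track.chromsizes[chrom]
        for a, b in zip(starts, ends):
            s = int(idx[a]) * bs
            e = min((int(idx[b]) + 1) * bs, L)
            if e - s < min_width:
                continue
            records.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "score": float(track.mean_density(chrom, s, e)),
                }
            )
    df = pd.DataFrame.from_records(
        records, columns=["chrom", "start", "end", "score"]
    )
    params = {
        "threshold_quantile": threshold_quantile,
        "threshold_value": thr,
        "min_width": min_width,
        "merge_gap": merge_gap,
    }
    logger.info("called %d peaks (threshold %.4g)", len(df), thr)
    return PeakSet(df, params)


def read_peaks_bed(path) -> PeakSet:
    """Import externally called peaks from BED3+ (score optional, column 5)."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
            records.append(
                {"chrom": f[0], "start": int(f[1]), "end": int(f[2]), "score": score}
            )
    return PeakSet(pd.DataFrame.from_records(records, columns=["chrom", "start", "end", "score"]),
                   {"source": str(path)})


def _overlaps(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> bool:
    t = trees.get(chrom)
    return bool(t is not None and t.overlap(start, end))


def overlap_test(
    a: PeakSet, b: PeakSet, universe: Sequence[Region]
) -> OverlapResult:
    """Two-sided Fisher's exact test on peak co-occurrence over a universe.

    Each universe region is classified by whether it intersects at least one
    A peak and at least one B peak; the resulting 2x2 table is tested with
    Fisher's exact test. The universe (e.g. all promoters, or genome bins)
    must be stated explicitly — the test is only meaningful relative to it.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    ta, tb = a.trees(), b.trees()
    in_a = np.array([_overlaps(ta, r.chrom, r.start, r.end) for r in universe])
    in_b = np.array([_overlaps(tb, r.chrom, r.start, r.end) for r in universe])
    table = (
        (int((in_a & in_b).sum()), int((in_a & ~in_b).sum())),
        (int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())),
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    n_overlap = sum(
        _overlaps(tb, row.chrom, row.start, row.end)
        for row in a.df.itertuples(index=False)
    )
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_overlap=int(n_overlap),
        universe=len(universe),
        table=table,
        odds_ratio=float(odds),
        p_value=float(p),
    )


def promoter_signal_table(
    tracks: Mapping[str, CoverageTrack],
    promoters: Sequence[Region],
    restrict_to: PeakSet | None = None,
) -> pd.DataFrame:
    """Mean normalized signal per promoter (rows) per track (columns).

    With ``restrict_to``, only promoters overlapping at least one peak are
    kept — the device used to focus correlations on marked promoters.
    """
    kept = list(promoters)
    if restrict_to is not None:
        trees = restrict_to.trees()
        kept = [r for r in kept if _overlaps(trees, r.chrom, r.start, r.end)]
    if not kept:
        raise ValueError("no promoters left after peak restriction")
    data = {}
    for name, track in tracks.items():
        data[name] = [track.mean_density(r.chrom, r.start, r.end) for r in kept]
    return pd.DataFrame(data, index=[r.name for r in kept])


def correlate(x, y, log_transform: bool = False, eps: float = 1e-3) -> CorrelationResult:
    """Pearson correlation with a least-squares line fit.

    The p-value is the standard two-sided t-distribution transform of R.
    ``log_transform`` applies log10(x + eps) to both vectors first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if log_transform:
        x = np.log10(x + eps)
        y = np.log10(y + eps)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=int(x.size),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_stderr=float(fit.stderr),
    )


def delta_vs_occupancy(delta: pd.Series, occupancy: pd.Series, **kw) -> CorrelationResult:
    """Correlate per-promoter signal change against writer occupancy.

    Both series must be indexed by the same promoter set (order-insensitive).
    """
    if set(delta.index) != set(occupancy.index):
        raise ValueError("delta and occupancy cover different promoter sets")
    occ = occupancy.loc[delta.index]
    return correlate(occ.to_numpy(), delta.to_numpy(), **kw)


def rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of gene per million mapped reads."""
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene lengths")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("zero library size")
    return counts.div(libsize / 1e6, axis=1).div(lengths / 1e3, axis=0)


def de_genes(
    counts_wt: pd.DataFrame,
    counts_ko: pd.DataFrame,
    lengths: pd.Series,
    pseudocount: float = 1.0,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential expression by log-RPKM t-test with fixed cutoffs.

    log2 fold change is computed between mean RPKM (+ pseudocount); the
    p-value is a two-sided two-sample t-test on per-replicate
    log2(RPKM + pseudocount). direction: 'up' iff log2fc > lfc_threshold
    and p < alpha (strict inequalities), 'down' symmetric, else 'ns'.
    """
    if set(counts_wt.index) != set(counts_ko.index):
        raise ValueError("WT and KO count tables cover different genes")
    if counts_wt.shape[1] < 2 or counts_ko.shape[1] < 2:
        raise ValueError("need at least 2 replicates per condition")
    counts_ko = counts_ko.loc[counts_wt.index]
    r_wt = rpkm(counts_wt, lengths)
    r_ko = rpkm(counts_ko, lengths)
    log2fc = np.log2(
        (r_ko.mean(axis=1) + pseudocount) / (r_wt.mean(axis=1) + pseudocount)
    )
    lw = np.log2(r_wt + pseudocount)
    lk = np.log2(r_ko + pseudocount)
    tstat, pval = stats.ttest_ind(lk, lw, axis=1)
    direction = np.where(
        (log2fc > lfc_threshold) & (pval < alpha),
        "up",
        np.where((log2fc < -lfc_threshold) & (pval < alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": pval, "direction": direction},
        index=counts_wt.index,
    )
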