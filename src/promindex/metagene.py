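"""Scale-regions metagene matrices and average profiles.

Each gene contributes one row spanning a fixed-width upstream flank, the
gene body rescaled to a fixed number of bins, and a fixed-width downstream
flank. Rows of minus-strand genes are oriented 5'→3' (reversed genomic
order), so column 0 is always 5' of the TSS and the last column 3' of the
TES. Cell values are mean per-base normalized signal, which keeps rows
comparable across genes of different lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome_io import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["MetageneMatrix", "build_matrix", "average_profile", "grouped_profiles"]


@dataclass
class MetageneMatrix:
    """Genes × scaled-position signal matrix with its layout metadata."""

    values: pd.DataFrame  # index: gene_id; columns: 0..ncol-1
    flank_bp: int
    binsize: int
    body_bins: int
    excluded: list[str] = field(default_factory=list)

    @property
    def flank_bins(self) -> int:
        return self.flank_bp // self.binsize

    @property
    def tss_column(self) -> int:
        """First gene-body column (the column at the TSS)."""
        return self.flank_bins

    @property
    def tes_column(self) -> int:
        """First downstream-flank column (the column just past the TES)."""
        return self.flank_bins + self.body_bins

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path) -> None:
        import json

        meta = {
            "flank_bp": self.flank_bp,
            "binsize": self.binsize,
            "body_bins": self.body_bins,
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            self.values.to_csv(fh, sep="\t", index_label="gene_id")


def _gene_column_edges(
    tss: int, tes: int, strand: str, flank_bp: int, binsize: int, body_bins: int
) -> np.ndarray:
    """Genomic positions of the column edges along the 5'→3' axis."""
    body_len = abs(tes - tss)
    x_flank_up = np.arange(-flank_bp, 1, binsize, dtype=float)
    x_body = np.linspace(0.0, body_len, body_bins + 1)
    x_flank_dn = body_len + np.arange(binsize, flank_bp + 1, binsize, dtype=float)
    x = np.concatenate([x_flank_up, x_body[1:], x_flank_dn])
    return tss + x if strand == "+" else tss - x


def build_matrix(
    track: CoverageTrack,
    genes: GeneSet,
    flank_bp: int = 5000,
    body_bins: int = 100,
    min_gene_length: int = 0,
) -> MetageneMatrix:
    """Build the scale-regions matrix from a coverage track.

    Flank cells have fixed genomic width equal to the track binsize; body
    cells are ``body_bins`` equal subdivisions of [TSS, TES). Genes shorter
    than ``min_gene_length`` or on chromosomes absent from the track are
    excluded (counted in ``excluded``).
    """
    if flank_bp % track.binsize != 0:
        raise ValueError("flank_bp must be a multiple of the track binsize")
    flank_bins = flank_bp // track.binsize
    ncol = 2 * flank_bins + body_bins

    rows: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for g in genes:
        if g.length < max(min_gene_length, 1) or g.chrom not in track.data:
            excluded.append(g.gene_id)
            continue
        edges = _gene_column_edges(
            g.tss, g.tes, g.strand, flank_bp, track.binsize, body_bins
        )
        lo = np.minimum(edges[:-1], edges[1:])
        hi = np.maximum(edges[:-1], edges[1:])
        rows[g.gene_id] = track.mean_density(g.chrom, lo, hi)
    if not rows:
        raise ValueError("no eligible genes for metagene matrix")
    if excluded:
        logger.info("metagene: excluded %d genes", len(excluded))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=range(ncol))
    return MetageneMatrix(values, flank_bp, track.binsize, body_bins, excluded)


def average_profile(m: MetageneMatrix, subset: list[str] | None = None) -> pd.Series:
    """Column-wise mean signal over a gene subset (default: all rows)."""
    df = m.values
    if subset is not None:
        missing = [g for g in subset if g not in df.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        if len(subset) == 0:
            raise ValueError("empty gene subset")
        df = df.loc[subset]
    return df.mean(axis=0)


def grouped_profiles(
    m: MetageneMatrix, expression: pd.Series | dict
) -> dict[str, pd.Series]:
    """Average profiles for expression-quartile groups.

    Genes (those present in both the matrix and the expression table) are
    split into the top 25% (high), bottom 25% (low) and the remainder
    (medium) of expression. Ties at a quartile boundary are resolved by
    stable gene_id order.
    """
    expr = pd.Series(expression)
    common = [g for g in m.gene_ids if g in expr.index]
    if len(common) < 4:
        raise ValueError("need expression for at least 4 genes in the matrix")
    order = sorted(common, key=lambda g: (expr[g], g))
    k = len(order) // 4
    groups = {
        "low": order[:k],
        "medium": order[k : len(order) - k],
        "high": order[len(order) - k :],
    }
    return {name: average_profile(m, ids) for name, ids in groups.items()}


def plot_profiles(profiles: dict[str, pd.Series], m: MetageneMatrix, path) -> None:
    """Write a simple average-profile figure (one line per group)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, prof in profiles.items():
        ax.plot(np.arange(len(prof)), prof.to_numpy(), label=name)
    ax.axvline(m.tss_column, color="grey", lw=0.8, ls="--")
    ax.axvline(m.tes_column, color="grey", lw=0.8, ls="--")
    ax.set_xticks([0, m.tss_column, m.tes_column, 2 * m.flank_bins + m.body_bins - 1])
    ax.set_xticklabels([f"-{m.flank_bp//1000} kb", "TSS", "TES", f"+{m.flank_bp//1000} kb"])
    ax.set_ylabel("mean normalized signal")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
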