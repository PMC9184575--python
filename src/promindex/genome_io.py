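"""Genomic file I/O and strand-aware region derivation.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; any 1-based input must be converted at the reader boundary. The
transcription start site (TSS) of a minus-strand gene is its ``end``
coordinate so that TSS→TES always reads 5'→3'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GeneSet",
    "Region",
    "FragmentSet",
    "read_gene_models",
    "read_fragments",
    "write_fragments",
    "read_chrom_sizes",
    "read_ref_class_map",
    "promoter_region",
    "genebody_region",
    "read_bedgraph",
    "write_bedgraph",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as an oriented genomic interval.

    ``start``/``end`` are the unstranded interval bounds; ``tss``/``tes``
    are derived, strand-aware termini.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start must be < end ({self.start} >= {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Region:
    """A role-tagged genomic interval (promoter, genebody or flank)."""

    chrom: str
    start: int
    end: int
    role: str = "flank"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start > end: {self.start} > {self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class GeneSet:
    """An ordered collection of gene models keyed by unique gene_id."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def subset(self, gene_ids: Iterable[str]) -> "GeneSet":
        return GeneSet(self._genes[g] for g in gene_ids)


def promoter_region(
    g: GeneModel, halfwidth: int = 500, chrom_length: int | None = None
) -> Region:
    """Symmetric promoter window ``[tss - halfwidth, tss + halfwidth)``.

    Clipped at the chromosome boundaries; the span is strand-independent
    because the window is symmetric around the TSS.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    start = max(0, g.tss - halfwidth)
    end = g.tss + halfwidth
    if chrom_length is not None:
        end = min(end, chrom_length)
    return Region(g.chrom, start, end, role="promoter")


def genebody_region(g: GeneModel, offset: int = 500) -> Region | None:
    """Gene body: from ``offset`` bases downstream of the TSS to the TES.

    Strand-aware; returns None when the gene is too short to leave a
    positive-width body after the offset.
    """
    if g.strand == "+":
        start, end = g.tss + offset, g.tes
    else:
        start, end = g.tes, g.tss - offset
    if end - start <= 0:
        return None
    return Region(g.chrom, start, end, role="genebody")


# ---------------------------------------------------------------------------
# Gene annotation reader


def _parse_gene_line(fields: list[str], lineno: int) -> GeneModel:
    # BED6 layout: chrom start end name score strand
    # TSV layout:  gene_id chrom start end strand [length]
    try:
        if len(fields) >= 6 and fields[5] in ("+", "-"):
            return GeneModel(
                gene_id=fields[3],
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                strand=fields[5],
            )
        if len(fields) >= 5 and fields[4] in ("+", "-"):
            return GeneModel(
                gene_id=fields[0],
                chrom=fields[1],
                start=int(fields[2]),
                end=int(fields[3]),
                strand=fields[4],
            )
        raise ValueError("strand column not found or not in {+,-}")
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def read_gene_models(path) -> GeneSet:
    """Read gene models from BED6 or a (gene_id, chrom, start, end, strand) TSV.

    Duplicate gene_ids are rejected; malformed lines raise :class:`ParseError`
    with the line number.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 5:
                raise ParseError(f"line {lineno}: expected >= 5 columns, got {len(fields)}")
            genes.append(_parse_gene_line(fields, lineno))
    return GeneSet(genes)


# ---------------------------------------------------------------------------
# Fragments

_FRAGMENT_COLUMNS = ["chrom", "start", "end", "ref_class", "sample_id"]


class FragmentSet:
    """Sequenced fragment intervals tagged by reference class.

    ``ref_class`` is 'sample' or 'spikein', determined solely by the
    reference (chromosome) name each interval maps to, never inferred from
    coordinates. Backed by a pandas DataFrame with columns
    chrom, start, end, ref_class, sample_id.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _FRAGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns {missing}")
        if len(df) and not (df["end"].to_numpy() > df["start"].to_numpy()).all():
            bad = df.index[df["end"] <= df["start"]][0]
            raise ValueError(f"fragment end <= start at row {bad}")
        bad_class = set(df["ref_class"].unique()) - {"sample", "spikein"}
        if bad_class:
            raise ValueError(f"unknown ref_class values {sorted(bad_class)}")
        if list(df.columns) != _FRAGMENT_COLUMNS:
            df = df[_FRAGMENT_COLUMNS]
        if not isinstance(df.index, pd.RangeIndex) or df.index.start != 0 or df.index.step != 1:
            df = df.reset_index(drop=True)
        self.df = df

    @classmethod
    def from_arrays(cls, chrom, start, end, ref_class, sample_id="") -> "FragmentSet":
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": pd.array(start, dtype="int64"),
                "end": pd.array(end, dtype="int64"),
                "ref_class": ref_class,
                "sample_id": sample_id,
            }
        )
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        return self.canonical().df.equals(other.canonical().df)

    def canonical(self) -> "FragmentSet":
        """Sorted copy (chrom, start, end) with plain-string columns, so
        equality is order- and dtype-independent."""
        df = self.df.copy()
        for col in ("chrom", "ref_class", "sample_id"):
            df[col] = df[col].astype(str)
        df = df.sort_values(
            ["chrom", "start", "end", "ref_class", "sample_id"], kind="mergesort"
        ).reset_index(drop=True)
        return FragmentSet(df)

    def count_by_ref_class(self) -> tuple[int, int]:
        """(sample_reads, spikein_reads); errors on an empty set."""
        if len(self.df) == 0:
            raise ValueError("empty FragmentSet: no fragments to count")
        n_spike = int((self.df["ref_class"] == "spikein").sum())
        return len(self.df) - n_spike, n_spike

    def sample_only(self) -> "FragmentSet":
        return FragmentSet(self.df[self.df["ref_class"] == "sample"].reset_index(drop=True))

    def validate_against(self, chromsizes: Mapping[str, int]) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False, observed=True):
            if chrom not in chromsizes:
                raise ValueError(f"fragment on unknown chromosome {chrom!r}")
            if int(sub["end"].max()) > chromsizes[chrom]:
                raise ValueError(
                    f"fragment exceeds declared size of chromosome {chrom!r}"
                )

    def concat(self, other: "FragmentSet") -> "FragmentSet":
        return FragmentSet(pd.concat([self.df, other.df], ignore_index=True))

    def tile(self, k: int) -> "FragmentSet":
        """Replicate every fragment k times (depth rescaling with identical layout)."""
        return FragmentSet(pd.concat([self.df] * k, ignore_index=True))


def read_fragments(
    path,
    ref_class_map: Mapping[str, str] | None = None,
    sample_id: str = "",
    chromsizes: Mapping[str, int] | None = None,
) -> FragmentSet:
    """Read BED3+ fragment intervals; chromosomes map to ref_class via
    ``ref_class_map`` (default 'sample' for unmapped chromosomes)."""
    ref_class_map = ref_class_map or {}
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 columns")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinates") from exc
            if e <= s:
                raise ParseError(f"line {lineno}: end <= start")
            chroms.append(fields[0])
            starts.append(s)
            ends.append(e)
    ref_class = [ref_class_map.get(c, "sample") for c in chroms]
    fs = FragmentSet.from_arrays(chroms, starts, ends, ref_class, sample_id)
    if chromsizes is not None:
        fs.validate_against(chromsizes)
    return fs


def write_fragments(fs: FragmentSet, path) -> None:
    """Write fragments as BED3 (sorted canonical order)."""
    df = fs.canonical().df
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected 'chrom length'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_ref_class_map(path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2 or fields[1] not in ("sample", "spikein"):
                raise ParseError(
                    f"line {lineno}: expected 'chrom sample|spikein'"
                )
            mapping[fields[0]] = fields[1]
    return mapping


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(intervals: Iterable[tuple[str, int, int, float]], path) -> None:
    """Write (chrom, start, end, value) rows as 4-column bedGraph."""
    with open(path, "w") as fh:
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"line {lineno}: bedGraph needs 4 columns")
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return rows
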