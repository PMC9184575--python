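"""The promoter/gene-body H3K36me3 index and the knockout screening rule.

The index is the ratio of mean normalized signal in promoter windows
(TSS ± 500 bp) to mean normalized signal in gene bodies (500 bp downstream
of the TSS to the TES). A knockout sample's index is divided by the index
of the wild-type sample from the same experimental batch; a ratio below
1 - threshold calls the knockout "decreased", above 1 + threshold
"increased". A gene is a confirmed hit only when two independent screening
rounds agree in direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .coverage import NormalizedTrack, normalized_coverage
from .genome_io import FragmentSet, GeneSet, genebody_region, promoter_region

logger = logging.getLogger(__name__)

__all__ = [
    "IndexResult",
    "ScreenCall",
    "HitStatus",
    "h3k36me3_index",
    "batch_normalize",
    "classify_change",
    "confirm_hits",
    "screen_panel",
]


@dataclass(frozen=True)
class IndexResult:
    sample_id: str
    promoter_signal: float
    genebody_signal: float
    index: float
    n_genes: int
    batch: str | None = None


@dataclass(frozen=True)
class ScreenCall:
    gene: str
    batch: str
    ratio: float
    call: str  # decreased | increased | unchanged
    round: int


@dataclass(frozen=True)
class HitStatus:
    gene: str
    round1: ScreenCall
    round2: ScreenCall | None
    confirmed: str  # hit_decreased | hit_increased | not_confirmed


def h3k36me3_index(
    track: NormalizedTrack,
    genes: GeneSet,
    halfwidth: int = 500,
    offset: int = 500,
    per_gene: bool = False,
    sample_id: str = "",
    batch: str | None = None,
) -> IndexResult:
    """Promoter-to-gene-body signal ratio over all eligible genes.

    A gene is eligible when its body (TSS + offset → TES) has positive
    width and it lies on a chromosome present in the track. By default the
    numerator and denominator are each a mean over genes of per-gene mean
    density; ``per_gene=True`` instead averages per-gene promoter/body
    ratios, which is less stable for weakly covered genes.
    """
    prom_means: list[float] = []
    body_means: list[float] = []
    n_excluded = 0
    for g in genes:
        body = genebody_region(g, offset=offset)
        if body is None or g.chrom not in track.data:
            n_excluded += 1
            continue
        prom = promoter_region(g, halfwidth=halfwidth, chrom_length=track.chromsizes[g.chrom])
        prom_means.append(track.mean_density(g.chrom, prom.start, prom.end))
        body_means.append(track.mean_density(g.chrom, body.start, body.end))
    if not prom_means:
        raise ValueError("no eligible genes (all bodies empty or off-track)")
    if n_excluded:
        logger.info("index: excluded %d genes with empty bodies", n_excluded)
    if per_gene:
        bm = np.asarray(body_means)
        pm = np.asarray(prom_means)
        ok = bm > 0
        if not ok.any():
            raise ValueError("gene-body signal is zero for every gene")
        index = float(np.mean(pm[ok] / bm[ok]))
        promoter_signal = float(pm.mean())
        genebody_signal = float(bm.mean())
    else:
        promoter_signal = float(np.mean(prom_means))
        genebody_signal = float(np.mean(body_means))
        if genebody_signal == 0:
            raise ValueError("gene-body signal is zero; index undefined")
        index = promoter_signal / genebody_signal
    return IndexResult(
        sample_id=sample_id,
        promoter_signal=promoter_signal,
        genebody_signal=genebody_signal,
        index=index,
        n_genes=len(prom_means),
        batch=batch,
    )


def batch_normalize(ko: IndexResult, wt: IndexResult) -> float:
    """KO index divided by the same-batch WT index."""
    if ko.batch is not None and wt.batch is not None and ko.batch != wt.batch:
        raise ValueError(f"batch mismatch: {ko.batch!r} vs {wt.batch!r}")
    if wt.index <= 0:
        raise ValueError("WT index must be positive")
    return ko.index / wt.index


def classify_change(ratio: float, threshold: float = 0.15) -> str:
    """Call a KO/WT index ratio: beyond ±threshold → decreased/increased.

    Ratios exactly at 1 - threshold or 1 + threshold are 'unchanged'
    (closed boundary on the unchanged side).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if ratio < 1 - threshold:
        return "decreased"
    if ratio > 1 + threshold:
        return "increased"
    return "unchanged"


def confirm_hits(
    round1: list[ScreenCall], round2: list[ScreenCall]
) -> list[HitStatus]:
    """Two-round confirmation: a hit requires agreeing non-unchanged calls.

    Every round-2 gene must have been screened in round 1; genes screened
    only in round 1 are reported as not confirmed.
    """
    r1 = {c.gene: c for c in round1}
    r2 = {c.gene: c for c in round2}
    extra = set(r2) - set(r1)
    if extra:
        raise ValueError(f"genes in round 2 but not round 1: {sorted(extra)}")
    out: list[HitStatus] = []
    for gene, c1 in r1.items():
        c2 = r2.get(gene)
        if c2 is not None and c1.call == c2.call and c1.call != "unchanged":
            confirmed = f"hit_{c1.call}"
        else:
            confirmed = "not_confirmed"
        out.append(HitStatus(gene=gene, round1=c1, round2=c2, confirmed=confirmed))
    return out


_MANIFEST_COLUMNS = ["sample_id", "gene", "batch", "round", "role"]


def screen_panel(
    manifest: pd.DataFrame,
    fragments: Mapping[str, FragmentSet],
    genes: GeneSet,
    chromsizes: Mapping[str, int],
    binsize: int = 50,
    constant: float = 1_000_000.0,
    threshold: float = 0.15,
    halfwidth: int = 500,
    offset: int = 500,
    no_spikein: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full two-round screen over a sample manifest.

    The manifest needs columns sample_id, gene, batch, round, role (WT/KO);
    each (batch, round) must contain exactly one WT sample. Returns
    (per-sample call table, per-gene hit table).
    """
    missing = [c for c in _MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")

    indexes: dict[str, IndexResult] = {}
    for row in manifest.itertuples(index=False):
        fs = fragments[row.sample_id]
        track = normalized_coverage(
            fs, chromsizes, binsize=binsize, constant=constant, no_spikein=no_spikein
        )
        indexes[row.sample_id] = h3k36me3_index(
            track,
            genes,
            halfwidth=halfwidth,
            offset=offset,
            sample_id=row.sample_id,
            batch=str(row.batch),
        )

    calls_by_round: dict[int, list[ScreenCall]] = {}
    records = []
    for (batch, rnd), grp in manifest.groupby(["batch", "round"], sort=True):
        wt_rows = grp[grp["role"] == "WT"]
        if len(wt_rows) != 1:
            raise ValueError(
                f"batch {batch!r} round {rnd}: expected exactly 1 WT sample, "
                f"got {len(wt_rows)}"
            )
        wt = indexes[wt_rows.iloc[0]["sample_id"]]
        for row in grp[grp["role"] == "KO"].itertuples(index=False):
            ko = indexes[row.sample_id]
            ratio = batch_normalize(ko, wt)
            call = ScreenCall(
                gene=str(row.gene),
                batch=str(batch),
                ratio=ratio,
                call=classify_change(ratio, threshold),
                round=int(rnd),
            )
            calls_by_round.setdefault(int(rnd), []).append(call)
            records.append(
                {
                    "sample_id": row.sample_id,
                    "gene": call.gene,
                    "batch": call.batch,
                    "round": call.round,
                    "index": ko.index,
                    "wt_index": wt.index,
                    "ratio": ratio,
                    "call": call.call,
                }
            )
    calls_df = pd.DataFrame.from_records(records)

    rounds = sorted(calls_by_round)
    if rounds == [1, 2]:
        hits = confirm_hits(calls_by_round[1], calls_by_round[2])
    elif len(rounds) == 1:
        hits = [
            HitStatus(c.gene, c, None, "not_confirmed") for c in calls_by_round[rounds[0]]
        ]
    else:
        raise ValueError(f"expected screening rounds {{1}} or {{1, 2}}, got {rounds}")
    hits_df = pd.DataFrame.from_records(
        [
            {
                "gene": h.gene,
                "round1_ratio": h.round1.ratio,
                "round1_call": h.round1.call,
                "round2_ratio": h.round2.ratio if h.round2 else np.nan,
                "round2_call": h.round2.call if h.round2 else "",
                "confirmed": h.confirmed,
            }
            for h in hits
        ]
    )
    return calls_df, hits_df
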