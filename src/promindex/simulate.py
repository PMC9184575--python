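"""Synthetic CUT&Tag-like data with known ground truth.

The fragment sampler emulates the phenomenology the analysis assumes:

* a gene-body signal rising linearly 5'→3' (the SETD2-deposited component),
* a promoter-centered Gaussian component around each TSS (the
  promoter-writer component the screen is designed to detect),
* uniform genomic background,
* spike-in fragments on a separate reference chromosome, whose count — not
  position — carries the normalization information,
* per-batch sequencing-depth variation (the nuisance spike-in
  normalization must remove).

Every generator is bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_io import FragmentSet, GeneModel, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "SignalArchitecture",
    "PanelDesign",
    "SPIKEIN_CHROM",
    "simulate_genome",
    "simulate_fragments",
    "simulate_ko_panel",
    "simulate_expression",
]

SPIKEIN_CHROM = "spikein_chr"
SPIKEIN_LENGTH = 100_000


@dataclass(frozen=True)
class SignalArchitecture:
    """Mixture weights and shape parameters of the fragment sampler.

    A fragment is spike-in with probability ``spikein_fraction``; otherwise
    its midpoint is drawn from the promoter component (Normal around a
    random gene's TSS, sd ``sigma_prom``) with probability
    ``promoter_weight``, from the rising gene-body gradient with
    probability ``body_gradient_weight``, and uniformly from the genome
    otherwise. Fragment lengths are Normal(fragment_length_mean, sd),
    clipped to >= 50 bases — nucleosomal-scale CUT&Tag fragments.
    """

    promoter_weight: float = 0.30
    body_gradient_weight: float = 0.50
    sigma_prom: float = 150.0
    spikein_fraction: float = 0.10
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 50.0
    gradient_slope: float = 1.0

    def __post_init__(self) -> None:
        if self.promoter_weight < 0 or self.body_gradient_weight < 0:
            raise ValueError("component weights must be non-negative")
        if self.promoter_weight + self.body_gradient_weight > 1:
            raise ValueError("promoter_weight + body_gradient_weight must be <= 1")
        if not 0 < self.spikein_fraction < 1:
            raise ValueError("spikein_fraction must be in (0, 1)")
        if self.gradient_slope < 0:
            raise ValueError("gradient_slope must be >= 0")

    def with_effect(self, effect: float) -> "SignalArchitecture":
        """Architecture of a knockout: promoter weight multiplied by effect.

        The freed probability mass flows to background, so total sample
        depth is unchanged — as in a resequenced KO library.
        """
        if effect <= 0:
            raise ValueError("effect must be positive")
        return replace(self, promoter_weight=self.promoter_weight * effect)


@dataclass
class PanelDesign:
    """Layout of a knockout screen: which genes, what effect, which batch.

    ``effects`` maps screened gene name → multiplier on the promoter
    component (1.0 = null, < 1 = true promoter-writer knockout).
    ``batches_per_round`` KO samples are distributed round-robin over
    batches; each batch carries its own WT and a multiplicative depth
    factor drawn log-uniformly from [1, depth_fold_range].
    """

    effects: dict[str, float]
    n_rounds: int = 2
    batches_per_round: int = 4
    depth: int = 200_000
    depth_fold_range: float = 4.0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.effects.values()):
            raise ValueError("effects must be positive")


def simulate_genome(
    n_genes: int,
    chrom_length: int,
    min_len: int = 5_000,
    max_len: int = 30_000,
    seed: int = 0,
    chrom: str = "chr1",
    margin: int = 10_000,
) -> tuple[GeneSet, dict[str, int]]:
    """Place non-overlapping genes of random length on one chromosome.

    Gaps between genes are drawn from a flat Dirichlet over the free space,
    strands are fair coin flips. Errors when the requested genes cannot be
    packed (total gene length above 80% of the available span).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(min_len, max_len + 1, size=n_genes)
    usable = chrom_length - 2 * margin
    if lengths.sum() > 0.8 * usable:
        raise ValueError(
            f"cannot pack {n_genes} genes of total length {lengths.sum()} "
            f"into {usable} usable bases"
        )
    free = usable - int(lengths.sum())
    gaps = rng.dirichlet(np.ones(n_genes + 1)) * free
    starts = margin + np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    starts = starts.astype(np.int64)
    strands = rng.choice(["+", "-"], size=n_genes)
    width = len(str(n_genes))
    genes = [
        GeneModel(
            gene_id=f"gene{str(i + 1).zfill(width)}",
            chrom=chrom,
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
            strand=str(strands[i]),
        )
        for i in range(n_genes)
    ]
    chromsizes = {chrom: int(chrom_length), SPIKEIN_CHROM: SPIKEIN_LENGTH}
    return GeneSet(genes), chromsizes


def _gradient_positions(u: np.ndarray, slope: float) -> np.ndarray:
    """Inverse-CDF sample of t in [0,1] with density proportional to 1 + slope*t."""
    if slope == 0:
        return u
    # CDF(t) = (t + slope t^2 / 2) / (1 + slope / 2); solve the quadratic
    c = 1.0 + slope / 2.0
    return (np.sqrt(1.0 + 2.0 * slope * c * u) - 1.0) / slope


def simulate_fragments(
    genes: GeneSet,
    chromsizes: dict[str, int],
    arch: SignalArchitecture,
    n_fragments: int,
    seed: int = 0,
    sample_id: str = "",
) -> FragmentSet:
    """Draw a fragment library from the mixture architecture."""
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    sample_chroms = [c for c in chromsizes if c != SPIKEIN_CHROM]
    if len(sample_chroms) != 1:
        raise ValueError("expected exactly one sample chromosome")
    chrom = sample_chroms[0]
    L = chromsizes[chrom]

    glist = list(genes)
    tss = np.array([g.tss for g in glist], dtype=float)
    tes = np.array([g.tes for g in glist], dtype=float)

    u = rng.random(n_fragments)
    is_spike = u < arch.spikein_fraction
    n_spike = int(is_spike.sum())
    n_samp = n_fragments - n_spike

    # component choice among sample fragments
    comp = rng.choice(
        3,
        size=n_samp,
        p=[
            arch.promoter_weight,
            arch.body_gradient_weight,
            1.0 - arch.promoter_weight - arch.body_gradient_weight,
        ],
    )
    mid = np.empty(n_samp)
    m_prom = comp == 0
    m_grad = comp == 1
    m_bg = comp == 2
    if m_prom.any():
        gi = rng.integers(0, len(glist), size=int(m_prom.sum()))
        mid[m_prom] = rng.normal(tss[gi], arch.sigma_prom)
    if m_grad.any():
        gi = rng.integers(0, len(glist), size=int(m_grad.sum()))
        t = _gradient_positions(rng.random(int(m_grad.sum())), arch.gradient_slope)
        mid[m_grad] = tss[gi] + t * (tes[gi] - tss[gi])
    if m_bg.any():
        mid[m_bg] = rng.random(int(m_bg.sum())) * L

    lens = np.maximum(
        50.0, rng.normal(arch.fragment_length_mean, arch.fragment_length_sd, n_samp)
    )
    start = np.clip(np.round(mid - lens / 2), 0, L - 1).astype(np.int64)
    end = np.clip(np.round(mid + lens / 2), 1, L).astype(np.int64)
    end = np.maximum(end, start + 1)

    # spike-in: uniform on the spike-in reference; only the count matters
    sl = np.maximum(
        50.0, rng.normal(arch.fragment_length_mean, arch.fragment_length_sd, n_spike)
    )
    s_start = (rng.random(n_spike) * (SPIKEIN_LENGTH - sl)).astype(np.int64)
    s_start = np.clip(s_start, 0, SPIKEIN_LENGTH - 1)
    s_end = np.minimum(s_start + np.maximum(sl.astype(np.int64), 1), SPIKEIN_LENGTH)

    codes = np.concatenate(
        [np.zeros(n_samp, dtype=np.int8), np.ones(n_spike, dtype=np.int8)]
    )
    df = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(codes, categories=[chrom, SPIKEIN_CHROM]),
            "start": np.concatenate([start, s_start]),
            "end": np.concatenate([end, s_end]),
            "ref_class": pd.Categorical.from_codes(
                codes, categories=["sample", "spikein"]
            ),
            "sample_id": pd.Categorical.from_codes(
                np.zeros(n_fragments, dtype=np.int8), categories=[sample_id or ""]
            ),
        }
    )
    return FragmentSet(df)


def simulate_ko_panel(
    design: PanelDesign,
    arch: SignalArchitecture,
    genes: GeneSet,
    chromsizes: dict[str, int],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, FragmentSet], pd.DataFrame]:
    """Generate a two-round KO screen with per-batch depth variation.

    Returns (manifest, sample_id → FragmentSet, truth table). Each batch
    holds one WT library plus its round-robin share of KO libraries, all
    drawn at that batch's depth.
    """
    rng = np.random.default_rng(seed)
    ko_genes = list(design.effects)
    manifest_rows = []
    fragments: dict[str, FragmentSet] = {}
    for rnd in range(1, design.n_rounds + 1):
        depth_factors = np.exp(
            rng.uniform(0, np.log(design.depth_fold_range), design.batches_per_round)
        )
        for b in range(design.batches_per_round):
            batch = f"r{rnd}b{b + 1}"
            depth = int(round(design.depth * depth_factors[b]))
            wt_id = f"WT_{batch}"
            fragments[wt_id] = simulate_fragments(
                genes,
                chromsizes,
                arch,
                depth,
                seed=int(rng.integers(2**31)),
                sample_id=wt_id,
            )
            manifest_rows.append(
                {"sample_id": wt_id, "gene": "WT", "batch": batch, "round": rnd, "role": "WT"}
            )
            for gene in ko_genes[b :: design.batches_per_round]:
                ko_id = f"{gene}_{batch}"
                fragments[ko_id] = simulate_fragments(
                    genes,
                    chromsizes,
                    arch.with_effect(design.effects[gene]),
                    depth,
                    seed=int(rng.integers(2**31)),
                    sample_id=ko_id,
                )
                manifest_rows.append(
                    {
                        "sample_id": ko_id,
                        "gene": gene,
                        "batch": batch,
                        "round": rnd,
                        "role": "KO",
                    }
                )
    manifest = pd.DataFrame.from_records(manifest_rows)
    truth = pd.DataFrame(
        {
            "gene": ko_genes,
            "effect": [design.effects[g] for g in ko_genes],
            "is_true_hit": [design.effects[g] != 1.0 for g in ko_genes],
        }
    )
    return manifest, fragments, truth


def simulate_expression(
    genes: GeneSet,
    n_reps: int = 3,
    base_mean: float = 500.0,
    dispersion: float = 0.05,
    linked_effects: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial replicate count matrices for WT and KO.

    Per-gene baseline means are log-normal around ``base_mean``;
    ``linked_effects`` maps gene_id → log2 fold change realized in the KO
    expectation (tie these to promoter-signal effects to emulate
    expression changes driven by promoter-mark loss). Counts are NB with
    gene-level dispersion ``dispersion`` (variance mu + dispersion*mu^2).
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    linked_effects = linked_effects or {}
    gene_ids = [g.gene_id for g in genes]
    mu_wt = base_mean * np.exp(rng.normal(0, 0.5, len(gene_ids)))
    lfc = np.array([linked_effects.get(g, 0.0) for g in gene_ids])
    mu_ko = mu_wt * 2.0**lfc

    def nb(mu: np.ndarray) -> np.ndarray:
        n = 1.0 / dispersion
        p = n / (n + mu)
        return rng.negative_binomial(n, p[:, None], size=(len(mu), n_reps))

    wt = pd.DataFrame(
        nb(mu_wt), index=gene_ids, columns=[f"WT_rep{i+1}" for i in range(n_reps)]
    )
    ko = pd.DataFrame(
        nb(mu_ko), index=gene_ids, columns=[f"KO_rep{i+1}" for i in range(n_reps)]
    )
    return wt, ko
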