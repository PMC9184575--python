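# Methods

## Problem and model

CUT&Tag and related tagmentation assays of the H3K36me3 mark yield fragment
intervals whose genomic density mixes several components: the canonical
SETD2-deposited signal that rises 5'→3' across transcribed gene bodies, a
promoter-centered component deposited by a promoter-acting
methyltransferase, and nonspecific background. `promindex` quantifies the
balance between the promoter and gene-body components and uses it as a
screening statistic: a knockout of a promoter-specific writer shifts the
balance away from promoters while leaving the gene-body component intact.

The statistic is the **H3K36me3 index**

    index = mean normalized signal at TSS ± 500 bp
            ────────────────────────────────────────
            mean normalized signal over gene bodies

with the gene body defined as 500 bp downstream of the TSS to the TES
(strand-aware). A knockout sample's index is divided by the index of the
wild-type sample processed in the same experimental batch, which cancels
batch-level efficiency and depth effects. Ratios below 0.85 are called
`decreased`, above 1.15 `increased`; a gene is a confirmed hit only when two
screening rounds (independent knockout clones) agree in a non-`unchanged`
direction.

## Coordinates and regions

All coordinates are 0-based half-open (BED convention). The TSS of a
minus-strand gene is its `end` coordinate; metagene rows are oriented
5'→3'. Promoters are symmetric around the TSS regardless of strand, because
the defining window (±500 bp) is symmetric. Genes whose body is empty after
the 500 bp offset are excluded from the index and from metagene matrices,
with a logged count; this avoids zero-width denominators. With offset =
halfwidth, promoter and body regions of a gene never overlap.

## Spike-in normalization

Coverage is binned (default 50 bp; fine enough to resolve a 1 kb promoter
window without excessive memory) and each bin stores fragment-bases, so the
track total equals the total clipped fragment length. Region signal is mean
per-base density, treating each bin as uniform. Bins are scaled by
`constant / spikein_reads` with `constant = 1,000,000` ("reference-adjusted
reads per million"); the constant is configurable. Fragments are counted
once as full-length intervals (tagmentation units), not as read pairs, and
no deduplication is applied. An optional no-spike-in mode scales by
`constant / sample_reads` instead, as a guard against over-normalization
when spike-in recovery is unreliable.

Two invariances follow and are tested: multiplying sample and spike-in
counts jointly by any constant leaves the normalized track unchanged
(depth-invariance), and multiplying only the sample counts by c scales the
track — and both index terms — by c, leaving the index unchanged.

## Index aggregation

The numerator and denominator are each a *mean over genes of per-gene mean
density*, not a mean of per-gene ratios: per-gene ratios are unstable for
weakly covered genes whose body mean approaches zero. The per-gene-ratio
variant is available behind `per_gene=True`. Boundary ratios of exactly
0.85 or 1.15 are classified `unchanged` (closed boundary on the unchanged
side); the 15% rule itself does not dictate inclusivity, so the choice is
documented rather than inferred.

## Metagene matrices

Scale-regions semantics: fixed-width flanks (default 5 kb, binned at the
coverage binsize, so 100 columns per side at 50 bp) surround a gene body
rescaled to `body_bins` (default 100) equal genomic subdivisions of
[TSS, TES). Cells average signal rather than summing it so rows are
comparable across gene lengths; genes shorter than `body_bins` bases still
get `body_bins` cells through fractional-overlap averaging. Flank cells
extending past a chromosome end read as diluted (zero signal outside),
which slightly lowers edge genes rather than dropping them. Expression
quartile grouping takes the top 25% (high) and bottom 25% (low) by
expression with ties broken by stable gene_id order, matching the exact
group sizes n//4 / n - 2(n//4) / n//4.

## Peak calling and association statistics

The bundled peak caller is a transparent quantile-threshold-merge: bins
strictly above the genome-wide `threshold_quantile` (default 0.99) merge
across gaps ≤ `merge_gap` (150 bp) and runs shorter than `min_width`
(200 bp) are dropped. It deliberately replaces production callers
(MACS2-class broad calling, SEACR-class sparse calling): the overlap and
correlation logic downstream is caller-agnostic, and externally called BED
peaks can be imported with `read_peaks_bed`. The caller is idempotent on
its own output's indicator signal.

Peak overlap is tested with a two-sided Fisher's exact test over an
explicit universe (all promoters, or genome bins); the universe must be
stated because the test is meaningless without it. Correlations report the
Pearson coefficient with the standard two-sided t-transform p-value plus a
least-squares slope/intercept and the slope's standard error. Signals are
correlated untransformed by default with a `log_transform` (log10(x + eps))
option.

Differential expression uses RPKM normalization, log2 fold change of mean
RPKM with pseudocount 1, and a two-sided two-sample t-test on
log2(RPKM + 1) per gene; genes pass at |log2FC| > 0.5 and P < 0.05 (strict
inequalities). This is a deliberately simple, documented replacement for a
negative-binomial framework: the gene lists only feed correlation stages,
and under the synthetic generator's dispersion settings the t-test's null
positive rate sits within binomial error of the nominal 0.05 (verified in
the acceptance checks).

## Synthetic data generator

The generator defines the study conditions and carries ground truth for
every downstream stage. A fragment is spike-in with probability
`spikein_fraction` (default 0.10, a typical carry-over proportion);
otherwise its midpoint is drawn from a Gaussian around a random gene's TSS
(`promoter_weight` 0.30, σ 150 bp — a nucleosome-scale promoter footprint),
from a gene-body gradient with density ∝ 1 + t along the 5'→3' body
(`body_gradient_weight` 0.50), or uniformly from the genome (remainder).
Fragment lengths are Normal(200, 50) clipped at 50 bp, the nucleosomal
fragment scale of tagmentation libraries. A knockout multiplies
`promoter_weight` by its effect, with the freed mass flowing to background
so total library depth is unchanged. Batch effects are multiplicative depth
factors drawn log-uniformly from [1, 4] per batch — exactly the nuisance
spike-in normalization is designed to remove; antibody-efficiency batch
effects are not modeled. Spike-in fragments are placed uniformly on a
dedicated reference chromosome because only their count matters.

Expression counts are negative-binomial with log-normal baseline means and
a gene-level dispersion (variance μ + φμ²); injected log2 fold changes are
realized in the KO expectation and can be tied to promoter effects.

What the generator does **not** emulate: mappability and sequence bias,
duplicate structure, chromatin accessibility confounding, antibody
efficiency differences, overlapping gene models, and multi-chromosome
genomes. Passing tests therefore demonstrate the correctness and
calibration of the computation, not robustness to those real-data
artifacts.

## Problem sizes used in the checks

The screen-recovery check runs 50 independently seeded panels of 20
knockout genes (3 true promoter-writer knockouts at effect 0.7, 17 nulls)
in 4 batches per round over 2 rounds at 200,000 fragments per sample on a
2 Mb synthetic chromosome carrying 60 genes; each panel is a full
simulate → normalize → index → classify → confirm run. At these depths the
true-knockout index ratio concentrates near 0.67 and null ratios within
±1% of 1, so the ±15% rule separates them with large margin; sensitivity
1.0 with zero false confirmations is the expected outcome, not a tuned one.
Metagene shape checks use 12 genes of 20-30 kb and 0.5-2 M fragments;
Fisher agreement enumerates every 2×2 table with margins ≤ 30.

## Numerical choices

Bin-level integrals treat signal as uniform within a bin; the final partial
bin of a chromosome uses its true width. Uniform coverage therefore yields
an index of exactly 1.0 and a flat metagene profile to machine precision.
Degenerate inputs error early: empty fragment sets, zero spike-in counts
(with a pointer to the no-spike-in mode), zero gene-body signal, zero
variance in correlation inputs, empty peak-overlap universes.

## Known limitations

The ±15% threshold is a fixed decision rule, not a significance test; no
per-gene uncertainty accompanies a screen call. The simplified peak caller
has no local background model and will merge distinct summits closer than
`merge_gap`. The expression test assumes approximate log-normality of
normalized counts within condition; at very low counts or very high
dispersion its calibration degrades. Overlapping genes are used as-is
(deduplication is the caller's responsibility via gene subsets).
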