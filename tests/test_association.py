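"""Peak calling, overlap testing, correlations, RPKM and DE calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from promindex.association import (
    PeakSet,
    call_peaks_simple,
    correlate,
    de_genes,
    delta_vs_occupancy,
    overlap_test,
    promoter_signal_table,
    read_peaks_bed,
    rpkm,
)
from promindex.genome_io import Region

from conftest import track_from_bin_values


def fisher_two_sided_oracle(table):
    """Exhaustive hypergeometric enumeration of all tables with the observed
    margins; two-sided p sums probabilities <= the observed table's."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    xs = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = hypergeom.pmf(xs, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def peaks(intervals, chrom="chr1"):
    df = pd.DataFrame(
        [(chrom, s, e, 1.0) for s, e in intervals],
        columns=["chrom", "start", "end", "score"],
    )
    return PeakSet(df)


class TestPeakCaller:
    def _track(self, values, binsize=50):
        return track_from_bin_values(
            np.asarray(values, float) * binsize, binsize=binsize
        )

    def test_single_block_called_as_one_peak(self):
        v = np.zeros(400)
        v[100:108] = 10.0  # 400 bp block
        ps = call_peaks_simple(self._track(v), threshold_quantile=0.95, min_width=200)
        assert len(ps) == 1
        row = ps.df.iloc[0]
        assert (row.start, row.end) == (5000, 5400)

    def test_nearby_blocks_merge(self):
        v = np.zeros(400)
        v[100:104] = 10.0
        v[106:110] = 10.0  # 100 bp gap < merge_gap 150
        ps = call_peaks_simple(self._track(v), threshold_quantile=0.95)
        assert len(ps) == 1
        assert (ps.df.iloc[0].start, ps.df.iloc[0].end) == (5000, 5500)

    def test_narrow_runs_dropped(self):
        v = np.zeros(400)
        v[100:102] = 10.0  # 100 bp < min_width 200
        ps = call_peaks_simple(self._track(v), threshold_quantile=0.95)
        assert len(ps) == 0

    def test_all_zero_track_yields_empty_peakset(self):
        ps = call_peaks_simple(self._track(np.zeros(100)))
        assert len(ps) == 0

    def test_calling_on_peak_indicator_is_idempotent(self):
        v = np.zeros(1000)
        v[100:110] = 1.0
        v[300:320] = 1.0
        first = call_peaks_simple(self._track(v), threshold_quantile=0.95)
        indicator = np.zeros(1000)
        for row in first.df.itertuples():
            indicator[row.start // 50 : row.end // 50] = 1.0
        second = call_peaks_simple(self._track(indicator), threshold_quantile=0.95)
        pd.testing.assert_frame_equal(
            first.df[["chrom", "start", "end"]], second.df[["chrom", "start", "end"]]
        )

    def test_bed_round_trip(self, tmp_path):
        v = np.zeros(400)
        v[50:60] = 4.0
        v[200:230] = 8.0
        ps = call_peaks_simple(self._track(v), threshold_quantile=0.9)
        p = tmp_path / "peaks.bed"
        ps.to_bed(p)
        back = read_peaks_bed(p)
        pd.testing.assert_frame_equal(
            ps.df[["chrom", "start", "end"]], back.df[["chrom", "start", "end"]]
        )


class TestOverlapTest:
    def _universe(self, n, width=100):
        return [Region("chr1", 1000 * i, 1000 * i + width) for i in range(n)]

    def test_fisher_p_matches_enumeration_for_crafted_table(self):
        # universe of 8 promoters: 3 with both peaks, 1 A-only, 1 B-only, 3 neither
        uni = self._universe(8)
        a = peaks([(r.start, r.end) for r in uni[:4]])
        b = peaks([(r.start, r.end) for r in uni[:3] + uni[4:5]])
        res = overlap_test(a, b, uni)
        assert res.table == ((3, 1), (1, 3))
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(res.table), rel=1e-12)

    def test_identical_peaksets_maximal_overlap(self):
        uni = self._universe(10)
        a = peaks([(r.start, r.end) for r in uni[:4]])
        res_same = overlap_test(a, a, uni)
        assert res_same.n_overlap == res_same.n_a == 4
        disjoint = peaks([(r.start, r.end) for r in uni[4:8]])
        res_disj = overlap_test(a, disjoint, uni)
        assert res_same.p_value <= res_disj.p_value
        assert res_disj.odds_ratio < 1

    def test_empty_universe_is_an_error(self):
        a = peaks([(0, 10)])
        with pytest.raises(ValueError, match="universe"):
            overlap_test(a, a, [])


class TestSignalTable:
    def test_uniform_track_and_restriction(self):
        track = track_from_bin_values(np.full(100, 3.0 * 50), binsize=50)
        promoters = [Region("chr1", 1000 * i, 1000 * i + 200, "promoter") for i in range(4)]
        table = promoter_signal_table({"t": track}, promoters)
        assert table.shape == (4, 1)
        np.testing.assert_allclose(table["t"], 3.0)
        restricted = promoter_signal_table(
            {"t": track}, promoters, restrict_to=peaks([(0, 1200)])
        )
        assert len(restricted) == 2  # first two promoters intersect the peak
        with pytest.raises(ValueError, match="no promoters"):
            promoter_signal_table({"t": track}, promoters, restrict_to=peaks([(4900, 4950)]))

    def test_table_matches_perbase_means(self, rng):
        from conftest import perbase_mean

        values = rng.random(500)
        track = track_from_bin_values(values, binsize=1)
        promoters = [Region("chr1", 10, 60), Region("chr1", 100, 130)]
        table = promoter_signal_table({"t": track}, promoters)
        for r in promoters:
            assert table.loc[r.name, "t"] == pytest.approx(
                perbase_mean(values, r.start, r.end), rel=1e-9
            )


class TestCorrelate:
    def test_exact_lines(self):
        res = correlate([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert correlate([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_sampling_distribution_of_r(self, rng):
        rho, n = 0.5, 2000
        cov = [[1, rho], [rho, 1]]
        x, y = rng.multivariate_normal([0, 0], cov, size=n).T
        assert abs(correlate(x, y).r - rho) < 0.05

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 3"):
            correlate([1, 2], [1, 2])
        with pytest.raises(ValueError, match="finite"):
            correlate([1, 2, np.nan], [1, 2, 3])


class TestDeltaVsOccupancy:
    def test_zero_delta_is_degenerate(self):
        idx = [f"p{i}" for i in range(5)]
        delta = pd.Series(0.0, index=idx)
        occ = pd.Series(np.arange(5.0), index=idx)
        with pytest.raises(ValueError, match="zero variance"):
            delta_vs_occupancy(delta, occ)

    def test_misaligned_promoters_are_an_error(self):
        delta = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        occ = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "d"])
        with pytest.raises(ValueError, match="different promoter sets"):
            delta_vs_occupancy(delta, occ)

    def test_slope_recovery_and_ordering(self, rng):
        n, k_full, k_trunc, sigma = 400, 1.2, 0.4, 0.3
        occ = pd.Series(rng.gamma(2.0, 1.0, n), index=[f"p{i}" for i in range(n)])
        d_full = k_full * occ + rng.normal(0, sigma, n)
        d_trunc = k_trunc * occ + rng.normal(0, sigma, n)
        r_full = delta_vs_occupancy(d_full, occ)
        r_trunc = delta_vs_occupancy(d_trunc, occ)
        assert abs(r_full.slope - k_full) < 3 * r_full.slope_stderr
        assert r_full.slope > r_trunc.slope


class TestRpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"s1": [10, 999_990]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 10_000})
        out = rpkm(counts, lengths)
        assert out.loc["g1", "s1"] == pytest.approx(10.0)

    def test_depth_invariance(self):
        counts = pd.DataFrame({"s1": [10, 90], "s2": [30, 270]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 500, "g2": 2000})
        out = rpkm(counts, lengths)
        np.testing.assert_allclose(out["s1"], out["s2"])

    def test_matches_double_loop_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(20, 4)),
            index=[f"g{i}" for i in range(20)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(200, 5000, size=20), index=counts.index)
        out = rpkm(counts, lengths)
        for g in counts.index:
            for s in counts.columns:
                expected = counts.loc[g, s] / (
                    (lengths[g] / 1e3) * (counts[s].sum() / 1e6)
                )
                assert out.loc[g, s] == pytest.approx(expected, rel=1e-12)

    def test_zero_library_is_an_error(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="library"):
            rpkm(counts, pd.Series({"g1": 100, "g2": 100}))


class TestDeGenes:
    def _lengths(self, genes):
        return pd.Series(1000, index=genes)

    def test_identical_conditions_are_ns(self, rng):
        genes = [f"g{i}" for i in range(50)]
        wt = pd.DataFrame(
            rng.integers(50, 500, size=(50, 3)), index=genes,
            columns=["w1", "w2", "w3"],
        )
        res = de_genes(wt, wt.copy(), self._lengths(genes))
        assert (res["direction"] == "ns").all()

    def test_injected_fold_change_detected(self):
        genes = ["target"] + [f"g{i}" for i in range(9)]
        wt = pd.DataFrame(
            {"w1": [100] + [200] * 9, "w2": [105] + [210] * 9, "w3": [95] + [190] * 9},
            index=genes,
        )
        ko = wt.copy()
        ko.loc["target"] = [400, 420, 380]  # 4x fold change
        ko.columns = ["k1", "k2", "k3"]
        res = de_genes(wt, ko, self._lengths(genes))
        assert res.loc["target", "direction"] == "up"

    def test_threshold_boundary_is_strict(self):
        # ratio of exactly 2 with lfc_threshold=1.0: log2fc == 1.0, not > 1.0.
        # Lengths of 1000 bp and library sizes of exactly 1e6 make RPKM equal
        # the raw count, so every step is exact in floating point.
        genes = ["edge", "ballast"]
        wt_edge = [0.75, 1.0, 1.25]
        ko_edge = [2.75, 3.0, 3.25]
        wt = pd.DataFrame(
            {f"w{i+1}": [v, 1e6 - v] for i, v in enumerate(wt_edge)}, index=genes
        )
        ko = pd.DataFrame(
            {f"k{i+1}": [v, 1e6 - v] for i, v in enumerate(ko_edge)}, index=genes
        )
        lengths = pd.Series({"edge": 1000, "ballast": 1000})
        res = de_genes(wt, ko, lengths, pseudocount=1.0, lfc_threshold=1.0)
        assert res.loc["edge", "log2fc"] == 1.0
        assert res.loc["edge", "p_value"] < 0.05
        assert res.loc["edge", "direction"] == "ns"

    def test_mismatched_gene_sets_are_an_error(self):
        wt = pd.DataFrame({"w1": [1, 2], "w2": [1, 2]}, index=["a", "b"])
        ko = pd.DataFrame({"k1": [1, 2], "k2": [1, 2]}, index=["a", "c"])
        with pytest.raises(ValueError, match="different genes"):
            de_genes(wt, ko, pd.Series({"a": 100, "b": 100, "c": 100}))

    def test_single_replicate_is_an_error(self):
        wt = pd.DataFrame({"w1": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="replicates"):
            de_genes(wt, wt, pd.Series({"a": 100, "b": 100}))

    def test_up_down_partition_is_disjoint(self, rng):
        genes = [f"g{i}" for i in range(200)]
        wt = pd.DataFrame(
            rng.integers(50, 500, size=(200, 3)).astype(float), index=genes
        )
        ko = wt * rng.choice([0.3, 1.0, 3.0], size=(200, 1))
        ko.columns = ["k1", "k2", "k3"]
        wt.columns = ["w1", "w2", "w3"]
        wt += rng.normal(0, 2, wt.shape)
        ko += rng.normal(0, 2, ko.shape)
        res = de_genes(wt.clip(lower=0), ko.clip(lower=0), self._lengths(genes))
        assert set(res["direction"]) <= {"up", "down", "ns"}
        sig = res[res["direction"] != "ns"]
        assert ((sig["log2fc"].abs() > 0.5) & (sig["p_value"] < 0.05)).all()
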