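"""Scoring methods: closed-form examples, brute-force oracles, invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from chipscore.assignment import (
    Assignment,
    assign_all_peaks,
    assign_closest_gene,
    assign_closest_peak,
    assign_window,
)
from chipscore.scoring import (
    MethodConfig,
    ScoreTable,
    build_distance_distribution,
    build_tss_profile,
    fit_nearest_distance_model,
    score_all_methods,
    score_binary,
    score_chen,
    score_cheng,
    score_closest_gene,
    score_linear,
    score_ouyang,
)

from conftest import (
    oracle_closest_gene_scores,
    oracle_distance_pool,
    oracle_linear_scores,
    oracle_ouyang_scores,
    random_genes,
    random_peaks,
)


def _gene(gene_id="g", chrom="1", strand="+", tss=100_000):
    return pd.DataFrame([(gene_id, chrom, strand, tss)],
                        columns=["gene_id", "chrom", "strand", "tss"])


def _peaks(*summits, chrom="1", intensity=10.0):
    return pd.DataFrame(
        [(f"p{i}", chrom, s, intensity) for i, s in enumerate(summits)],
        columns=["peak_id", "chrom", "summit", "intensity"],
    )


class TestBinary:
    def test_peak_inside_window_scores_one(self):
        genes = _gene(tss=100_000)
        t = score_binary(genes, assign_window(genes, _peaks(104_999), 5_000))
        assert t.scores["g"] == 1.0

    def test_peak_outside_window_scores_zero(self):
        genes = _gene(tss=100_000)
        t = score_binary(genes, assign_window(genes, _peaks(106_000), 5_000))
        assert t.scores["g"] == 0.0

    def test_wrong_strategy_rejected(self):
        genes = _gene()
        a = assign_closest_peak(genes, _peaks(100_000))
        with pytest.raises(ValueError, match="window"):
            score_binary(genes, a)

    def test_matches_interval_oracle(self, rng):
        genes = random_genes(rng, 50, chrom_length=500_000)
        peaks = random_peaks(rng, 200, chrom_length=500_000)
        t = score_binary(genes, assign_window(genes, peaks, 5_000))
        expected = oracle_linear_scores(genes, peaks, 5_000)
        for gid, s in t.scores.items():
            assert s == (1.0 if expected[gid] > 0 else 0.0)


class TestLinear:
    def test_closed_form_weights(self):
        L = 50_000
        genes = _gene(tss=100_000)
        peaks = _peaks(100_000, 100_000 + L // 2, 100_000 + L)
        t = score_linear(genes, assign_window(genes, peaks, L))
        assert t.scores["g"] == pytest.approx(1.0 + 0.5 + 0.0, abs=1e-12)

    def test_no_peaks_scores_zero(self):
        genes = _gene()
        t = score_linear(genes, assign_window(genes, _peaks(10**7), 50_000))
        assert t.scores["g"] == 0.0

    def test_matches_per_peak_oracle(self, rng):
        genes = random_genes(rng, 50, chrom_length=500_000)
        peaks = random_peaks(rng, 200, chrom_length=500_000)
        t = score_linear(genes, assign_window(genes, peaks, 50_000))
        expected = oracle_linear_scores(genes, peaks, 50_000)
        for gid, s in t.scores.items():
            assert s == pytest.approx(expected[gid], rel=1e-9, abs=1e-12)


class TestOuyang:
    def test_distance_zero_contributes_full_intensity(self):
        genes = _gene(tss=100_000)
        t = score_ouyang(genes, assign_all_peaks(genes, _peaks(100_000)), _peaks(100_000))
        assert t.scores["g"] == pytest.approx(10.0)

    def test_decay_constant(self):
        config = MethodConfig()
        genes = _gene(tss=100_000)
        peaks = _peaks(100_000 + int(config.ouyang_d0))
        t = score_ouyang(genes, assign_all_peaks(genes, peaks), peaks, config)
        assert t.scores["g"] == pytest.approx(10.0 * math.exp(-1), rel=1e-12)

    def test_matches_brute_force_sum(self, rng):
        genes = random_genes(rng, 50)
        peaks = random_peaks(rng, 200)
        config = MethodConfig()
        t = score_ouyang(genes, assign_all_peaks(genes, peaks), peaks, config)
        expected = oracle_ouyang_scores(genes, peaks, config.ouyang_d0, config.ouyang_cap)
        for gid, s in t.scores.items():
            assert s == pytest.approx(expected[gid], rel=1e-9, abs=1e-12)


class TestChengProfile:
    def test_flat_coverage_gives_uniform_weights(self):
        genes = pd.DataFrame([("a", "1", "+", 50_000), ("b", "1", "-", 150_000)],
                             columns=["gene_id", "chrom", "strand", "tss"])
        cov = pd.DataFrame([("1", 0, 1_000_000, 1.0)],
                           columns=["chrom", "start", "end", "value"])
        prof = build_tss_profile(genes, coverage=cov)
        n_bins = prof.weights.size
        assert np.allclose(prof.weights, 1.0 / n_bins)
        assert np.allclose(prof.signal, 1.0)

    def test_single_bin_coverage_gives_indicator(self):
        genes = _gene(tss=50_000)
        config = MethodConfig()
        # one bin-width of coverage right at the TSS (0-based interval)
        cov = pd.DataFrame([("1", 50_000 - 1, 50_000 - 1 + config.cheng_bin, 2.0)],
                           columns=["chrom", "start", "end", "value"])
        prof = build_tss_profile(genes, coverage=cov, config=config)
        hot = int(np.argmax(prof.weights))
        assert prof.weights[hot] == pytest.approx(1.0)
        assert np.count_nonzero(prof.weights) == 1

    def test_minus_strand_flip(self):
        # signal 3 kb downstream of each TSS must land in the same bin
        genes = pd.DataFrame([("a", "1", "+", 50_000), ("b", "1", "-", 150_000)],
                             columns=["gene_id", "chrom", "strand", "tss"])
        cov = pd.DataFrame(
            [("1", 52_999, 53_099, 1.0), ("1", 146_901, 147_001, 1.0)],
            columns=["chrom", "start", "end", "value"])
        prof = build_tss_profile(genes, coverage=cov)
        assert np.argmax(prof.signal[0]) == np.argmax(prof.signal[1])

    def test_matches_column_means_oracle(self, rng):
        genes = random_genes(rng, 20, n_chroms=1, chrom_length=400_000)
        n_bins = 200
        cov_rows = []
        for s in range(0, 400_000, 1000):
            cov_rows.append(("1", s, s + 1000, float(rng.integers(0, 5))))
        cov = pd.DataFrame(cov_rows, columns=["chrom", "start", "end", "value"])
        prof = build_tss_profile(genes, coverage=cov)
        col_means = prof.signal.mean(axis=0)
        assert np.allclose(prof.weights, col_means / col_means.sum())
        assert prof.weights.shape == (n_bins,)
        assert prof.weights.sum() == pytest.approx(1.0)

    def test_zero_signal_rejected(self):
        genes = _gene(tss=50_000)
        cov = pd.DataFrame([("1", 0, 100_000, 0.0)],
                           columns=["chrom", "start", "end", "value"])
        with pytest.raises(ValueError, match="zero"):
            build_tss_profile(genes, coverage=cov)


class TestChengScore:
    def _profile(self, rng, n=40):
        genes = random_genes(rng, n, n_chroms=1, chrom_length=1_000_000)
        peaks = random_peaks(rng, 200, n_chroms=1, chrom_length=1_000_000)
        return build_tss_profile(genes, peaks=peaks)

    def test_z_standardisation(self, rng):
        prof = self._profile(rng)
        t = score_cheng(prof)
        assert t.scores.mean() == pytest.approx(0.0, abs=1e-12)
        assert t.scores.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_zero_signal_gene_has_minimal_z(self, rng):
        prof = self._profile(rng)
        raw = prof.signal @ prof.weights
        t = score_cheng(prof)
        assert t.scores.iloc[int(np.argmin(raw))] == t.scores.min()

    def test_matches_weighted_sum_oracle(self, rng):
        prof = self._profile(rng)
        t = score_cheng(prof)
        s = np.array([float(np.dot(prof.weights, row)) for row in prof.signal])
        z = (s - s.mean()) / s.std(ddof=1)
        assert np.allclose(t.scores.to_numpy(), z, rtol=1e-9)


class TestChenModel:
    def test_observed_equal_expected_scores_zero(self):
        from chipscore.scoring import NearestDistanceModel
        edges = np.array([0.0, 100.0, 1000.0])
        m = NearestDistanceModel(edges, np.array([5.0, 5.0]), np.array([5.0, 5.0]),
                                 np.maximum(0, 1 - np.array([5.0, 5.0]) / np.array([5.0, 5.0])))
        assert m.score_for_distance(50) == 0.0

    def test_dominant_observed_approaches_one(self):
        from chipscore.scoring import NearestDistanceModel
        edges = np.array([0.0, 100.0])
        o, e = np.array([1e6]), np.array([1.0])
        m = NearestDistanceModel(edges, o, e, np.maximum(0.0, 1 - e / o))
        assert 0.999 < m.score_for_distance(10) < 1.0

    def test_expected_matches_analytic_uniform(self, rng):
        """E(b) for uniform summits agrees with the closed-form nearest-
        neighbour distance law for a TSS at distance d from m uniform points
        on [1, G]: P(nearest > d) ~ (1 - 2d/G)^m away from the edges."""
        G, m, n_genes = 1_000_000, 50, 200
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chrom": "1", "strand": "+",
            "tss": np.linspace(G * 0.3, G * 0.7, n_genes).astype(int),
        })
        peaks = pd.DataFrame({
            "peak_id": [f"p{i}" for i in range(m)], "chrom": "1",
            "summit": rng.integers(1, G, size=m), "intensity": 10.0,
        })
        edges = (0, 2_000, 10_000, 50_000, G)
        config = MethodConfig(chen_bins=edges, chen_shuffles=200, rng_seed=5)
        model = fit_nearest_distance_model(genes, peaks, config, {"1": G})
        p_gt = lambda d: max(0.0, 1 - 2 * d / G) ** m
        for b in range(len(edges) - 1):
            analytic = n_genes * (p_gt(edges[b]) - p_gt(edges[b + 1]))
            # per-shuffle counts are at most Binomial(n_genes, p)-spread;
            # 3 SE of the 200-shuffle mean, with a 1-count floor
            se = math.sqrt(max(analytic, 1.0) / 200)
            assert abs(model.expected[b] - analytic) <= max(3 * se, 1.0)

    def test_score_chen_is_table_lookup(self, rng):
        genes = random_genes(rng, 60)
        peaks = random_peaks(rng, 200)
        config = MethodConfig(chen_shuffles=5, rng_seed=3)
        model = fit_nearest_distance_model(genes, peaks, config)
        a = assign_closest_peak(genes, peaks)
        t = score_chen(genes, a, model)
        for row in a.table.itertuples(index=False):
            assert t.scores[row.gene_id] == model.score_for_distance(row.distance)

    def test_no_peaks_rejected(self, rng):
        genes = random_genes(rng, 10)
        empty = genes.iloc[:0][["gene_id"]].assign(chrom="1", summit=1, intensity=1.0)
        empty = empty.rename(columns={"gene_id": "peak_id"})
        with pytest.raises(ValueError, match="no peaks"):
            fit_nearest_distance_model(genes, empty)


class TestDistanceDistribution:
    def test_degenerate_single_distance(self):
        genes = _gene(tss=100_000)
        dist = build_distance_distribution(genes, _peaks(99_000, 101_000), cap=10_000)
        assert dist.cdf("upstream", 999) == 0.0
        assert dist.cdf("upstream", 1000) == 1.0

    def test_empirical_cdf_quartiles(self):
        genes = _gene(tss=100_000)
        peaks = _peaks(100_010, 100_100, 101_000, 110_000, 50_000)
        dist = build_distance_distribution(genes, peaks, cap=100_000)
        for d, expected in [(10, 0.25), (100, 0.5), (1000, 0.75), (10_000, 1.0)]:
            assert dist.cdf("downstream", d) == pytest.approx(expected)

    def test_zero_distance_counts_downstream(self):
        genes = _gene(tss=100_000)
        dist = build_distance_distribution(genes, _peaks(100_000, 99_000), cap=10_000)
        assert dist.n_downstream == 1
        assert dist.n_upstream == 1

    def test_matches_all_pairs_oracle(self, rng):
        genes = random_genes(rng, 30)
        peaks = random_peaks(rng, 100)
        dist = build_distance_distribution(genes, peaks, cap=1_000_000)
        up, down = oracle_distance_pool(genes, peaks, 1_000_000)
        assert dist.upstream.tolist() == up
        assert dist.downstream.tolist() == down

    def test_empty_side_rejected(self):
        genes = _gene(strand="+", tss=100_000)
        with pytest.raises(ValueError, match="upstream"):
            build_distance_distribution(genes, _peaks(100_500), cap=10_000)


class TestClosestGeneScore:
    def test_farthest_peak_contributes_zero(self):
        genes = _gene(tss=100_000)
        # the lone upstream peak has p = 1 and adds -ln(1) = 0; the three
        # downstream peaks have p = 1/3, 2/3, 1
        peaks = _peaks(99_000, 100_100, 100_500, 105_000)
        a = assign_closest_gene(genes, peaks, cap=1_000_000)
        dist = build_distance_distribution(genes, peaks, cap=1_000_000)
        t = score_closest_gene(genes, a, dist)
        expected = -(math.log(1 / 3) + math.log(2 / 3) + math.log(1.0))
        assert t.scores["g"] == pytest.approx(expected, rel=1e-12)

    def test_gene_without_peaks_scores_zero(self):
        genes = pd.DataFrame([("a", "1", "+", 100_000), ("b", "2", "+", 100_000)],
                             columns=["gene_id", "chrom", "strand", "tss"])
        peaks = _peaks(99_000, 100_100, 100_500, chrom="1")
        a = assign_closest_gene(genes, peaks)
        dist = build_distance_distribution(genes, peaks)
        t = score_closest_gene(genes, a, dist)
        assert t.scores["b"] == 0.0

    def test_hand_evaluated_quartile_sum(self):
        # 4 downstream peaks at CDF values 0.25 / 0.5 / 0.75 / 1.0 plus one
        # upstream peak contributing -ln(1) = 0
        genes = _gene(tss=100_000)
        peaks = _peaks(90_000, 100_010, 100_100, 101_000, 110_000)
        a = assign_closest_gene(genes, peaks)
        dist = build_distance_distribution(genes, peaks)
        t = score_closest_gene(genes, a, dist)
        expected = -(math.log(0.25) + math.log(0.5) + math.log(0.75) + math.log(1.0))
        assert t.scores["g"] == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        genes = random_genes(rng, 40)
        peaks = random_peaks(rng, 150)
        a = assign_closest_gene(genes, peaks, cap=1_000_000)
        dist = build_distance_distribution(genes, peaks, cap=1_000_000)
        t = score_closest_gene(genes, a, dist)
        expected = oracle_closest_gene_scores(genes, peaks, 1_000_000)
        for gid, s in t.scores.items():
            assert s == pytest.approx(expected[gid], rel=1e-9, abs=1e-12)

    def test_scale_invariance(self, rng):
        """Multiplying all coordinates and the cap by c leaves scores unchanged."""
        genes = random_genes(rng, 25, chrom_length=100_000)
        peaks = random_peaks(rng, 80, chrom_length=100_000)
        c = 7
        g2 = genes.assign(tss=genes["tss"] * c)
        p2 = peaks.assign(summit=peaks["summit"] * c)
        t1 = score_closest_gene(genes, assign_closest_gene(genes, peaks, 10**6),
                                build_distance_distribution(genes, peaks, 10**6))
        t2 = score_closest_gene(g2, assign_closest_gene(g2, p2, c * 10**6),
                                build_distance_distribution(g2, p2, c * 10**6))
        assert np.allclose(t1.scores.to_numpy(), t2.scores.to_numpy())


class TestScoreTableInvariants:
    def test_monotone_under_added_peak(self, rng):
        genes = random_genes(rng, 30, n_chroms=1, chrom_length=1_000_000)
        peaks = random_peaks(rng, 60, n_chroms=1, chrom_length=1_000_000)
        extra = pd.concat([peaks, _peaks(500_000, chrom="1")[-1:]], ignore_index=True)
        extra.loc[extra.index[-1], "peak_id"] = "pz_extra"
        L = 50_000
        lin1 = score_linear(genes, assign_window(genes, peaks, L)).scores
        lin2 = score_linear(genes, assign_window(genes, extra, L)).scores
        assert (lin2 >= lin1 - 1e-12).all()
        o1 = score_ouyang(genes, assign_all_peaks(genes, peaks), peaks).scores
        o2 = score_ouyang(genes, assign_all_peaks(genes, extra), extra).scores
        assert (o2 >= o1 - 1e-12).all()

    def test_input_order_invariance_of_scores(self, rng):
        genes = random_genes(rng, 40)
        peaks = random_peaks(rng, 150)
        g2 = genes.sample(frac=1, random_state=3).reset_index(drop=True)
        p2 = peaks.sample(frac=1, random_state=4).reset_index(drop=True)
        t1 = score_all_methods(genes, peaks, MethodConfig(chen_shuffles=3))
        t2 = score_all_methods(g2, p2, MethodConfig(chen_shuffles=3))
        for m in t1:
            pd.testing.assert_series_equal(
                t1[m].scores.sort_index(), t2[m].scores.sort_index())

    def test_every_gene_present(self, rng):
        genes = random_genes(rng, 40)
        peaks = random_peaks(rng, 50)
        tables = score_all_methods(genes, peaks, MethodConfig(chen_shuffles=3))
        for t in tables.values():
            assert set(t.scores.index) == set(genes["gene_id"])

    def test_ranking_deterministic_tie_break(self):
        t = ScoreTable(pd.Series({"b": 1.0, "a": 1.0, "c": 2.0}), "binary")
        assert t.ranked().index.tolist() == ["c", "a", "b"]
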