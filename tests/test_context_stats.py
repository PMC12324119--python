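import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from methconcord import annotation as anno
from methconcord.context_stats import (
    depth_binned_concordance,
    pearson,
    summarize_context,
)
from methconcord.mc_sets import decompose

from conftest import make_callset


def naive_pearson(x, y):
    """Two-pass textbook implementation (the oracle)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return None
    return sxy / (sxx * syy) ** 0.5


class TestPearson:
    def test_perfect_positive(self):
        assert pearson([10, 20, 30], [10, 20, 30]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([5.0, 40.0, 90.0])
        assert pearson(x, 100 - x) == pytest.approx(-1.0)

    def test_hand_computed_zero(self):
        # sum((x-mean)(y-mean)) = (-50)(-33.3)+0(66.6)+50(-33.3) = 0
        assert pearson([0, 50, 100], [0, 100, 0]) == pytest.approx(0.0)

    def test_zero_variance_undefined(self):
        assert pearson([5, 5, 5], [1, 2, 3]) is None

    def test_too_short_undefined(self):
        assert pearson([1.0], [2.0]) is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            pearson([1, 2], [1, 2, 3])

    def test_against_naive_oracle_and_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            x = rng.uniform(0, 100, n)
            y = rng.uniform(0, 100, n)
            got = pearson(x, y)
            expected = naive_pearson(list(x), list(y))
            assert got == pytest.approx(expected, abs=1e-12)
            assert got == pytest.approx(
                scipy.stats.pearsonr(x, y).statistic, abs=1e-9
            )

    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=20),
        st.lists(st.floats(0, 100), min_size=2, max_size=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_symmetric(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        r = pearson(x, y)
        if r is not None:
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
            assert pearson(y, x) == pytest.approx(r)


def two_label_setup(levels_a, levels_b, split):
    """Callsets over a toy chromosome; CpGs 0..n-1 at even positions,
    island = first `split` sites, open territory the rest."""
    n = len(levels_a)
    seq_positions = [2 * i for i in range(n)]
    cs_a = make_callset(
        [("chr1", p, int(l), 100 - int(l)) for p, l in
         zip(seq_positions, levels_a)]
    )
    cs_b = make_callset(
        [("chr1", p, int(l), 100 - int(l)) for p, l in
         zip(seq_positions, levels_b)]
    )
    seq = "CG" * n + "A" * 10_000
    islands = {"chr1": [(0, 2 * split)]}
    cat = anno.build_cpg_context(islands, {"chr1": len(seq)},
                                 flank_shore=10, flank_shelf_outer=20)
    idx = anno.index_reference_cpgs({"chr1": seq}, [cat])
    return cs_a, cs_b, cat, idx


class TestSummarizeContext:
    def test_proportion_normalized_by_reference(self):
        # 10 island CpGs, 6 methylated on A
        levels_a = [100] * 6 + [0] * 4 + [100] * 5
        levels_b = [0] * 15
        cs_a, cs_b, cat, idx = two_label_setup(levels_a, levels_b, 10)
        rows = summarize_context(decompose(cs_a, cs_b), cs_a, cs_b, idx, cat)
        island = next(r for r in rows if r.label == "island")
        assert island.n_ref_cpg == 10
        assert island.prop_mc_a == pytest.approx(0.60)
        assert island.prop_mc_b == 0.0

    def test_identical_callsets_r_one(self):
        rng = np.random.default_rng(1)
        levels = rng.integers(0, 101, 30)
        cs_a, cs_b, cat, idx = two_label_setup(levels, levels, 15)
        rows = summarize_context(decompose(cs_a, cs_a), cs_a, cs_a, idx, cat)
        for r in rows:
            if r.n_sites_corr >= 2 and r.pearson_r is not None:
                assert r.pearson_r == pytest.approx(1.0)

    def test_independent_uniform_levels_r_near_zero(self):
        rng = np.random.default_rng(2)
        n = 10_000
        la = rng.uniform(0, 100, n)
        lb = rng.uniform(0, 100, n)
        cs_a, cs_b, cat, idx = two_label_setup(la, lb, n)
        rows = summarize_context(decompose(cs_a, cs_b), cs_a, cs_b, idx, cat)
        island = next(r for r in rows if r.label == "island")
        assert island.n_sites_corr == n
        assert abs(island.pearson_r) < 0.05

    def test_partition_counts_conserve_mc_total(self, small_sim, small_calls):
        cfg, genome = small_sim
        cs_a, cs_b, _ = small_calls
        cat = anno.build_cpg_context(genome.islands, genome.genome_sizes)
        idx = anno.index_reference_cpgs(genome.sequences, [cat])
        report = decompose(cs_a, cs_b)
        rows = summarize_context(report, cs_a, cs_b, idx, cat)
        assert sum(r.n_mc_a for r in rows) == len(report.mc_a)
        assert sum(r.n_mc_b for r in rows) == len(report.mc_b)

    def test_zero_reference_label_flagged(self):
        levels = [100] * 5
        cs_a, cs_b, cat, idx = two_label_setup(levels, levels, 5)
        rows = summarize_context(decompose(cs_a, cs_b), cs_a, cs_b, idx, cat)
        shelf = next(r for r in rows if r.label == "shelf")
        assert shelf.n_ref_cpg == 0 and shelf.prop_mc_a is None


class TestDepthBinned:
    def test_inclusive_integer_bins(self):
        # all sites depth 10, edges [5, 10, 15] -> first bin "5-10x"
        cs_a = make_callset([("chr1", p, 5, 5) for p in range(10)])
        cs_b = make_callset([("chr1", p, 6, 4) for p in range(10)])
        out = depth_binned_concordance(cs_a, cs_b, [5, 10, 15])
        assert out.bins[0].label == "5-10x"
        assert out.bins[0].n_sites == 10
        assert out.bins[1].n_sites == 0

    def test_matched_only_with_no_equal_depths(self):
        cs_a = make_callset([("chr1", p, 5, 5) for p in range(5)])
        cs_b = make_callset([("chr1", p, 4, 4) for p in range(5)])
        out = depth_binned_concordance(cs_a, cs_b, [5, 10], matched_only=True)
        assert all(b.n_sites == 0 for b in out.bins)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            depth_binned_concordance(
                make_callset([]), make_callset([]), [5, 5, 10]
            )

    def test_histogram_marginals_sum_to_sites(self):
        rng = np.random.default_rng(3)
        entries_a, entries_b = [], []
        for p in range(200):
            d = int(rng.integers(5, 16))
            entries_a.append(("chr1", p, int(rng.integers(0, d + 1)),
                              d - int(rng.integers(0, d + 1)) % (d + 1)))
            entries_b.append(("chr1", p, int(rng.integers(0, d + 1)), d))
        cs_a = make_callset([(c, p, nm, max(nu, 0)) for c, p, nm, nu in entries_a])
        cs_b = make_callset(entries_b)
        out = depth_binned_concordance(cs_a, cs_b, [5, 10, 15, 20],
                                       final_open_bin=True)
        assert sum(int(b.hist2d.sum()) for b in out.bins) == sum(
            b.n_sites for b in out.bins
        )

    def test_per_bin_r_matches_sampling_model(self):
        """At matched depth d with theta ~ Uniform(0,1) and binomial reads,
        corr(level_a, level_b) = Var(theta)/(Var(theta)+E[theta(1-theta)]/d)
        = d/(d+2)."""
        rng = np.random.default_rng(4)
        n_per_depth = 5_000
        entries_a, entries_b = [], []
        pos = 0
        depths = [6, 12, 24, 40]
        for d in depths:
            theta = rng.uniform(0, 1, n_per_depth)
            ka = rng.binomial(d, theta)
            kb = rng.binomial(d, theta)
            for i in range(n_per_depth):
                entries_a.append(("chr1", pos, int(ka[i]), d - int(ka[i])))
                entries_b.append(("chr1", pos, int(kb[i]), d - int(kb[i])))
                pos += 1
        cs_a = make_callset(entries_a)
        cs_b = make_callset(entries_b)
        out = depth_binned_concordance(
            cs_a, cs_b, [5, 6, 12, 24, 40], matched_only=True
        )
        by_label = {b.label: b for b in out.bins}
        for d, label in [(6, "5-6x"), (12, "7-12x"), (24, "13-24x"),
                         (40, "25-40x")]:
            expected = d / (d + 2)
            assert by_label[label].n_sites == n_per_depth
            assert by_label[label].pearson_r == pytest.approx(
                expected, abs=0.05
            )

    def test_r_monotone_in_matched_depth(self):
        """Sampling-noise property: per-bin r is non-decreasing in depth."""
        rng = np.random.default_rng(9)
        entries_a, entries_b = [], []
        pos = 0
        for d in (4, 10, 20, 40):
            theta = rng.beta(2, 2, 3_000)
            for t in theta:
                ka, kb = rng.binomial(d, t), rng.binomial(d, t)
                entries_a.append(("chr1", pos, int(ka), d - int(ka)))
                entries_b.append(("chr1", pos, int(kb), d - int(kb)))
                pos += 1
        out = depth_binned_concordance(
            make_callset(entries_a), make_callset(entries_b),
            [3, 4, 10, 20, 40], matched_only=True,
        )
        rs = [b.pearson_r for b in out.bins if b.n_sites > 0]
        assert rs == sorted(rs)
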