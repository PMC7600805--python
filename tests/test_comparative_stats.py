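"""PGLS under Brownian motion, Spearman with exact small-n null, Wilcoxon
rank tests, binned tables and species summaries."""

from __future__ import annotations

import itertools
import math
from collections import namedtuple

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numt_atlas.comparative_stats import (
    bin_length_similarity,
    bm_covariance,
    load_tree,
    pgls_fit,
    random_ultrametric_tree,
    rank_test,
    simulate_bm,
    spearman,
    summarize_species,
)

FakeNumt = namedtuple("FakeNumt", "nuc_interval identity type_label")


def numt(length, identity=0.9, label="insertion"):
    return FakeNumt((0, length), identity, label)


# ---------------------------------------------------------------------------
# Brownian covariance and PGLS

FIVE_TIP = "((A:1.0,B:1.0):1.0,(C:1.5,(D:0.5,E:0.5):1.0):0.5);"


def five_tip_cov_by_hand():
    """C[i,j] = shared root-to-MRCA path length, enumerated explicitly."""
    taxa = ["A", "B", "C", "D", "E"]
    C = np.zeros((5, 5))
    depth = {"A": 2.0, "B": 2.0, "C": 2.0, "D": 2.0, "E": 2.0}
    for i, t in enumerate(taxa):
        C[i, i] = depth[t]
    C[0, 1] = C[1, 0] = 1.0  # (A,B) share the first internal edge
    for i, j in [(2, 3), (2, 4)]:  # C with D/E share 0.5
        C[i, j] = C[j, i] = 0.5
    C[3, 4] = C[4, 3] = 1.5  # (D,E) share 0.5 + 1.0
    return taxa, C


def test_bm_covariance_matches_hand_enumeration():
    tree = load_tree(FIVE_TIP)
    taxa, C_hand = five_tip_cov_by_hand()
    C = bm_covariance(tree, taxa)
    assert np.allclose(C, C_hand)


class TestPGLS:
    def test_star_tree_equals_ols(self):
        """With C proportional to the identity, GLS collapses to OLS at
        machine precision (beta, R^2 and p)."""
        tree = load_tree("(" + ",".join(f"t{i}:1.0" for i in range(10)) + ");")
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = 1.0 + 0.5 * x + rng.normal(size=10)
        fit = pgls_fit(y, x, tree)
        X = np.column_stack([np.ones(10), x])
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.beta, beta_ols, atol=1e-12)
        from scipy.stats import linregress

        lr = linregress(x, y)
        assert fit.p_value == pytest.approx(lr.pvalue, abs=1e-12)
        assert fit.r2 == pytest.approx(lr.rvalue**2, abs=1e-12)

    def test_exact_linear_relation_gives_r2_one(self):
        tree = load_tree(FIVE_TIP)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = pgls_fit(2.0 + 3.0 * x, x, tree)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.beta == pytest.approx([2.0, 3.0], abs=1e-10)

    def test_beta_matches_dense_linear_algebra_oracle(self):
        """beta-hat equals (X' C^-1 X)^-1 X' C^-1 y computed with an
        explicitly enumerated C and plain matrix inversion."""
        tree = load_tree(FIVE_TIP)
        taxa, C = five_tip_cov_by_hand()
        y = np.array([2.3, 1.9, 4.1, 3.3, 3.8])
        x = np.array([1.0, 1.2, 2.5, 2.0, 2.2])
        X = np.column_stack([np.ones(5), x])
        Ci = np.linalg.inv(C)
        beta_oracle = np.linalg.inv(X.T @ Ci @ X) @ X.T @ Ci @ y
        fit = pgls_fit(y, x, tree, taxa=taxa)
        assert np.max(np.abs(fit.beta - beta_oracle)) < 1e-10

    def test_slope_recovery_under_bm(self):
        """Mean estimated slope over BM simulations on 50-tip trees lies
        within 3 SE of the generating slope."""
        slopes = []
        for s in range(60):
            rng = np.random.default_rng(900 + s)
            tree = random_ultrametric_tree(50, rng)
            x = simulate_bm(tree, rng)
            y = 1.5 * x + simulate_bm(tree, rng)
            slopes.append(pgls_fit(y, x, tree).beta[1])
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 1.5) < 3 * se

    def test_degenerate_inputs_rejected(self):
        tree = load_tree("(a:0.0,b:0.0,c:0.0);")
        with pytest.raises(ValueError):
            pgls_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], tree)  # singular C
        t2 = load_tree("(a:1.0,b:1.0);")
        with pytest.raises(ValueError):
            pgls_fit([1.0, 2.0], [1.0, 2.0], t2)  # n < 3


# ---------------------------------------------------------------------------
# Spearman


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 7.0, 11.0]
        y = [0.1, 0.4, 0.5, 2.0, 30.0]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1, p1 = spearman(x, y)
        r2, p2 = spearman(-x, y)
        assert r2 == pytest.approx(-r1)
        assert p2 == pytest.approx(p1)

    def test_exact_p_matches_permutation_oracle_n8(self):
        """The n=8 p-value equals brute-force enumeration over all 8! rank
        permutations, with rho recomputed independently per permutation."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=8)
        y = 0.5 * x + rng.normal(size=8)
        rho, p = spearman(x, y)
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        count = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        assert p == pytest.approx(count / total)

    def test_t_approximation_for_larger_n(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho, p = spearman(x, y)
        from scipy.stats import spearmanr

        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# rank tests


class TestRankTest:
    def test_identical_groups_near_null_centre(self):
        a = np.arange(10.0)
        r = rank_test(a, a + 0.0, paired=False)
        # U statistic at its null mean, p close to 1
        assert r.statistic == pytest.approx(50.0)
        assert r.p_value > 0.9

    def test_complete_separation_exact_p(self):
        """a = b + 100 elementwise, n=10 per group: the one-sided rank-sum
        p equals 1 / C(20, 10)."""
        b = np.arange(10.0)
        r = rank_test(b + 100.0, b, alternative="greater")
        assert r.test_name == "rank-sum"
        assert r.p_value == pytest.approx(1.0 / math.comb(20, 10))

    @pytest.mark.parametrize("n", [8, 10])
    def test_signed_rank_exact_matches_enumeration(self, n):
        """Exact signed-rank p equals enumeration over all 2^n sign
        assignments of the ranked |differences|."""
        rng = np.random.default_rng(40 + n)
        diffs = rng.normal(0.4, 1.0, size=n)
        while len(np.unique(np.abs(diffs))) < n or (diffs == 0).any():
            diffs = rng.normal(0.4, 1.0, size=n)
        r = rank_test(diffs, alternative="greater")
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        w_obs = ranks[diffs > 0].sum()
        count = 0
        for signs in itertools.product([0, 1], repeat=n):
            w = sum(rk for rk, s in zip(ranks, signs) if s)
            count += w >= w_obs
        assert r.p_value == pytest.approx(count / 2**n)

    def test_null_calibration(self):
        """Type-I error of the rank-sum test at alpha = 0.05 over simulated
        null datasets stays inside the binomial confidence band."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            rejections += rank_test(a, b).p_value < 0.05
        rate = rejections / n_sim
        assert 0.05 - 3 * math.sqrt(0.05 * 0.95 / n_sim) <= rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sim)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_test([], [1.0])
        with pytest.raises(ValueError):
            rank_test([1.0], [])

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=15),
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=15),
    )
    def test_p_value_always_valid(self, a, b):
        r = rank_test(np.array(a), np.array(b))
        assert 0.0 <= r.p_value <= 1.0


# ---------------------------------------------------------------------------
# bin tables and species summaries


class TestBinTable:
    def test_all_in_first_bin(self):
        bt = bin_length_similarity([numt(300) for _ in range(5)], length_edges=[0, 1_000, 2_000])
        assert bt.length_props[0] == pytest.approx(1.0)
        assert bt.length_counts.sum() == 5

    def test_boundary_value_goes_right(self):
        bt = bin_length_similarity([numt(500)], length_edges=[0, 500, 1_000])
        assert list(bt.length_counts) == [0, 1]

    def test_last_edge_closed(self):
        bt = bin_length_similarity([numt(100, identity=1.0)], identity_edges=[0.7, 0.85, 1.0])
        assert list(bt.identity_counts) == [0, 1]

    def test_strictly_increasing_edges_required(self):
        with pytest.raises(ValueError):
            bin_length_similarity([numt(100)], length_edges=[0, 0, 100])

    def test_independent_divergence_gives_flat_mean_lengths(self):
        """Negative control: when identity is drawn independently of length,
        per-identity-bin mean lengths are flat within sampling error."""
        rng = np.random.default_rng(17)
        numts = [
            numt(int(rng.integers(100, 3_000)), identity=float(rng.uniform(0.7, 1.0)))
            for _ in range(2_000)
        ]
        bt = bin_length_similarity(numts)
        lengths = np.array([n.nuc_interval[1] for n in numts], dtype=float)
        overall = lengths.mean()
        sd = lengths.std(ddof=1)
        for mean_len, count in zip(bt.identity_mean_len, bt.identity_counts):
            if count >= 30:
                assert abs(mean_len - overall) < 4 * sd / math.sqrt(count)


class TestSummarizeSpecies:
    def test_zero_numts(self):
        s = summarize_species([], [], [], genome_size=10**6)
        assert s.n_numts == 0 and s.pct_genome == 0.0 and s.mean_len == 0.0

    def test_arithmetic(self):
        numts = [numt(100), numt(200, label="duplicate"), numt(300)]
        s = summarize_species(numts, ["c1"], ["f1"], genome_size=10**6)
        assert s.total_len == 600
        assert s.pct_genome == pytest.approx(0.06)
        assert s.mean_len == pytest.approx(200.0)
        assert s.n_insertion == 2 and s.n_duplicate == 1
        assert s.n_insertion + s.n_duplicate == s.n_numts
        assert s.n_complex_clusters == 1

    def test_matches_truth_aggregation(self, bundle):
        """Summaries over truth-derived records equal direct truth totals."""
        truth = bundle.result.truth
        FakeRec = namedtuple("FakeRec", "nuc_interval type_label")
        recs = [
            FakeRec(t.nuc_interval, "duplicate" if t.true_type == "duplicate" else "insertion")
            for t in truth
        ]
        gsize = sum(len(s) for s in bundle.result.nuclear.values())
        s = summarize_species(recs, [], [], genome_size=gsize)
        assert s.n_numts == len(truth)
        assert s.total_len == sum(t.nuc_interval[1] - t.nuc_interval[0] for t in truth)
        assert s.n_duplicate == sum(1 for t in truth if t.true_type == "duplicate")
        assert s.pct_genome == pytest.approx(100.0 * s.total_len / gsize)

    def test_invalid_genome_size(self):
        with pytest.raises(ValueError):
            summarize_species([], [], [], genome_size=0)
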