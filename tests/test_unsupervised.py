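"""PCA, PC-correlated windows and Fisher overlap enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import cfmodal as cf


def make_matrix(levels: np.ndarray) -> cf.WindowMethylationMatrix:
    windows = [f"chr1:{i * 1000}-{(i + 1) * 1000}" for i in range(levels.shape[1])]
    df = pd.DataFrame(levels, index=[f"s{i}" for i in range(levels.shape[0])], columns=windows)
    return cf.WindowMethylationMatrix(
        levels=df, coverage=df * 0 + 5, window_width=1000,
        n_positions=pd.Series(10, index=windows))


class TestPCA:
    def test_single_varying_window_explains_everything(self):
        levels = np.full((6, 4), 0.5)
        levels[:, 2] = np.linspace(0.1, 0.9, 6)
        res = cf.pca(make_matrix(levels), n_components=3, scale=False)
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self, tiny_matrix):
        res = cf.pca(tiny_matrix, n_components=7, scale=True)
        X = tiny_matrix.levels
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-8)

    def test_duplicated_samples_land_on_identical_coordinates(self):
        rng = np.random.default_rng(3)
        levels = rng.uniform(0, 1, size=(5, 6))
        levels = np.vstack([levels, levels[2]])  # s5 duplicates s2
        res = cf.pca(make_matrix(levels), n_components=3)
        np.testing.assert_allclose(res.scores.iloc[2], res.scores.iloc[5], atol=1e-10)

    def test_sign_convention_deterministic(self, tiny_matrix):
        a = cf.pca(tiny_matrix, n_components=3)
        b = cf.pca(tiny_matrix, n_components=3)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        for comp in a.loadings.columns:
            col = a.loadings[comp]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            cf.pca(make_matrix(np.full((1, 4), 0.5)))


class TestPCCorrelates:
    def test_window_equal_to_scores_ranks_first(self, tiny_matrix):
        res = cf.pca(tiny_matrix, n_components=2)
        levels = tiny_matrix.levels.copy()
        levels["chr9:0-1000"] = res.scores["PC1"]
        m = cf.WindowMethylationMatrix(levels=levels, coverage=levels * 0 + 5,
                                       window_width=1000,
                                       n_positions=pd.Series(10, index=levels.columns))
        top = cf.pc_correlates(m, res, component=1, proba=0.05, top_n=10)
        assert top.iloc[0]["window"] == "chr9:0-1000"
        assert top.iloc[0]["r"] == pytest.approx(1.0)

    def test_constant_window_excluded_not_error(self, tiny_matrix):
        levels = tiny_matrix.levels.copy()
        levels["chr9:0-1000"] = 0.5
        m = cf.WindowMethylationMatrix(levels=levels, coverage=levels * 0 + 5,
                                       window_width=1000,
                                       n_positions=pd.Series(10, index=levels.columns))
        res = cf.pca(tiny_matrix, n_components=2)
        top = cf.pc_correlates(m, res, component=1, proba=1.0, top_n=100)
        assert "chr9:0-1000" not in set(top["window"])

    def test_p_values_match_permutation_oracle(self):
        """Correlation-test p from the t transform agrees with a permutation
        null distribution of |r| within Monte-Carlo error."""
        rng = np.random.default_rng(7)
        n = 12
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n)  # moderate correlation
        r_obs = np.corrcoef(x, y)[0, 1]
        t = r_obs * math.sqrt((n - 2) / (1 - r_obs**2))
        from scipy import stats
        p_analytic = 2 * stats.t.sf(abs(t), df=n - 2)
        n_perm = 100_000
        perm_r = np.empty(n_perm)
        for i in range(n_perm):
            perm_r[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = (1 + np.sum(np.abs(perm_r) >= abs(r_obs))) / (1 + n_perm)
        mc_err = 4 * math.sqrt(p_analytic * (1 - p_analytic) / n_perm)
        assert abs(p_perm - p_analytic) < max(mc_err, 5e-4)

    def test_stable_under_sample_reordering(self, tiny_matrix):
        res = cf.pca(tiny_matrix, n_components=2)
        a = cf.pc_correlates(tiny_matrix, res, component=1, proba=1.0, top_n=6)
        shuffled = cf.WindowMethylationMatrix(
            levels=tiny_matrix.levels.iloc[::-1], coverage=tiny_matrix.coverage.iloc[::-1],
            window_width=1000, n_positions=tiny_matrix.n_positions)
        b = cf.pc_correlates(shuffled, res, component=1, proba=1.0, top_n=6)
        assert list(a["window"]) == list(b["window"])
        np.testing.assert_allclose(a["r"], b["r"], atol=1e-12)


def hypergeom_two_sided_p(a, b, c, d):
    """Brute-force two-sided Fisher p: enumerate all tables with the same
    margins, sum probabilities <= P(observed)."""
    n1, n2 = a + b, c + d
    k = a + c  # total overlapping
    n = n1 + n2

    def log_choose(m, j):
        return math.lgamma(m + 1) - math.lgamma(j + 1) - math.lgamma(m - j + 1)

    def prob(x):
        if x < 0 or x > n1 or k - x < 0 or k - x > n2:
            return 0.0
        return math.exp(log_choose(n1, x) + log_choose(n2, k - x) - log_choose(n, k))

    p_obs = prob(a)
    return sum(p for x in range(0, k + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))


class TestFisherOverlap:
    def build(self, n_query_hit, n_query, n_rest_hit, n_rest):
        """Window universe on chr1; feature covers the first hit windows."""
        wid = lambda i: f"chr1:{i * 1000}-{(i + 1) * 1000}"
        query = {wid(i) for i in range(n_query)}
        background = {wid(i) for i in range(n_query + n_rest)}
        hits = [wid(i) for i in range(n_query_hit)]
        hits += [wid(n_query + i) for i in range(n_rest_hit)]
        feature = cf.intervals.windows_frame(hits)[["chrom", "start", "end"]]
        return query, background, feature

    def test_p_matches_hypergeometric_enumeration(self):
        query, background, feature = self.build(10, 10, 10, 90)
        res = cf.fisher_overlap(query, background, feature)
        assert res.contingency == (10, 0, 10, 80)
        assert res.p_value == pytest.approx(hypergeom_two_sided_p(10, 0, 10, 80), abs=1e-10)

    def test_equal_overlap_fraction_gives_or_one(self):
        query, background, feature = self.build(5, 10, 45, 90)
        res = cf.fisher_overlap(query, background, feature)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_feature_covering_genome_gives_p_one(self):
        query, background, _ = self.build(0, 10, 0, 90)
        genome = pd.DataFrame([("chr1", 0, 10**9)], columns=["chrom", "start", "end"])
        res = cf.fisher_overlap(query, background, genome)
        assert res.contingency[0] == len(query)
        assert res.p_value == pytest.approx(1.0)

    def test_two_sided_p_symmetric_in_rows(self):
        query, background, feature = self.build(7, 10, 20, 90)
        res = cf.fisher_overlap(query, background, feature)
        a, b, c, d = res.contingency
        from scipy import stats
        _, p_swapped = stats.fisher_exact([[a, c], [b, d]], alternative="two-sided")
        assert res.p_value == pytest.approx(p_swapped, abs=1e-12)

    def test_empty_query_raises(self):
        _, background, feature = self.build(5, 10, 5, 90)
        with pytest.raises(ValueError):
            cf.fisher_overlap(set(), background, feature)


def test_planted_enhancer_signal_enriches_pc_correlates(signal_cohort):
    """Windows carrying planted group effects (restricted to enhancer windows
    by construction) make the PC that separates the groups enrich for the
    enhancer feature set: odds ratio > 1 at p < 0.01."""
    import cfmodal as cf
    atlas, _, truth, matrix = signal_cohort
    res = cf.pca(matrix, n_components=5)
    y = (truth.sample_labels.loc[res.scores.index] == "cancer").astype(float)
    best_pc = int(np.argmax([abs(np.corrcoef(res.scores[c], y)[0, 1])
                             for c in res.scores.columns])) + 1
    top = cf.pc_correlates(matrix, res, component=best_pc, proba=0.01, top_n=200)
    background = set(matrix.levels.dropna(axis=1).columns)
    enhancers = cf.cohort_annotation(atlas)["enhancers"]
    enr = cf.fisher_overlap(set(top["window"]), background, enhancers, "enhancer")
    assert enr.odds_ratio > 1
    assert enr.p_value < 0.01


def test_fisher_p_matches_enumeration_and_scipy_small_margins():
    """The exact-test p behind fisher_overlap equals both brute-force
    enumeration and scipy's fisher_exact on all tables with margins <= 12."""
    from scipy import stats
    from cfmodal.unsupervised import fisher_two_sided_p
    for n1, n2 in itertools.product([1, 3, 7, 12], repeat=2):
        for a in range(n1 + 1):
            for c in range(n2 + 1):
                b, d = n1 - a, n2 - c
                p_impl = fisher_two_sided_p(a, b, c, d)
                assert p_impl == pytest.approx(hypergeom_two_sided_p(a, b, c, d), abs=1e-10)
                _, p_scipy = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
                assert p_impl == pytest.approx(p_scipy, abs=1e-10)
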