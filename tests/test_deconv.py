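"""Atlas construction, tissue-specific region selection and NNLS deconvolution."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

import cfmodal as cf
from test_classify import welch_t_oracle


def calls_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_meth", "n_unmeth"])


def identity_atlas(values: np.ndarray, tissues=None) -> cf.TissueReferenceAtlas:
    tissues = tissues or [f"t{i}" for i in range(values.shape[1])]
    A = pd.DataFrame(values, index=[f"r{i}" for i in range(values.shape[0])], columns=tissues)
    return cf.TissueReferenceAtlas(A=A, tissue_groups=tissues, selected_regions={},
                                   tissue_correlations=A.corr())


class TestAggregateEnhancers:
    def test_pooled_ratio_within_region(self):
        enh = pd.DataFrame([("chr1", 0, 100)], columns=["chrom", "start", "end"])
        calls = {"s": calls_df([("chr1", 5, 7, 5, 5), ("chr1", 10, 12, 10, 0)])}
        out = cf.aggregate_enhancers(calls, enh)
        assert out.loc["chr1:0-100", "s"] == pytest.approx(0.75)

    def test_region_without_covered_cpgs_missing(self):
        enh = pd.DataFrame([("chr1", 0, 100), ("chr1", 200, 300)],
                           columns=["chrom", "start", "end"])
        calls = {"s": calls_df([("chr1", 5, 7, 1, 1)])}
        out = cf.aggregate_enhancers(calls, enh)
        assert np.isnan(out.loc["chr1:200-300", "s"])

    def test_min_cpgs_threshold(self):
        enh = pd.DataFrame([("chr1", 0, 100)], columns=["chrom", "start", "end"])
        calls = {"s": calls_df([("chr1", 5, 7, 1, 1), ("chr1", 10, 12, 1, 1)])}
        out = cf.aggregate_enhancers(calls, enh, min_cpgs=3)
        assert np.isnan(out.loc["chr1:0-100", "s"])


class TestTissueSpecificDmrs:
    def test_recovers_planted_regions(self, small_atlas, atlas_replicates):
        reps, labels = atlas_replicates
        sel = cf.tissue_specific_dmrs(reps, labels, k_per_tissue=10)
        for t in small_atlas.tissue_names:
            truth = small_atlas.specific_regions[t]
            recall = len(sel[t] & truth) / len(truth)
            assert recall >= 0.9

    def test_constant_region_never_selected(self):
        rng = np.random.default_rng(0)
        regions = [f"r{i}" for i in range(50)]
        samples = {}
        labels = {}
        for t in ("t0", "t1"):
            for rep in range(3):
                name = f"{t}_{rep}"
                col = rng.uniform(0, 1, 50)
                col[0] = 0.5  # constant region across everything
                samples[name] = col
                labels[name] = t
        df = pd.DataFrame(samples, index=regions)
        sel = cf.tissue_specific_dmrs(df, pd.Series(labels), k_per_tissue=5)
        assert "r0" not in set().union(*sel.values())

    def test_identical_tissues_yield_nothing_above_floor(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.2, 0.8, 40)
        samples, labels = {}, {}
        for t in ("t0", "t1"):
            for rep in range(3):
                name = f"{t}_{rep}"
                samples[name] = base + rng.normal(0, 0.005, 40)
                labels[name] = t
        df = pd.DataFrame(samples, index=[f"r{i}" for i in range(40)]).clip(0, 1)
        with pytest.warns(UserWarning):
            sel = cf.tissue_specific_dmrs(df, pd.Series(labels), k_per_tissue=5)
        assert all(len(s) == 0 for s in sel.values())

    def test_invariant_to_sample_order_and_replicate_duplication(self, atlas_replicates):
        reps, labels = atlas_replicates
        sel = cf.tissue_specific_dmrs(reps, labels, k_per_tissue=10)
        shuffled = reps[reps.columns[::-1]]
        sel_shuf = cf.tissue_specific_dmrs(shuffled, labels, k_per_tissue=10)
        assert sel == sel_shuf
        # duplicating every replicate leaves medians and spreads, hence
        # selection, unchanged
        dup = pd.concat([reps, reps.add_suffix("_dup")], axis=1)
        labels_dup = pd.concat([labels, labels.rename(lambda s: f"{s}_dup")])
        sel_dup = cf.tissue_specific_dmrs(dup, labels_dup, k_per_tissue=10)
        assert sel == sel_dup


class TestBuildReference:
    def test_single_replicate_equals_that_replicate(self):
        regions = [f"r{i}" for i in range(5)]
        df = pd.DataFrame({"t0_0": np.linspace(0, 1, 5), "t1_0": np.linspace(1, 0, 5)},
                          index=regions)
        labels = pd.Series({"t0_0": "t0", "t1_0": "t1"})
        ref = cf.build_reference(df, labels, {"t0": {"r0", "r1"}, "t1": {"r3"}})
        for region in ("r0", "r1", "r3"):
            assert ref.A.loc[region, "t0"] == df.loc[region, "t0_0"]

    def test_sister_tissues_cluster_together(self):
        """Hierarchical clustering of atlas columns pairs tissues generated
        from a shared baseline."""
        rng = np.random.default_rng(9)
        base_a = rng.uniform(0, 1, 200)
        base_b = rng.uniform(0, 1, 200)
        cols = {
            "a1": np.clip(base_a + rng.normal(0, 0.03, 200), 0, 1),
            "a2": np.clip(base_a + rng.normal(0, 0.03, 200), 0, 1),
            "b1": np.clip(base_b + rng.normal(0, 0.03, 200), 0, 1),
            "b2": np.clip(base_b + rng.normal(0, 0.03, 200), 0, 1),
        }
        A = pd.DataFrame(cols, index=[f"r{i}" for i in range(200)])
        Z = linkage(A.T.to_numpy(), method="average")
        clusters = fcluster(Z, t=2, criterion="maxclust")
        assert clusters[0] == clusters[1] and clusters[2] == clusters[3]
        assert clusters[0] != clusters[2]


class TestNNLS:
    def test_identity_atlas_recovers_vector(self):
        atlas = identity_atlas(np.eye(2))
        y = pd.Series([0.3, 0.7], index=atlas.A.index)
        c = cf.nnls_deconv(atlas, y)
        np.testing.assert_allclose(c.x.to_numpy(), [0.3, 0.7], atol=1e-12)

    def test_recovery_from_constructed_mixture(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(0, 1, size=(100, 5))
        x_true = rng.dirichlet(np.ones(5))
        atlas = identity_atlas(A)
        y = pd.Series(A @ x_true, index=atlas.A.index)
        c = cf.nnls_deconv(atlas, y)
        assert np.abs(c.x_normalized.to_numpy() - x_true).max() < 1e-6

    def test_constraint_clips_at_zero(self):
        atlas = identity_atlas(np.array([[1.0], [0.0]]))
        y = pd.Series([0.0, 1.0], index=atlas.A.index)
        c = cf.nnls_deconv(atlas, y)
        assert c.x.iloc[0] == 0.0

    def test_objective_never_worse_than_zero_vector(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(0, 1, size=(40, 4))
        atlas = identity_atlas(A)
        y = pd.Series(rng.uniform(0, 1, 40), index=atlas.A.index)
        c = cf.nnls_deconv(atlas, y)
        assert c.residual_norm <= np.linalg.norm(y.to_numpy()) + 1e-12

    def test_homogeneity_when_constraints_inactive(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(0.1, 1, size=(50, 3))
        x_true = np.array([0.5, 0.3, 0.2])
        atlas = identity_atlas(A)
        y = pd.Series(A @ x_true, index=atlas.A.index)
        c1 = cf.nnls_deconv(atlas, y)
        c2 = cf.nnls_deconv(atlas, 2.0 * y)
        np.testing.assert_allclose(2 * c1.x.to_numpy(), c2.x.to_numpy(), atol=1e-9)

    def test_missing_regions_dropped_pairwise(self):
        atlas = identity_atlas(np.eye(3))
        y = pd.Series([0.2, np.nan, 0.8], index=atlas.A.index)
        c = cf.nnls_deconv(atlas, y)
        assert c.n_regions_used == 2

    def test_all_missing_raises(self):
        atlas = identity_atlas(np.eye(2))
        y = pd.Series([np.nan, np.nan], index=atlas.A.index)
        with pytest.raises(ValueError):
            cf.nnls_deconv(atlas, y)


class TestCompareContribution:
    def test_identical_groups_p_one(self):
        stat, p = cf.compare_contribution({"a": [0.1, 0.1, 0.1], "b": [0.1, 0.1, 0.1]})
        assert (stat, p) == (0.0, 1.0)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.10, 0.02, 20)
        b = rng.normal(0.05, 0.02, 20)
        _, p = cf.compare_contribution({"a": a, "b": b})
        assert p < 0.01

    def test_matches_welch_oracle(self):
        a = [0.12, 0.10, 0.14, 0.11, 0.13]
        b = [0.08, 0.09, 0.07, 0.10, 0.06]
        stat, p = cf.compare_contribution({"a": a, "b": b})
        t_oracle, p_oracle = welch_t_oracle(a, b)
        assert stat == pytest.approx(t_oracle, rel=1e-9)
        assert p == pytest.approx(p_oracle, rel=1e-6)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            cf.compare_contribution({"a": [0.1], "b": [0.2, 0.3]})


class TestContributionModel:
    def test_tumor_admixture_detected(self):
        rng = np.random.default_rng(6)
        n = 20
        base = rng.dirichlet(np.ones(5) * 10, size=2 * n)
        tumor = np.zeros((2 * n, 1))
        tumor[n:] = 0.05  # cancer samples get 5% tumor-tissue admixture
        X = np.hstack([base * (1 - tumor), tumor])
        contrib = pd.DataFrame(X, index=[f"s{i}" for i in range(2 * n)],
                               columns=[f"t{i}" for i in range(6)])
        labels = pd.Series(["control"] * n + ["cancer"] * n, index=contrib.index)
        res = cf.contribution_model(contrib, labels, config=cf.ModelConfig(seed=0),
                                    positive="cancer")
        assert res.auc >= 0.9

    def test_label_feature_gives_perfect_auc(self):
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=[f"s{i}" for i in range(10)])
        contrib = pd.DataFrame({"t0": (labels == "a").astype(float),
                                "t1": 1 - (labels == "a").astype(float)})
        res = cf.contribution_model(contrib, labels, config=cf.ModelConfig(seed=0),
                                    positive="a")
        assert res.auc == 1.0
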