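"""Correlation matrices, Ward.D2 trait clustering (frozen R hclust oracle),
PCA in the prcomp convention and projection of new animals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from osteophen import cohortsim as cs
from osteophen import multivar as mv
from osteophen.errors import DesignError, ValidationError

# symmetric toy correlation matrix with two tight blocks and one loner;
# R> hclust(as.dist(1 - r), method = "ward.D2") gives merge heights
# 0.1, 0.2, 0.3719318934, 0.8296585643, 1.5408331080 and
# cutree(k = 3) = (1, 1, 1, 2, 2, 3)
R_ORACLE_R = np.array([
    [1.00, 0.90, 0.70, 0.10, 0.05, -0.20],
    [0.90, 1.00, 0.65, 0.15, 0.10, -0.10],
    [0.70, 0.65, 1.00, 0.20, 0.00, 0.05],
    [0.10, 0.15, 0.20, 1.00, 0.80, 0.30],
    [0.05, 0.10, 0.00, 0.80, 1.00, 0.25],
    [-0.20, -0.10, 0.05, 0.30, 0.25, 1.00],
])
R_ORACLE_HEIGHTS = [0.1, 0.2, 0.3719318934, 0.8296585643, 1.5408331080]


def _corr_from_matrix(r: np.ndarray) -> mv.CorrelationMatrix:
    traits = [f"t{i}" for i in range(len(r))]
    rdf = pd.DataFrame(r, index=traits, columns=traits)
    zeros = pd.DataFrame(np.zeros_like(r), index=traits, columns=traits)
    return mv.CorrelationMatrix(traits, rdf, zeros, zeros.astype(int),
                                zeros.astype(bool))


class TestPearsonMatrix:
    def test_self_correlation_and_diagonal(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 3, 5, 4, 6]})
        out = mv.pearson_matrix(df, ["a", "b"])
        assert out.r.loc["a", "a"] == 1.0
        assert out.p.loc["a", "a"] == 0.0
        assert not out.mask.loc["a", "a"]

    def test_perfect_anticorrelation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [-1.0, -2, -3, -4]})
        out = mv.pearson_matrix(df, ["x", "y"])
        assert out.r.loc["x", "y"] == pytest.approx(-1.0)

    def test_five_point_toy_matches_hand_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 3, 5, 4, 6])
        # cov = 9/4, sx = sy = sqrt(10)/2 -> r = 9/10
        df = pd.DataFrame({"x": x, "y": y})
        out = mv.pearson_matrix(df, ["x", "y"])
        assert out.r.loc["x", "y"] == pytest.approx(0.9, abs=1e-12)

    def test_symmetry_and_pairwise_counts(self, small_cohort):
        table, _ = small_cohort
        table = table.copy()
        table.loc[table.index[:5], "BMC"] = np.nan
        out = mv.pearson_matrix(table, ["BMC", "TMD", "Fu"])
        np.testing.assert_allclose(out.r, out.r.T)
        assert out.n.loc["BMC", "TMD"] == len(table) - 5
        assert out.n.loc["TMD", "Fu"] == len(table)

    def test_constant_trait_unavailable(self):
        df = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [1.0, 2, 3, 4]})
        out = mv.pearson_matrix(df, ["a", "b"])
        assert np.isnan(out.r.loc["a", "b"])
        assert ("a", "b") in out.unavailable

    def test_mask_marks_nonsignificant(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        out = mv.pearson_matrix(df, ["a", "b"])
        assert bool(out.mask.loc["a", "b"]) == (out.p.loc["a", "b"] > 0.05)


class TestClusterTraits:
    def test_matches_r_ward_d2_oracle(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        d = 1.0 - R_ORACLE_R
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="ward")
        np.testing.assert_allclose(z[:, 2], R_ORACLE_HEIGHTS, rtol=1e-9)
        labels = mv.cluster_traits(_corr_from_matrix(R_ORACLE_R), k=3)
        assert list(labels) == [1, 1, 1, 2, 2, 3]

    def test_two_perfect_blocks(self):
        r = np.full((4, 4), 0.0)
        r[:2, :2] = 1.0
        r[2:, 2:] = 1.0
        labels = mv.cluster_traits(_corr_from_matrix(r), k=2)
        assert labels.iloc[0] == labels.iloc[1] != labels.iloc[2] == labels.iloc[3]

    def test_k_one_single_cluster(self):
        labels = mv.cluster_traits(_corr_from_matrix(R_ORACLE_R), k=1)
        assert set(labels) == {1}

    def test_unavailable_entries_rejected(self):
        r = R_ORACLE_R.copy()
        r[0, 1] = r[1, 0] = np.nan
        corr = _corr_from_matrix(r)
        corr.unavailable = [("t0", "t1")]
        with pytest.raises(ValidationError, match="unavailable"):
            mv.cluster_traits(corr, k=2)

    def test_latent_factor_structure_recovered(self):
        # three latent factors, three traits each: Ward.D2 on 1 - r should
        # recover the factor assignment in nearly every replicate
        traits = tuple(
            cs.TraitSpec(f"{fac}{i}", "", 0.85, 0.05, 0.10, 0.0, 1.0, 0.0, fac, 0.9)
            for fac in ("size", "material", "lacunar") for i in range(3)
        )
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = cs.SimulationConfig(traits=traits, n_do_per_sex=0, seed=seed)
            table, _ = cs.simulate_founder_cohort(cfg)
            corr = mv.pearson_matrix(table, [t.name for t in traits])
            labels = mv.cluster_traits(corr, k=3)
            expected = np.repeat([1, 2, 3], 3)
            # compare partitions up to relabeling
            ok = all(
                (labels.iloc[i] == labels.iloc[j]) == (expected[i] == expected[j])
                for i in range(9) for j in range(i + 1, 9)
            )
            hits += ok
        assert hits / n_seeds >= 0.9


class TestPCA:
    def test_two_perfectly_correlated_traits(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        df = pd.DataFrame({"a": a, "b": 3.0 * a + 1.0})
        model = mv.fit_pca(df, ["a", "b"])
        assert model.explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_centered(self, small_cohort):
        table, _ = small_cohort
        model = mv.fit_pca(table, ["BMC", "Ct.Ar", "TMD", "Fu"])
        np.testing.assert_allclose(model.scores.mean(axis=0), 0.0, atol=1e-8)

    def test_eigenvalues_match_correlation_eigendecomposition(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        model = mv.fit_pca(df, list("abcd"))
        lam = np.linalg.eigvalsh(np.corrcoef(df.to_numpy(), rowvar=False))[::-1]
        np.testing.assert_allclose(model.explained, lam / lam.sum(), atol=1e-10)

    def test_matches_r_prcomp_oracle(self):
        # R> prcomp(x, center=TRUE, scale.=TRUE) on the 5x3 toy below
        x = np.array([[1.0, 2.0, 0.5], [2.0, 1.9, 1.0], [3.1, 3.5, 0.2],
                      [4.2, 3.9, 2.0], [5.0, 5.2, 1.4]])
        df = pd.DataFrame(x, columns=list("abc"))
        model = mv.fit_pca(df, list("abc"))
        # for standardized PCA the eigenvalues sum to p = 3, so
        # sdev_i = sqrt(3 * explained_i)
        got_sdev = np.sqrt(3.0 * model.explained)
        expected_sdev = [1.546064149101, 0.764943006789, 0.156677513477]
        np.testing.assert_allclose(got_sdev, expected_sdev, rtol=1e-9)
        np.testing.assert_allclose(
            np.abs(model.weightings["PC1"]),
            np.abs([0.633668498588, 0.599629021879, 0.488783459231]),
            rtol=1e-9,
        )

    def test_sign_convention_largest_loading_positive(self, small_cohort):
        table, _ = small_cohort
        model = mv.fit_pca(table, ["BMC", "Ct.Ar", "TMD", "Fu", "PYD"])
        w = model.weightings.to_numpy()
        assert (w[np.argmax(np.abs(w), axis=0), np.arange(w.shape[1])] > 0).all()

    def test_orthonormal_loadings_and_reconstruction(self, small_cohort):
        table, _ = small_cohort
        traits = ["BMC", "Ct.Ar", "TMD", "Fu", "PYD", "Su"]
        model = mv.fit_pca(table, traits)
        w = model.weightings.to_numpy()
        np.testing.assert_allclose(w.T @ w, np.eye(w.shape[1]), atol=1e-8)
        x = ((table[traits].dropna() - model.center) / model.scale).to_numpy()
        np.testing.assert_allclose(model.scores.to_numpy() @ w.T, x, atol=1e-8)

    def test_explained_invariant_to_trait_order(self, small_cohort):
        table, _ = small_cohort
        a = mv.fit_pca(table, ["BMC", "Ct.Ar", "TMD", "Fu"])
        b = mv.fit_pca(table, ["Fu", "TMD", "BMC", "Ct.Ar"])
        np.testing.assert_allclose(a.explained, b.explained, atol=1e-10)

    def test_constant_trait_named_in_error(self, small_cohort):
        table, _ = small_cohort
        table = table.assign(const=1.0)
        with pytest.raises(DesignError, match="const"):
            mv.fit_pca(table, ["BMC", "const"])


class TestProjection:
    def test_founder_mean_row_maps_to_origin(self, small_cohort):
        table, _ = small_cohort
        traits = ["BMC", "Ct.Ar", "TMD", "Fu"]
        model = mv.fit_pca(table, traits)
        mean_row = pd.DataFrame([model.center], columns=traits)
        mean_row["animal_id"] = "mean"
        out = mv.project_onto_pca(model, mean_row)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-10)

    def test_training_rows_reproduce_fitted_scores(self, small_cohort):
        table, _ = small_cohort
        traits = ["BMC", "Ct.Ar", "TMD", "Fu"]
        model = mv.fit_pca(table, traits)
        proj = mv.project_onto_pca(model, table)
        np.testing.assert_allclose(
            proj.to_numpy(), model.scores.to_numpy(), atol=1e-10
        )

    def test_projection_is_affine_in_inputs(self, small_cohort):
        table, _ = small_cohort
        traits = ["BMC", "Ct.Ar", "TMD", "Fu"]
        model = mv.fit_pca(table, traits)
        x = table[traits].iloc[0]
        y = table[traits].iloc[1]
        for alpha in (0.0, 0.3, 1.0):
            blend = pd.DataFrame([alpha * x + (1 - alpha) * y])
            px = mv.project_onto_pca(model, pd.DataFrame([x])).to_numpy()
            py = mv.project_onto_pca(model, pd.DataFrame([y])).to_numpy()
            pb = mv.project_onto_pca(model, blend).to_numpy()
            np.testing.assert_allclose(pb, alpha * px + (1 - alpha) * py, atol=1e-10)

    def test_rows_with_missing_traits_skipped(self, small_cohort):
        table, _ = small_cohort
        traits = ["BMC", "Ct.Ar", "TMD", "Fu"]
        model = mv.fit_pca(table, traits)
        broken = table.copy()
        broken.loc[broken.index[0], "BMC"] = np.nan
        out = mv.project_onto_pca(model, broken)
        assert len(out) == len(table) - 1
        assert out.attrs["skipped"] == 1


class TestNormalEllipse:
    def test_isotropic_cloud_near_circular(self):
        rng = np.random.default_rng(0)
        pts = pd.DataFrame(rng.normal(size=(20_000, 2)), columns=["PC1", "PC2"])
        (e,) = mv.normal_ellipse(pts, ["g"] * len(pts))
        assert e.axes[0] == pytest.approx(1.0, rel=0.05)
        assert e.axes[1] == pytest.approx(1.0, rel=0.05)
        assert not e.degenerate

    def test_anisotropic_axes_recovered(self):
        rng = np.random.default_rng(1)
        pts = pd.DataFrame(
            rng.normal(size=(10_000, 2)) * [2.0, 0.5], columns=["PC1", "PC2"]
        )
        (e,) = mv.normal_ellipse(pts, ["g"] * len(pts))
        assert e.axes[0] == pytest.approx(2.0, rel=0.05)
        assert e.axes[1] == pytest.approx(0.5, rel=0.05)

    def test_collinear_points_degenerate(self):
        pts = pd.DataFrame({"PC1": [0.0, 1, 2, 3], "PC2": [0.0, 2, 4, 6]})
        (e,) = mv.normal_ellipse(pts, ["g"] * 4)
        assert e.degenerate

    def test_level_scales_axes(self):
        rng = np.random.default_rng(2)
        pts = pd.DataFrame(rng.normal(size=(500, 2)), columns=["PC1", "PC2"])
        (e1,) = mv.normal_ellipse(pts, ["g"] * 500, level=1.0)
        (e2,) = mv.normal_ellipse(pts, ["g"] * 500, level=2.0)
        assert e2.axes[0] == pytest.approx(2 * e1.axes[0])

    def test_too_few_points_rejected(self):
        pts = pd.DataFrame({"PC1": [0.0, 1], "PC2": [0.0, 1]})
        with pytest.raises(ValidationError):
            mv.normal_ellipse(pts, ["g", "g"])
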