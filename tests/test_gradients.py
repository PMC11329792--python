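import numpy as np
import pytest

from sfgrad.functional import ActivationMatrix
from sfgrad.gradients import (
    DiffusionSpec,
    TopTermsProfile,
    activation_pca_first,
    axis_coordinate,
    correlate,
    diffusion_map,
    eigengap_k,
    functional_diversity,
    lexical_gradient,
    spectral_clusters,
    thickness_map,
    top_terms,
)
from sfgrad.matrix import ConnectivityMatrix


def block_affinity(sizes, within=1.0, between=0.05, seed=0):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    w = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    rng = np.random.default_rng(seed)
    w += rng.uniform(0, 0.01, size=(n, n))
    w = (w + w.T) / 2
    return ConnectivityMatrix(w), labels


class TestDiffusionMap:
    def test_constant_right_eigenvector_dropped(self):
        w, _ = block_affinity([4, 4])
        comps = diffusion_map(w, DiffusionSpec(n_components=3))
        # remaining components are orthogonal to the constant under the
        # stationary measure pi = d / sum(d)
        v = np.where(np.isnan(w.values), 0, w.values)
        np.fill_diagonal(v, 0)
        pi = v.sum(1) / v.sum()
        for k in range(comps.shape[1]):
            assert abs(np.sum(pi * comps[:, k])) < 1e-8

    def test_two_block_sign_separation(self):
        w, labels = block_affinity([6, 6], between=0.02)
        c1 = diffusion_map(w)[:, 0]
        side = np.sign(c1)
        assert len(np.unique(side[labels == 0])) == 1
        assert len(np.unique(side[labels == 1])) == 1
        assert side[labels == 0][0] != side[labels == 1][0]

    def test_t2_squares_eigenvalue_scaling(self):
        w, _ = block_affinity([5, 5], seed=1)
        c1 = diffusion_map(w, DiffusionSpec(t=1, n_components=4))
        c2 = diffusion_map(w, DiffusionSpec(t=2, n_components=4))
        # psi * lam^2 = (psi * lam) * lam: component-wise ratio is constant
        for k in range(4):
            ratio = c2[:, k] / c1[:, k]
            assert np.allclose(ratio, ratio[0], atol=1e-8)

    def test_disconnected_rejected(self):
        w = ConnectivityMatrix(np.kron(np.eye(2), np.ones((3, 3))) - np.eye(6))
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_map(w)

    def test_stationary_orthogonality(self):
        w, _ = block_affinity([4, 3, 5], seed=2)
        comps = diffusion_map(w, DiffusionSpec(n_components=5))
        v = np.where(np.isnan(w.values), 0, w.values)
        np.fill_diagonal(v, 0)
        pi = v.sum(1) / v.sum()
        for a in range(5):
            for b in range(a + 1, 5):
                assert abs(np.sum(pi * comps[:, a] * comps[:, b])) < 1e-8


class TestSpectralClustering:
    def test_three_blocks_recovered(self):
        w, labels = block_affinity([7, 7, 7], between=0.02)
        assert eigengap_k(w) == 3
        pred = spectral_clusters(w, 3, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, pred) == pytest.approx(1.0)

    def test_k1_single_label(self):
        w, _ = block_affinity([5])
        assert set(spectral_clusters(w, 1).tolist()) == {0}

    def test_k_exceeding_parcels_rejected(self):
        w, _ = block_affinity([4])
        with pytest.raises(ValueError, match="exceeds"):
            spectral_clusters(w, 5)


class TestTopTerms:
    def test_fewer_nonzero_than_k(self):
        fa = ActivationMatrix([[1.0, 0.0, 2.0, 0.0, 0.5]])
        prof = top_terms(fa, k=10)
        assert prof.term_indices[0].tolist() == [2, 0, 4]

    def test_weights_descending(self):
        rng = np.random.default_rng(0)
        fa = ActivationMatrix(rng.random((6, 20)))
        prof = top_terms(fa, k=10)
        for w in prof.weights:
            assert np.all(np.diff(w) <= 0)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.random((4, 15))
        prof = top_terms(ActivationMatrix(vals), k=5)
        for p in range(4):
            exp = np.argsort(-vals[p], kind="stable")[:5]
            assert prof.term_indices[p].tolist() == exp.tolist()


class TestFunctionalDiversity:
    def test_identical_embeddings_zero(self):
        prof = TopTermsProfile([np.array([0, 1, 2])], [np.array([1.0, 2.0, 3.0])], 10)
        emb = np.tile(np.array([1.0, 2.0]), (3, 1))
        assert functional_diversity(prof, emb).values[0] == pytest.approx(0.0)

    def test_two_points_distance_two(self):
        prof = TopTermsProfile([np.array([0, 1])], [np.array([1.0, 1.0])], 10)
        emb = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert functional_diversity(prof, emb).values[0] == pytest.approx(1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(8, 5))
        prof = TopTermsProfile([np.arange(8)], [rng.random(8) + 0.1], 10)
        d1 = functional_diversity(prof, emb).values[0]
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        d2 = functional_diversity(prof, emb @ q).values[0]
        assert d1 == pytest.approx(d2, abs=1e-10)

    def test_missing_embedding_dropped(self):
        prof = TopTermsProfile([np.array([0, 1, 2])], [np.array([1.0, 1.0, 1.0])], 10)
        emb = np.array([[0.0, 0.0], [2.0, 0.0], [np.nan, np.nan]])
        assert functional_diversity(prof, emb).values[0] == pytest.approx(1.0)


class TestLexicalGradient:
    def test_all_in_category(self):
        prof = TopTermsProfile([np.array([0, 1])], [np.array([2.0, 3.0])], 10)
        out = lexical_gradient(prof, np.array([1.0, 1.0]), "category_proportion")
        assert out.values[0] == pytest.approx(1.0)

    def test_equal_weights_mean(self):
        prof = TopTermsProfile([np.array([0, 1])], [np.array([1.0, 1.0])], 10)
        out = lexical_gradient(prof, np.array([1.0, 3.0]), "mean_score")
        assert out.values[0] == pytest.approx(2.0)

    def test_weighted_hand_computed(self):
        prof = TopTermsProfile([np.array([0, 1, 2])], [np.array([3.0, 1.0, 1.0])], 10)
        scores = np.array([2.0, np.nan, 4.0])
        out = lexical_gradient(prof, scores, "mean_score")
        # term 1 uncovered -> weights renormalize to (3, 1): (6+4)/4
        assert out.values[0] == pytest.approx(2.5)

    def test_no_covered_terms_missing(self):
        prof = TopTermsProfile([np.array([0])], [np.array([1.0])], 10)
        out = lexical_gradient(prof, np.array([np.nan]), "mean_score")
        assert np.isnan(out.values[0])


class TestActivationPCA:
    def test_rank_one_recovery(self):
        u = np.array([3.0, -1.0, 0.5, 2.0])
        v = np.array([1.0, 2.0, 0.5])
        fa = ActivationMatrix(np.outer(u, v))
        scores = activation_pca_first(fa).values
        centered = u - u.mean()
        r = np.corrcoef(scores, centered)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_matches_eigensolve_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.random((10, 6))
        fa = ActivationMatrix(x)
        scores = activation_pca_first(fa).values
        xc = x - x.mean(axis=0)
        vals, vecs = np.linalg.eigh(xc.T @ xc)
        pc1 = xc @ vecs[:, -1]
        r = np.corrcoef(scores, pc1)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            activation_pca_first(ActivationMatrix(np.ones((4, 3))))


class TestCorrelate:
    def test_identity(self):
        rng = np.random.default_rng(4)
        v = rng.random(30)
        rep = correlate(v, v, n_perm=500, seed=0)
        assert rep.spearman_r == pytest.approx(1.0)
        assert rep.p_null == pytest.approx(1 / 501)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        g = rng.random(40)
        f = rng.random(40)
        r1 = correlate(g, f, n_perm=200, seed=1).spearman_r
        r2 = correlate(g, np.exp(3 * f), n_perm=200, seed=1).spearman_r
        assert r1 == pytest.approx(r2)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(6)
        rep = correlate(rng.random(25), rng.random(25), n_perm=99, seed=2)
        assert 0 < rep.p_null <= 1

    def test_too_few_parcels_rejected(self):
        with pytest.raises(ValueError, match="10"):
            correlate(np.arange(5.0), np.arange(5.0), n_perm=10)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate(np.ones(20), np.arange(20.0), n_perm=10)


class TestVIF:
    def test_orthogonal_predictors(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        from sfgrad.gradients import vif

        np.testing.assert_allclose(vif([x1, x2]), [1.0, 1.0], atol=1e-10)

    def test_duplicate_predictor_infinite(self):
        from sfgrad.gradients import vif

        rng = np.random.default_rng(7)
        x = rng.random(30)
        out = vif([x, x.copy(), rng.random(30)])
        assert np.isinf(out[0]) and np.isinf(out[1])

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        from sfgrad.gradients import vif

        rng = np.random.default_rng(8)
        base = rng.random(50)
        maps = [base + rng.normal(scale=0.5, size=50) for _ in range(3)]
        got = vif(maps)
        design = sm.add_constant(np.column_stack(maps))
        exp = [variance_inflation_factor(design, i + 1) for i in range(3)]
        np.testing.assert_allclose(got, exp, rtol=1e-8)


class TestThicknessAndAxes:
    def test_mean_across_subjects(self, toy_atlas):
        out = thickness_map([np.full(3, 2.0), np.full(3, 3.0)], toy_atlas)
        np.testing.assert_allclose(out.values, 2.5)

    def test_callosal_variant_rejected(self):
        from sfgrad.atlas import Parcel, ParcelAtlas

        parcels = [Parcel(i, f"p{i}", "r", (float(i), 0, 0), 1.0) for i in range(696)]
        at = ParcelAtlas(parcels, variant="with-callosum")
        with pytest.raises(ValueError, match="without-callosum"):
            thickness_map([np.ones(696)], at)

    def test_matches_loop_oracle(self, toy_atlas):
        rng = np.random.default_rng(9)
        stack = [rng.random(3) for _ in range(4)]
        out = thickness_map(stack, toy_atlas).values
        for p in range(3):
            assert out[p] == pytest.approx(np.mean([s[p] for s in stack]))

    def test_axis_read_off(self, toy_atlas):
        np.testing.assert_allclose(axis_coordinate(toy_atlas, "axial").values, [0, 0, 10])
        np.testing.assert_allclose(axis_coordinate(toy_atlas, "coronal").values, [0, 4, 0])
        np.testing.assert_allclose(axis_coordinate(toy_atlas, "sagittal").values, [0, 3, 0])
        with pytest.raises(ValueError, match="axis"):
            axis_coordinate(toy_atlas, "diagonal")
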