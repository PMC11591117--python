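"""CCA fitting, oracle equivalence, invariances, and fusion."""

import numpy as np
import pytest

from ccawoa import FeatureMatrix, fit_cca, fuse
from ccawoa.cca import n_significant_components
from ccawoa.exceptions import AlignmentError, NumericalRankError

from _oracles import direct_eigen_correlations, first_canonical_correlation_oracle


def _random_views(n, p1, p2, seed, shared=0.5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p1))
    Y = shared * X @ rng.standard_normal((p1, p2)) + rng.standard_normal((n, p2))
    return FeatureMatrix(X), FeatureMatrix(Y)


class TestFitCCA:
    def test_identical_views_all_correlations_one(self, rng):
        X = FeatureMatrix(rng.standard_normal((80, 5)))
        model = fit_cca(X, X, ridge=1e-8)
        assert np.all(model.correlations > 1.0 - 1e-6)
        assert np.all(model.correlations <= 1.0 + 1e-8)

    def test_independent_noise_low_correlations(self):
        rng = np.random.default_rng(11)
        X = FeatureMatrix(rng.standard_normal((2000, 3)))
        Y = FeatureMatrix(rng.standard_normal((2000, 3)))
        model = fit_cca(X, Y)
        assert np.all(model.correlations < 0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_first_correlation_matches_numeric_maximization(self, seed):
        X, Y = _random_views(200, 4, 4, seed)
        model = fit_cca(X, Y, ridge=0.0)
        oracle = first_canonical_correlation_oracle(X.values, Y.values)
        assert model.correlations[0] == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", range(4))
    def test_all_correlations_match_direct_eigen_route(self, seed):
        X, Y = _random_views(150, 5, 3, seed)
        model = fit_cca(X, Y, ridge=0.0)
        ref = direct_eigen_correlations(X.values, Y.values)
        assert np.allclose(model.correlations, ref[: model.d], atol=1e-8)

    def test_correlations_sorted_and_bounded(self, rng):
        X, Y = _random_views(120, 5, 4, 3)
        model = fit_cca(X, Y)
        assert np.all(np.diff(model.correlations) <= 1e-12)
        assert np.all((model.correlations >= 0) & (model.correlations <= 1 + 1e-8))

    def test_projected_components_unit_variance(self):
        X, Y = _random_views(300, 4, 4, 5)
        model = fit_cca(X, Y, ridge=0.0)
        z = (X.values - model.mean_x) @ model.Wx
        assert np.allclose(z.var(0, ddof=1), 1.0, atol=1e-6)

    def test_affine_column_rescaling_invariance(self):
        X, Y = _random_views(250, 4, 3, 8)
        base = fit_cca(X, Y, ridge=0.0).correlations
        scales = np.array([3.0, 0.2, 7.0, 1.5])
        X2 = FeatureMatrix(X.values * scales + np.array([1.0, -2.0, 0.5, 9.0]))
        again = fit_cca(X2, Y, ridge=0.0).correlations
        assert np.allclose(base, again, atol=1e-8)

    def test_sample_mismatch_raises_alignment_error(self, rng):
        X = FeatureMatrix(rng.standard_normal((50, 3)))
        Y = FeatureMatrix(rng.standard_normal((40, 3)))
        with pytest.raises(AlignmentError):
            fit_cca(X, Y)

    def test_rank_deficient_without_ridge_raises(self, rng):
        base = rng.standard_normal((40, 2))
        X = FeatureMatrix(np.hstack([base, base]))  # duplicated columns
        Y = FeatureMatrix(rng.standard_normal((40, 3)))
        with pytest.raises(NumericalRankError, match="ridge"):
            fit_cca(X, Y, ridge=0.0)
        fit_cca(X, Y, ridge=1e-6)  # regularized fit succeeds

    def test_max_components_caps_width(self):
        X, Y = _random_views(100, 5, 5, 2)
        model = fit_cca(X, Y, max_components=2)
        assert model.d == 2

    def test_model_save_load_round_trip(self, tmp_path):
        X, Y = _random_views(90, 4, 3, 6)
        model = fit_cca(X, Y)
        path = tmp_path / "model.npz"
        model.save(path)
        from ccawoa import CCAModel

        again = CCAModel.load(path)
        assert np.allclose(model.Wx, again.Wx)
        assert np.allclose(model.correlations, again.correlations)
        assert np.allclose(fuse(model, X, Y).values, fuse(again, X, Y).values)


class TestComponentSelection:
    def test_truncate_keeps_leading_pairs(self):
        X, Y = _random_views(120, 5, 5, 4)
        model = fit_cca(X, Y)
        small = model.truncate(2)
        assert small.d == 2
        assert np.allclose(small.correlations, model.correlations[:2])
        assert np.allclose(small.Wx, model.Wx[:, :2])
        with pytest.raises(ValueError):
            model.truncate(0)

    def test_bartlett_counts_planted_correlated_pairs(self):
        # two shared latent signals buried among noise columns: the
        # sequential test should keep about that many pairs, far fewer
        # than the full numerical rank
        rng = np.random.default_rng(3)
        n = 600
        shared = rng.standard_normal((n, 2))
        X = np.hstack([shared + 0.3 * rng.standard_normal((n, 2)),
                       rng.standard_normal((n, 8))])
        Y = np.hstack([shared + 0.3 * rng.standard_normal((n, 2)),
                       rng.standard_normal((n, 8))])
        model = fit_cca(FeatureMatrix(X), FeatureMatrix(Y))
        d_sig = n_significant_components(model, n)
        assert 2 <= d_sig <= 4

    def test_bartlett_independent_noise_keeps_minimum(self):
        rng = np.random.default_rng(5)
        X = FeatureMatrix(rng.standard_normal((500, 6)))
        Y = FeatureMatrix(rng.standard_normal((500, 6)))
        model = fit_cca(X, Y)
        assert n_significant_components(model, 500) == 1


class TestFuse:
    def test_identical_views_sum_is_double_projection(self, rng):
        X = FeatureMatrix(rng.standard_normal((70, 4)))
        model = fit_cca(X, X, ridge=1e-8)
        fused = fuse(model, X, X, mode="sum")
        zx = (X.values - model.mean_x) @ model.Wx
        zy = (X.values - model.mean_y) @ model.Wy
        assert np.allclose(fused.values, zx + zy)

    def test_concat_width_is_twice_components(self):
        X, Y = _random_views(80, 5, 4, 1)
        model = fit_cca(X, Y)
        fused = fuse(model, X, Y, mode="concat")
        assert fused.n_features == 2 * model.d

    def test_labels_pass_through(self, labeled_matrix):
        X = labeled_matrix
        model = fit_cca(X, X, ridge=1e-8)
        fused = fuse(model, X, X)
        assert np.array_equal(fused.labels, X.labels)

    def test_column_mismatch_raises(self):
        X, Y = _random_views(60, 4, 4, 2)
        model = fit_cca(X, Y)
        bad = FeatureMatrix(X.values[:, :3])
        with pytest.raises(ValueError):
            fuse(model, bad, Y)
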