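"""CCA correctness, permutation inference, and stability diagnostics."""

import warnings

import numpy as np
import pytest

from sbmtools import (
    BEHAVIOR_COLUMNS,
    PhantomSpec,
    first_canonical_correlation,
    fit_cca,
    generate_phantom,
    loo_stability,
    permutation_test,
    subsample_reproducibility,
)
from sbmtools.cca import DegenerateColumnError, correct_coefficients


def _planted(n=300, k=20, seed=0):
    _, truth = generate_phantom(
        PhantomSpec(n_subjects=n, n_sources=k, source_radius_vox=1.5, seed=seed)
    )
    x = truth.loadings
    y = truth.phenotype[list(BEHAVIOR_COLUMNS)].to_numpy()
    return x, y, truth


class TestFitCCA:
    def test_identical_blocks_give_unit_correlations(self, rng):
        x = rng.normal(size=(40, 3))
        res = fit_cca(x, x.copy())
        np.testing.assert_allclose(res.correlations, 1.0, atol=1e-10)

    def test_mode_count_and_bonferroni(self, rng):
        res = fit_cca(rng.normal(size=(60, 5)), rng.normal(size=(60, 3)))
        assert res.n_modes == 3
        assert res.bonferroni_alpha == pytest.approx(0.05 / 3)

    def test_correlations_sorted_and_bounded(self, rng):
        res = fit_cca(rng.normal(size=(80, 6)), rng.normal(size=(80, 4)))
        assert np.all(np.diff(res.correlations) <= 1e-12)
        assert np.all((res.correlations >= 0) & (res.correlations <= 1))

    def test_variates_unit_variance_and_uncorrelated(self, rng):
        res = fit_cca(rng.normal(size=(100, 5)), rng.normal(size=(100, 4)))
        np.testing.assert_allclose(res.x_variates.std(axis=0, ddof=1), 1.0)
        cross = np.corrcoef(res.x_variates.T)
        assert np.abs(cross - np.eye(4)).max() < 1e-8

    def test_closed_form_first_correlation(self, rng):
        """r1^2 = largest eigenvalue of Sxx^-1 Sxy Syy^-1 Syx."""
        x = rng.normal(size=(50, 6))
        y = rng.normal(size=(50, 4))
        res = fit_cca(x, y)
        xc = x - x.mean(0)
        yc = y - y.mean(0)
        Sxx, Syy = xc.T @ xc, yc.T @ yc
        Sxy = xc.T @ yc
        ev = np.linalg.eigvals(
            np.linalg.inv(Sxx) @ Sxy @ np.linalg.inv(Syy) @ Sxy.T
        ).real
        assert res.correlations[0] == pytest.approx(np.sqrt(ev.max()), abs=1e-8)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.cross_decomposition import CCA as SkCCA

        x = rng.normal(size=(70, 5))
        y = rng.normal(size=(70, 3))
        res = fit_cca(x, y)
        sk = SkCCA(n_components=3, max_iter=2000).fit(x, y)
        u, v = sk.transform(x, y)
        sk_r = [abs(np.corrcoef(u[:, i], v[:, i])[0, 1]) for i in range(3)]
        np.testing.assert_allclose(res.correlations, sk_r, atol=1e-6)
        # weights agree up to sign/scale
        for i in range(3):
            w_ours = res.x_weights[:, i]
            w_sk = sk.x_rotations_[:, i]
            cos = abs(w_ours @ w_sk) / (np.linalg.norm(w_ours) * np.linalg.norm(w_sk))
            assert cos == pytest.approx(1.0, abs=1e-5)

    def test_column_rescaling_invariance(self, rng):
        x = rng.normal(size=(60, 4))
        y = rng.normal(size=(60, 3))
        r0 = fit_cca(x, y).correlations
        x2 = x.copy()
        x2[:, 1] = 7.5 * x2[:, 1] - 3.0
        y2 = y.copy()
        y2[:, 0] = -0.2 * y2[:, 0] + 11.0
        r1 = fit_cca(x2, y2).correlations
        np.testing.assert_allclose(r0, r1, atol=1e-8)

    def test_planted_mode_recovery(self):
        hits = 0
        for seed in range(5):
            x, y, truth = _planted(seed=seed)
            res = fit_cca(x, y)
            assert 0.6 <= res.correlations[0] <= 0.85
            w = res.x_weights[:, 0]
            cos = abs(w @ truth.brain_weights) / np.linalg.norm(w)
            hits += cos >= 0.9
        assert hits >= 4

    def test_zero_variance_column_named(self, rng):
        x = rng.normal(size=(30, 3))
        x[:, 1] = 2.0
        with pytest.raises(DegenerateColumnError, match="x2"):
            fit_cca(x, rng.normal(size=(30, 2)))

    def test_overfit_warning_when_n_too_small(self, rng):
        with pytest.warns(UserWarning, match="overfit"):
            fit_cca(rng.normal(size=(10, 12)), rng.normal(size=(10, 2)))


class TestCorrectedCoefficients:
    def test_orthonormal_block_proportional_to_raw(self, rng):
        # centered orthonormal x (QR against the intercept): structure
        # coefficients align with raw weights
        q = np.linalg.qr(np.column_stack([np.ones(60), rng.normal(size=(60, 4))]))[0]
        x = q[:, 1:] * np.sqrt(59)  # mean-zero, mutually orthonormal columns
        y = x[:, :2] @ rng.normal(size=(2, 3)) + 0.1 * rng.normal(size=(60, 3))
        res = fit_cca(x, y)
        w = res.x_weights[:, 0]
        c = res.x_corrected[:, 0]
        cos = abs(w @ c) / (np.linalg.norm(w) * np.linalg.norm(c))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_collinear_columns_get_equal_corrected_values(self, rng):
        base = rng.normal(size=60)
        x = np.column_stack([base, base, rng.normal(size=60)])
        y = (base + 0.1 * rng.normal(size=60))[:, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_cca(x, y)
        assert res.x_corrected[0, 0] == pytest.approx(res.x_corrected[1, 0], abs=1e-8)

    def test_sign_flip_equivariance(self, rng):
        x = rng.normal(size=(50, 4))
        y = rng.normal(size=(50, 3))
        res = fit_cca(x, y)
        res.x_variates = -res.x_variates
        xc, _ = correct_coefficients(res, x, y)
        np.testing.assert_allclose(xc, -res.x_corrected, atol=1e-10)


class TestPermutation:
    def test_identity_blocks_reach_lower_bound(self, rng):
        x = rng.normal(size=(40, 3))
        p, null = permutation_test(x, x.copy(), n_perm=200, seed=0)
        assert p == pytest.approx(1.0 / 201.0)
        assert null.shape == (200,)

    def test_planted_mode_significant(self):
        x, y, _ = _planted(seed=3)
        p, _ = permutation_test(x, y, n_perm=500, seed=0)
        assert p < 0.05 / min(x.shape[1], y.shape[1])

    def test_min_permutations_enforced(self, rng):
        with pytest.raises(ValueError):
            permutation_test(rng.normal(size=(30, 2)), rng.normal(size=(30, 2)),
                             n_perm=10)


class TestStability:
    def test_exact_linear_relation_gives_unit_fold_correlations(self, rng):
        x = rng.normal(size=(10, 2))
        y = x @ np.array([[1.0, 0.5], [0.2, -1.0]])
        rep = loo_stability(x, y)
        np.testing.assert_allclose(rep.loo_weight_corr_x, 1.0, atol=1e-6)
        np.testing.assert_allclose(rep.loo_weight_corr_y, 1.0, atol=1e-6)

    def test_strong_signal_beats_pure_noise_by_margin(self, rng):
        # pure-noise control sits in the genuinely ill-posed regime
        # (px + py > n - 1), where the main-mode weights are arbitrary
        # directions of a subspace intersection and LOO refits swing
        x, y, _ = _planted(seed=4)
        strong = loo_stability(x, y)
        xn = rng.normal(size=(55, 50))
        yn = rng.normal(size=(55, 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            noisy = loo_stability(xn, yn)
        assert strong.mean_x - noisy.mean_x >= 0.3

    def test_subsample_full_size_is_one(self):
        x, y, _ = _planted(n=150, k=10, seed=5)
        curve = subsample_reproducibility(x, y, sizes=[150], n_draws=3, seed=0)
        assert curve["mean_corr"].iloc[0] == pytest.approx(1.0)

    def test_subsample_flags_ill_posed_sizes(self):
        x, y, _ = _planted(n=150, k=10, seed=6)
        curve = subsample_reproducibility(x, y, sizes=[8, 60], n_draws=3, seed=0)
        assert bool(curve.loc[curve["size"] == 8, "ill_posed"].iloc[0])
        assert not bool(curve.loc[curve["size"] == 60, "ill_posed"].iloc[0])


def test_first_canonical_correlation_matches_full_fit(rng):
    x = rng.normal(size=(50, 4))
    y = rng.normal(size=(50, 3))
    assert first_canonical_correlation(x, y) == pytest.approx(
        fit_cca(x, y).correlations[0]
    )
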