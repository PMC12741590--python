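"""PLSC core: SVD correctness, sign convention, permutation and bootstrap."""

import numpy as np
import pytest
from scipy import stats

import connpls as cp
from connpls.plsc import compute_loadings, fdr_bh


def _random_instance(rng, n=20, m=6, q=3):
    return rng.standard_normal((n, m)), rng.standard_normal((n, q))


class TestFitPlsc:
    def test_singular_values_match_eigendecomposition_oracle(self, rng):
        """Independent oracle: s_l^2 are the eigenvalues of R R'."""
        X, Y = _random_instance(rng)
        n = X.shape[0]
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        Yz = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        R = Yz.T @ Xz / (n - 1)
        eigvals = np.sort(np.linalg.eigvalsh(R @ R.T))[::-1]
        lcs = cp.fit_plsc(X, Y)
        np.testing.assert_allclose(lcs.singular_values**2, eigvals, atol=1e-10)
        # saliences are the corresponding eigenvectors (up to sign)
        for l in range(lcs.n_components):
            v = lcs.clinical_saliences[:, l]
            resid = R @ R.T @ v - lcs.singular_values[l] ** 2 * v
            assert np.abs(resid).max() < 1e-10

    def test_reconstruction_of_cross_correlation(self, rng):
        X, Y = _random_instance(rng)
        n = X.shape[0]
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        Yz = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        R = Yz.T @ Xz / (n - 1)
        lcs = cp.fit_plsc(X, Y)
        recon = lcs.clinical_saliences @ np.diag(lcs.singular_values) @ lcs.brain_saliences.T
        np.testing.assert_allclose(recon, R, atol=1e-10)

    def test_noise_free_rank_one_data(self, rng):
        # equal-magnitude saliences are invariant under the column z-scoring,
        # so the exact rank-1 solution is recovered up to sign
        u = rng.choice([-1.0, 1.0], size=15) / np.sqrt(15)
        v = rng.choice([-1.0, 1.0], size=5) / np.sqrt(5)
        s = rng.standard_normal(30)
        lcs = cp.fit_plsc(np.outer(s, u), np.outer(s, v))
        assert np.isclose(lcs.cov_explained[0], 1.0)
        assert np.allclose(lcs.cov_explained[1:], 0.0, atol=1e-20)
        assert abs(abs(np.dot(lcs.brain_saliences[:, 0], u)) - 1.0) < 1e-10
        assert abs(abs(np.dot(lcs.clinical_saliences[:, 0], v)) - 1.0) < 1e-10

    def test_at_most_q_components(self, planted_cohort):
        lcs = cp.fit_plsc(planted_cohort.X_patients, planted_cohort.Y_patients)
        assert lcs.n_components == 9
        assert np.all(np.diff(lcs.singular_values) <= 1e-12)
        assert np.isclose(lcs.cov_explained.sum(), 1.0)

    def test_sign_convention_largest_clinical_entry_positive(self, fitted_planted):
        V = fitted_planted.clinical_saliences
        for l in range(V.shape[1]):
            assert V[np.argmax(np.abs(V[:, l])), l] > 0

    def test_latent_correlation_nonnegative(self, fitted_planted):
        assert fitted_planted.latent_correlation(0) >= 0

    def test_zero_variance_column_error_names_column(self, rng):
        X, Y = _random_instance(rng)
        X[:, 2] = 7.0
        with pytest.raises(ValueError, match=r"X.*\[2\]"):
            cp.fit_plsc(X, Y)

    def test_subject_reordering_invariance(self, rng):
        X, Y = _random_instance(rng)
        lcs = cp.fit_plsc(X, Y)
        perm = rng.permutation(X.shape[0])
        lcs2 = cp.fit_plsc(X[perm], Y[perm])
        np.testing.assert_allclose(lcs2.singular_values, lcs.singular_values, atol=1e-12)
        np.testing.assert_allclose(lcs2.brain_scores, lcs.brain_scores[perm], atol=1e-10)

    def test_variable_reordering_permutes_saliences_coherently(self, rng):
        X, Y = _random_instance(rng)
        cols = rng.permutation(X.shape[1])
        lcs = cp.fit_plsc(X, Y)
        lcs2 = cp.fit_plsc(X[:, cols], Y)
        np.testing.assert_allclose(lcs2.singular_values, lcs.singular_values, atol=1e-12)
        np.testing.assert_allclose(lcs2.brain_saliences, lcs.brain_saliences[cols], atol=1e-10)


class TestPermutationTest:
    def test_p_never_below_add_one_bound(self, planted_cohort):
        c = planted_cohort
        lcs = cp.permutation_test(c.X_patients, c.Y_patients, n_perm=50, seed=0)
        assert np.all(lcs.perm_p >= 1.0 / 51.0)
        assert np.all(lcs.perm_p <= 1.0)

    def test_planted_component_detected(self, planted_cohort):
        c = planted_cohort
        lcs = cp.permutation_test(c.X_patients, c.Y_patients, n_perm=200, seed=1)
        assert lcs.perm_p[0] <= 0.05
        assert lcs.perm_q[0] <= 0.05

    def test_null_p_for_lc1_is_not_small(self):
        spec = cp.CohortSpec(n_regions=10, n_patients=40, latent_effect=0.0, seed=77)
        c = cp.generate_cohort(spec)
        lcs = cp.permutation_test(c.X_patients, c.Y_patients, n_perm=200, seed=2)
        assert lcs.perm_p[0] > 0.05

    def test_recovery_improves_with_effect_size(self):
        """Mean |corr(u_hat, u*)| increases along a fixed-seed effect ladder."""
        means = []
        for eff in (0.5, 1.5, 3.0, 6.0):
            cors = []
            for seed in range(5):
                spec = cp.CohortSpec(n_regions=10, n_patients=60, latent_effect=eff,
                                     n_support_edges=20, seed=100 + seed)
                c = cp.generate_cohort(spec)
                lcs = cp.fit_plsc(c.X_patients, c.Y_patients)
                cors.append(abs(np.corrcoef(lcs.brain_saliences[:, 0], c.truth.u_star)[0, 1]))
            means.append(np.mean(cors))
        assert means == sorted(means)


class TestLoadings:
    def test_matches_per_column_pearson_oracle(self, rng):
        X, Y = _random_instance(rng)
        lcs = cp.fit_plsc(X, Y)
        ld = compute_loadings(X, Y, lcs, component=0)
        for k in range(X.shape[1]):
            r, _ = stats.pearsonr(X[:, k], lcs.brain_scores[:, 0])
            assert np.isclose(ld.brain.loadings[k], r, atol=1e-12)
        for j in range(Y.shape[1]):
            r, _ = stats.pearsonr(Y[:, j], lcs.clinical_scores[:, 0])
            assert np.isclose(ld.clinical.loadings[j], r, atol=1e-12)
        assert np.all(np.abs(ld.brain.loadings) <= 1.0)

    def test_degenerate_column_flagged_not_failed(self, rng):
        X, Y = _random_instance(rng)
        lcs = cp.fit_plsc(X, Y)
        Xd = X.copy()
        Xd[:, 1] = 3.14  # constant column supplied to loading computation only
        ld = compute_loadings(Xd, Y, lcs, component=0)
        assert ld.brain.degenerate[1]
        assert ld.brain.loadings[1] == 0.0

    def test_rank_one_support_loads_at_unity_and_off_support_flagged(self, rng):
        # noise-free rank-1 data: every support column is proportional to the
        # composite score (|loading| = 1); all-zero off-support columns are
        # degenerate-flagged with loading 0 rather than failing
        u = np.full(4, 0.5)
        v = np.full(4, 0.5)
        s = rng.standard_normal(25)
        X_fit = np.outer(s, u)
        Y = np.outer(s, v)
        lcs = cp.fit_plsc(X_fit, Y)
        X_full = np.hstack([X_fit, np.zeros((25, 6))])
        ld = compute_loadings(X_full, Y, lcs, component=0)
        assert np.all(np.abs(np.abs(ld.brain.loadings[:4]) - 1.0) < 1e-10)
        assert ld.brain.degenerate[4:].all()
        assert np.all(ld.brain.loadings[4:] == 0.0)


class TestBootstrapLoadings:
    def test_z_is_loading_over_sd_and_support_recovered(self):
        spec = cp.CohortSpec(n_regions=12, n_patients=80, latent_effect=3.0,
                             n_support_edges=10, seed=21)
        c = cp.generate_cohort(spec)
        ld = cp.bootstrap_loadings(c.X_patients, c.Y_patients, n_boot=200, seed=3)
        ok = ld.brain.boot_sd > 0
        np.testing.assert_allclose(
            ld.brain.z[ok], ld.brain.loadings[ok] / ld.brain.boot_sd[ok], atol=1e-12
        )
        support = np.zeros(spec.n_edges, dtype=bool)
        support[c.truth.brain_support] = True
        # strong planted effect on a small support: every support edge recovered
        assert ld.brain.sig_mask[support].all()
        assert ld.brain.sig_mask[~support].mean() <= 0.05

    def test_clinical_support_significant(self, planted_cohort):
        c = planted_cohort
        ld = cp.bootstrap_loadings(c.X_patients, c.Y_patients, n_boot=200, seed=4)
        nz = c.truth.v_star != 0
        assert ld.clinical.sig_mask[nz].all()

    def test_small_n_warns(self, rng):
        X, Y = _random_instance(rng, n=8)
        with pytest.warns(UserWarning, match="only 8 subjects"):
            cp.bootstrap_loadings(X, Y, n_boot=20, seed=0)


def _bh_stepup_oracle(p, alpha):
    """Literal Benjamini-Hochberg step-up, written independently."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestFdrBH:
    def test_all_ones_no_rejections(self):
        q, mask = fdr_bh(np.ones(10))
        assert not mask.any()
        assert np.allclose(q, 1.0)

    def test_single_small_p(self):
        q, mask = fdr_bh(np.array([0.01]))
        assert mask[0]
        assert np.isclose(q[0], 0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(50) ** 2
        q, mask = fdr_bh(p, alpha=0.05)
        # q < alpha can differ from the step-up rule only at exact ties with alpha
        oracle = _bh_stepup_oracle(p, 0.05)
        assert np.array_equal(mask, oracle)
        # monotonicity of q in p-order
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fdr_bh(np.array([0.5, 1.2]))
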