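"""Channel statistics and the three contribution measures.

The analytic oracle throughout is the closed-form variance of the
cross-correlation coefficient, Var(mu_q) = a~_q^T (A~ C_s A~^T + C_z) a~_q,
evaluated with the true model covariances; estimators computed from
simulated data must converge to it, and contribution measures computed from
exact statistics must hit their documented bounds exactly.
"""

import numpy as np
import pytest

import silencemap as sm
from silencemap.estimators import (ChannelStats, analytic_mu_variance,
                                   contribution_highres, contribution_lowres,
                                   estimate_channel_stats, hemispheric_ratio)
from silencemap.simulate import build_source_covariance
from conftest import referenced


def exact_stats(A_t, C_s, C_z):
    """ChannelStats with population (not sample) moments."""
    C_y = A_t @ C_s @ A_t.T + C_z
    return ChannelStats(var_y=np.diag(C_y).copy(),
                        var_mu=analytic_mu_variance(A_t, C_s, C_z),
                        C_z_hat=C_z, A_tilde=A_t)


def beta_oracle_lowres(A_t, C_s_diag_var, silent, C_z):
    """Direct evaluation of the defining sums for uncorrelated sources:
    beta_q = sum_{i not silent} (a_q^T a_i)^2 sigma^2 / sum_j (a_q^T a_j)^2."""
    p = A_t.shape[1]
    beta = np.zeros(p)
    for q in range(p):
        num = sum((A_t[:, q] @ A_t[:, i]) ** 2 * C_s_diag_var
                  for i in range(p) if i not in silent)
        den = sum((A_t[:, q] @ A_t[:, j]) ** 2 for j in range(p))
        beta[q] = num / den
    return beta


class TestChannelStats:
    def test_white_noise_variance(self):
        rng = np.random.default_rng(0)
        Y = 2.0 * rng.standard_normal((6, 100_000))
        A_t = rng.normal(size=(6, 10))
        st = estimate_channel_stats(Y, A_t, np.zeros((6, 6)))
        assert np.allclose(st.var_y, 4.0, rtol=0.05)

    def test_zero_recording_gives_zero_stats(self):
        A_t = np.ones((4, 6))
        st = estimate_channel_stats(np.zeros((4, 50)), A_t,
                                    np.zeros((4, 4)))
        assert np.all(st.var_y == 0) and np.all(st.var_mu == 0)

    def test_mu_variance_matches_closed_form(self, small_instance):
        """Noisy simulation: sample Var(mu) converges to the analytic value."""
        Y, A_t, C_z = referenced(small_instance)
        st = estimate_channel_stats(Y, A_t, C_z)
        truth = analytic_mu_variance(A_t, small_instance.source_model.C_s,
                                     C_z)
        rel = np.linalg.norm(st.var_mu - truth) / np.linalg.norm(truth)
        assert rel < 0.1

    def test_welch_matches_sample_for_white_data(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((4, 20_000)) * 3.0
        A_t = rng.normal(size=(4, 6))
        wide = estimate_channel_stats(Y, A_t, np.zeros((4, 4)),
                                      method="welch", fs=512.0,
                                      band=(0.0, 256.0))
        samp = estimate_channel_stats(Y, A_t, np.zeros((4, 4)))
        assert np.allclose(wide.var_y, samp.var_y, rtol=0.1)

    def test_welch_needs_enough_data(self):
        with pytest.raises(ValueError):
            estimate_channel_stats(np.zeros((3, 500)), np.ones((3, 4)),
                                   np.zeros((3, 3)), method="welch", fs=512.0)


class TestContributionLowres:
    def test_all_silent_gives_zero(self, small_leadfield):
        A_t = sm.make_reference_scheme(small_leadfield.n, 1).M @ small_leadfield.A
        C_z = 1e-4 * np.eye(A_t.shape[0])
        st = exact_stats(A_t, np.zeros((A_t.shape[1],) * 2), C_z)
        beta = contribution_lowres(st)
        assert np.allclose(beta.values, 0.0, atol=1e-15)

    def test_no_silence_reaches_sigma_s2(self, small_leadfield):
        """Uncorrelated sources, no silence, exact stats: beta = sigma_s^2."""
        A_t = sm.make_reference_scheme(small_leadfield.n, 2).M @ small_leadfield.A
        sigma_s2 = 1.7
        C_s = sigma_s2 * np.eye(A_t.shape[1])
        st = exact_stats(A_t, C_s, np.zeros((A_t.shape[0],) * 2))
        beta = contribution_lowres(st)
        assert np.allclose(beta.values, sigma_s2, rtol=1e-10)

    def test_tiny_instance_matches_defining_sums(self):
        rng = np.random.default_rng(3)
        n, p = 4, 5
        A_t = rng.normal(size=(n - 1, p))
        silent = {2}
        sigma_s2 = 0.8
        C_s = sigma_s2 * np.eye(p)
        for i in silent:
            C_s[i, i] = 0.0
        C_z = np.diag(rng.uniform(0.01, 0.05, n - 1))
        st = exact_stats(A_t, C_s, C_z)
        beta = contribution_lowres(st)
        oracle = beta_oracle_lowres(A_t, sigma_s2, silent, C_z)
        assert np.allclose(beta.values, oracle, rtol=1e-10)

    def test_scale_invariance(self):
        """Jointly rescaling Y (hence Var terms) and A~ cancels in beta."""
        rng = np.random.default_rng(4)
        A_t = rng.normal(size=(5, 8))
        C_s = np.eye(8)
        C_z = 0.1 * np.eye(5)
        c = 3.7
        b1 = contribution_lowres(exact_stats(A_t, C_s, C_z))
        b2 = contribution_lowres(exact_stats(c * A_t, C_s, c * c * C_z))
        assert np.allclose(b1.values, b2.values, rtol=1e-10)

    def test_monotone_in_silent_set(self):
        """Exact beta never increases when the silent set grows."""
        rng = np.random.default_rng(5)
        A_t = rng.normal(size=(6, 9))
        C_z = np.zeros((6, 6))
        prev = None
        for silent in [set(), {1}, {1, 4}, {1, 4, 7}]:
            C_s = np.eye(9)
            for i in silent:
                C_s[i, i] = 0.0
            beta = contribution_lowres(exact_stats(A_t, C_s, C_z)).values
            if prev is not None:
                assert np.all(beta <= prev + 1e-12)
            prev = beta


class TestContributionHighres:
    def test_no_silence_is_all_ones(self, small_grid, small_leadfield):
        model = build_source_covariance(small_grid)
        A_t = sm.make_reference_scheme(small_leadfield.n, 3).M @ small_leadfield.A
        st = exact_stats(A_t, model.C_s_full, np.zeros((A_t.shape[0],) * 2))
        bh = contribution_highres(st, model.C_s_full)
        assert np.allclose(bh.values, 1.0, rtol=1e-10)

    def test_all_silent_is_zero(self, small_grid, small_leadfield):
        model = build_source_covariance(small_grid)
        A_t = sm.make_reference_scheme(small_leadfield.n, 3).M @ small_leadfield.A
        st = exact_stats(A_t, np.zeros_like(model.C_s_full),
                         1e-3 * np.eye(A_t.shape[0]))
        bh = contribution_highres(st, model.C_s_full)
        assert np.allclose(bh.values, 0.0, atol=1e-15)

    def test_random_instance_matches_quadratic_forms(self):
        rng = np.random.default_rng(6)
        n, p = 6, 10
        A_t = rng.normal(size=(n - 1, p))
        B = rng.normal(size=(p, p))
        C_full = B @ B.T
        silent = [0, 3]
        C_s = C_full.copy()
        C_s[silent, :] = 0.0
        C_s[:, silent] = 0.0
        C_z = np.diag(rng.uniform(0.1, 0.3, n - 1))
        st = exact_stats(A_t, C_s, C_z)
        bh = contribution_highres(st, C_full).values
        S_full = A_t @ C_full @ A_t.T
        for q in range(p):
            a = A_t[:, q]
            num = a @ (A_t @ C_s @ A_t.T) @ a
            den = a @ S_full @ a
            assert bh[q] == pytest.approx(min(num / den, 1.0), rel=1e-9)


class TestHemisphericRatio:
    def test_symmetric_beta_is_all_ones(self, small_grid):
        beta = sm.ContributionVector(np.full(small_grid.p, 0.4), "beta_low")
        ratio = hemispheric_ratio(beta, small_grid)
        assert np.allclose(ratio.values, 1.0)

    def test_silent_patch_low_mirror_high(self, small_grid):
        vals = np.ones(small_grid.p)
        right = small_grid.hemisphere_indices("R")
        patch = right[:5]
        vals[patch] = 0.01
        ratio = hemispheric_ratio(
            sm.ContributionVector(vals, "beta_low"), small_grid).values
        assert np.allclose(ratio[patch], 0.01)
        assert np.allclose(ratio[small_grid.mirror_map[patch]], 1.0)
        assert np.all(ratio >= 0) and np.all(ratio <= 1)

    def test_strip_sources_get_one(self, strip_grid):
        rng = np.random.default_rng(7)
        beta = sm.ContributionVector(rng.uniform(0, 1, strip_grid.p),
                                     "beta_low")
        ratio = hemispheric_ratio(beta, strip_grid).values
        strip = strip_grid.hemisphere == "strip"
        assert np.all(ratio[strip] == 1.0)

    def test_doubly_silent_pair_resolves_to_one(self, small_grid):
        vals = np.ones(small_grid.p)
        q = int(small_grid.hemisphere_indices("R")[0])
        qm = small_grid.mirror_map[q]
        vals[[q, qm]] = 0.0
        ratio = hemispheric_ratio(
            sm.ContributionVector(vals, "beta_low"), small_grid).values
        assert ratio[q] == 1.0 and ratio[qm] == 1.0

    def test_pair_product_bounded(self, small_grid):
        rng = np.random.default_rng(8)
        beta = sm.ContributionVector(rng.uniform(0.1, 1, small_grid.p),
                                     "beta_low")
        ratio = hemispheric_ratio(beta, small_grid).values
        for q in range(small_grid.p):
            m = small_grid.mirror_map[q]
            if m >= 0:
                prod = ratio[q] * ratio[m]
                assert prod <= 1.0 + 1e-12
                if beta.values[q] == pytest.approx(beta.values[m]):
                    assert prod == pytest.approx(1.0)

    def test_explicit_baseline_variant(self, small_grid):
        rng = np.random.default_rng(9)
        b = rng.uniform(0.2, 1.0, small_grid.p)
        base = rng.uniform(0.2, 1.0, small_grid.p)
        ratio = hemispheric_ratio(
            sm.ContributionVector(b, "beta_low"), small_grid,
            baseline=sm.ContributionVector(base, "beta_low")).values
        assert np.allclose(ratio, np.minimum(b / base, 1.0))
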