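"""Correctness of the seven DE tests: oracles, degenerate rules, invariances."""

import numpy as np
import pytest
from itertools import combinations
from scipy import optimize, special, stats

import statsmodels.api as sm

from rdrbench.data import CountMatrix
from rdrbench.de_tests import (
    METHODS,
    bp4_glm_test,
    fit_zinb,
    hurdle_lrt,
    moderated_t_trend,
    nb_wald,
    run_method,
    ttest_log_cpm,
    wilcoxon_test,
    zinb_lrt,
)
from rdrbench.sim import BP4Params, bp4_rvs
from .conftest import make_matrix, matrix_from_logvalues


def _bigger_matrix(rng, n_iso=80, n_per_group=10):
    vals = rng.poisson(rng.gamma(1.0, 6.0, size=(n_iso, 2 * n_per_group)))
    vals[0] = 0
    return make_matrix(
        vals.astype(float), labels=["a"] * n_per_group + ["b"] * n_per_group
    )


class TestSharedContracts:
    """Properties every test must satisfy, checked on one overdispersed matrix."""

    @pytest.mark.parametrize("name", sorted(METHODS))
    def test_pvalues_in_unit_interval(self, rng, name):
        m = _bigger_matrix(rng)
        p = run_method(name, m).pvalues.to_numpy()
        ok = np.isfinite(p)
        assert np.all((p[ok] >= 0) & (p[ok] <= 1))

    @pytest.mark.parametrize("name", sorted(METHODS))
    def test_label_swap_leaves_p_unchanged(self, rng, name):
        m = _bigger_matrix(rng)
        swapped = CountMatrix(
            values=m.values,
            isoform_ids=m.isoform_ids,
            cell_ids=m.cell_ids,
            group_labels=np.where(m.group_labels == "a", "b", "a"),
            library_sizes=m.library_sizes,
        )
        p1 = run_method(name, m).pvalues.to_numpy()
        p2 = run_method(name, swapped).pvalues.to_numpy()
        ok = np.isfinite(p1) & np.isfinite(p2)
        assert np.allclose(p1[ok], p2[ok], rtol=1e-6, atol=1e-9)
        assert np.array_equal(np.isfinite(p1), np.isfinite(p2))

    @pytest.mark.parametrize("name", sorted(METHODS))
    def test_row_order_invariance(self, rng, name):
        m = _bigger_matrix(rng)
        perm = rng.permutation(m.n_isoforms)
        m_perm = CountMatrix(
            values=m.values[perm],
            isoform_ids=m.isoform_ids[perm],
            cell_ids=m.cell_ids,
            group_labels=m.group_labels,
            library_sizes=m.library_sizes,
        )
        p1 = run_method(name, m).pvalues
        p2 = run_method(name, m_perm).pvalues
        both = p1.loc[m.isoform_ids].to_numpy(), p2.loc[m.isoform_ids].to_numpy()
        ok = np.isfinite(both[0]) & np.isfinite(both[1])
        # trend-based tests refit a lowess on permuted x-order; allow tiny drift
        assert np.allclose(both[0][ok], both[1][ok], rtol=1e-5, atol=1e-8)

    @pytest.mark.parametrize("name", sorted(METHODS))
    def test_identical_groups_give_large_p(self, rng, name):
        # duplicate the same cells into both groups: no evidence of DE
        half = rng.poisson(rng.gamma(1.0, 6.0, size=(60, 10))).astype(float)
        vals = np.hstack([half, half])
        m = make_matrix(vals, labels=["a"] * 10 + ["b"] * 10)
        res = run_method(name, m)
        p = res.pvalues.to_numpy()
        ok = np.isfinite(p)
        assert np.all(p[ok] > 0.95)


class TestWelchTTest:
    def test_matches_hand_coded_welch_formula(self):
        a = np.array([10.0, 11.0, 12.0])
        b = np.array([20.0, 21.0, 22.0])
        m = matrix_from_logvalues(
            np.vstack([np.concatenate([a, b])]), labels=["x"] * 3 + ["y"] * 3
        )
        res = ttest_log_cpm(m)
        # independent Welch oracle
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (b.mean() - a.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p = 2 * stats.t.sf(abs(t), df)
        assert res.table["statistic"].iloc[0] == pytest.approx(t)
        assert res.table["pvalue"].iloc[0] == pytest.approx(p)
        assert res.table["effect"].iloc[0] == pytest.approx(10.0)

    def test_constant_equal_groups_give_p_one(self):
        y = np.full((1, 8), 3.0)
        m = matrix_from_logvalues(y, labels=["x"] * 4 + ["y"] * 4)
        res = ttest_log_cpm(m)
        assert res.table["pvalue"].iloc[0] == 1.0

    def test_affine_transform_of_log_values_preserves_p(self, rng):
        y = rng.uniform(1.0, 6.0, size=(40, 12))
        m1 = matrix_from_logvalues(y, labels=["x"] * 6 + ["y"] * 6)
        m2 = matrix_from_logvalues(2.0 * y + 1.0, labels=["x"] * 6 + ["y"] * 6)
        p1 = ttest_log_cpm(m1).pvalues.to_numpy()
        p2 = ttest_log_cpm(m2).pvalues.to_numpy()
        assert np.allclose(p1, p2)

    def test_too_few_cells_rejected(self):
        m = matrix_from_logvalues(np.ones((3, 3)), labels=["x", "x", "y"])
        with pytest.raises(ValueError):
            ttest_log_cpm(m)


class TestWilcoxon:
    def test_exact_p_by_exhaustive_enumeration(self):
        a, b = (1.0, 2.0, 3.0), (4.0, 5.0, 6.0)
        m = matrix_from_logvalues(
            np.array([a + b]), labels=["x"] * 3 + ["y"] * 3
        )
        p_pkg = wilcoxon_test(m).pvalues.iloc[0]
        # oracle: enumerate all 20 assignments of ranks to group x
        pooled = np.array(a + b)
        obs_u = sum(1 for i in a for j in b if i > j)  # U of group x
        us = []
        for idx in combinations(range(6), 3):
            ga = pooled[list(idx)]
            gb = pooled[[k for k in range(6) if k not in idx]]
            us.append(sum(1 for i in ga for j in gb if i > j))
        us = np.array(us)
        dev = abs(obs_u - 4.5)  # distance from the null mean n1*n2/2
        p_exact = np.mean(np.abs(us - 4.5) >= dev - 1e-12)
        assert p_exact == pytest.approx(0.1)
        assert p_pkg == pytest.approx(0.1)

    def test_complete_ties_give_p_one(self):
        m = matrix_from_logvalues(np.full((1, 10), 2.0), labels=["x"] * 5 + ["y"] * 5)
        assert wilcoxon_test(m).pvalues.iloc[0] == 1.0

    def test_invariant_to_monotone_transform(self, rng):
        y = rng.gamma(2.0, 2.0, size=(30, 16))
        lab = ["x"] * 8 + ["y"] * 8
        p1 = wilcoxon_test(matrix_from_logvalues(y, lab)).pvalues.to_numpy()
        p2 = wilcoxon_test(matrix_from_logvalues(np.sqrt(y), lab)).pvalues.to_numpy()
        assert np.allclose(p1, p2)


class TestModeratedT:
    def test_equal_variances_reduce_to_ordinary_t_with_more_df(self, rng):
        # identical residual pattern for every isoform -> equal variances
        resid = rng.normal(0, 1, size=12)
        resid[:6] -= resid[:6].mean()
        resid[6:] -= resid[6:].mean()
        mu = rng.uniform(2, 8, size=100)
        y = mu[:, None] + resid[None, :]
        lab = ["x"] * 6 + ["y"] * 6
        m = matrix_from_logvalues(y, lab)
        res = moderated_t_trend(m)
        # ordinary pooled t for comparison
        a, b = y[:, :6], y[:, 6:]
        d = 10
        sp2 = (((a - a.mean(1, keepdims=True)) ** 2).sum(1)
               + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)) / d
        t_ord = (b.mean(1) - a.mean(1)) / np.sqrt(sp2 * (1 / 6 + 1 / 6))
        assert np.isinf(res.prior_df)  # no variance scatter -> infinite prior df
        assert np.allclose(res.table["statistic"].to_numpy(), t_ord, rtol=1e-4)

    def test_posterior_variance_between_observed_and_trend(self, rng):
        y = rng.normal(4.0, 1.0, size=(150, 16)) * rng.uniform(
            0.5, 2.0, size=(150, 1)
        )
        m = matrix_from_logvalues(y, ["x"] * 8 + ["y"] * 8)
        res = moderated_t_trend(m)
        lo = np.minimum(res.residual_var, res.prior_var)
        hi = np.maximum(res.residual_var, res.prior_var)
        assert np.all(res.posterior_var >= lo - 1e-12)
        assert np.all(res.posterior_var <= hi + 1e-12)

    def test_moments_method_matches_independent_oracle(self, rng):
        """Prior df and trend reproduce a hand-coded moments estimator."""
        y = rng.normal(4.0, 1.0, size=(100, 12)) * rng.uniform(
            0.6, 1.8, size=(100, 1)
        )
        m = matrix_from_logvalues(y, ["x"] * 6 + ["y"] * 6)
        res = moderated_t_trend(m)
        # oracle: same moments equations, independently coded
        from statsmodels.nonparametric.smoothers_lowess import lowess

        a, b = y[:, :6], y[:, 6:]
        d = 10
        s2 = (((a - a.mean(1, keepdims=True)) ** 2).sum(1)
              + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)) / d
        amean = y.mean(1)
        z = np.log(s2)
        fitted = lowess(z, amean, frac=0.4, return_sorted=True)
        ztr = np.interp(amean, fitted[:, 0], fitted[:, 1])
        evar = np.var(z - ztr, ddof=1) - special.polygamma(1, d / 2)
        if evar > 0:
            d0 = 2 * optimize.brentq(
                lambda v: special.polygamma(1, v) - evar, 1e-3, 1e8
            )
        else:
            d0 = np.inf
        s0 = np.exp(ztr - special.digamma(d / 2) + np.log(d / 2))
        assert res.prior_df == pytest.approx(d0, rel=1e-3)
        assert np.allclose(res.prior_var, s0, rtol=1e-6)

    def test_small_panel_rejected(self, rng):
        y = rng.normal(0, 1, size=(10, 8))
        m = matrix_from_logvalues(np.abs(y), ["x"] * 4 + ["y"] * 4)
        with pytest.raises(ValueError, match="50 isoforms"):
            moderated_t_trend(m)


class TestNBWald:
    def test_zero_dispersion_matches_poisson_glm_oracle(self, rng):
        vals = rng.poisson(5.0, size=(30, 16)).astype(float)
        vals[0] += 1  # avoid degenerate rows
        lib = rng.uniform(50, 150, size=16) * 0 + vals.sum(0)
        m = make_matrix(vals, labels=["a"] * 8 + ["b"] * 8, library_sizes=lib)
        res = nb_wald(m, fixed_dispersion=0.0)
        offs = np.log(m.library_sizes / m.library_sizes.mean())
        X = np.column_stack([np.ones(16), np.r_[np.zeros(8), np.ones(8)]])
        for i in range(5):
            fit = sm.GLM(
                vals[i], X, family=sm.families.Poisson(), offset=offs
            ).fit()
            z_oracle = fit.params[1] / fit.bse[1]
            assert res.table["statistic"].iloc[i] == pytest.approx(
                z_oracle, rel=1e-4, abs=1e-6
            )

    def test_zero_total_in_one_group_gives_missing_p(self, rng):
        vals = rng.poisson(4.0, size=(20, 12)).astype(float)
        vals[3, :6] = 0.0
        vals[3, 6:] = 9.0
        m = make_matrix(vals, labels=["a"] * 6 + ["b"] * 6)
        res = nb_wald(m)
        assert np.isnan(res.table["pvalue"].iloc[3])
        assert "zero total" in res.table["note"].iloc[3]

    def test_effect_sign_follows_group_means(self, rng):
        vals = np.hstack(
            [rng.poisson(3.0, size=(40, 10)), rng.poisson(12.0, size=(40, 10))]
        ).astype(float)
        m = make_matrix(vals, labels=["a"] * 10 + ["b"] * 10,
                        library_sizes=np.full(20, 100.0))
        res = nb_wald(m)
        assert np.median(res.table["effect"]) > 0.5  # roughly log2(4) = 2


class TestZINB:
    def test_mle_recovers_generating_parameters(self, rng):
        pi, mu, r = 0.3, 5.0, 2.0
        n = 10_000
        y = rng.negative_binomial(r, r / (r + mu), size=n).astype(float)
        y[rng.random(n) < pi] = 0.0
        (pi_hat, mu_hat, r_hat), ll, _ = fit_zinb(y)
        assert abs(pi_hat - pi) < 0.03
        assert abs(mu_hat - mu) / mu < 0.05
        assert abs(r_hat - r) / r < 0.20

    def test_identical_groups_give_p_near_one(self, rng):
        half = rng.negative_binomial(2, 0.4, size=(10, 12)).astype(float)
        vals = np.hstack([half, half])
        m = make_matrix(vals, labels=["a"] * 12 + ["b"] * 12)
        res = zinb_lrt(m)
        p = res.pvalues.to_numpy()
        assert np.all(p[np.isfinite(p)] > 0.9)

    def test_lrt_detects_strong_mean_shift(self, rng):
        a = rng.negative_binomial(2, 2 / (2 + 3.0), size=(5, 40)).astype(float)
        b = rng.negative_binomial(2, 2 / (2 + 30.0), size=(5, 40)).astype(float)
        m = make_matrix(np.hstack([a, b]), labels=["a"] * 40 + ["b"] * 40)
        res = zinb_lrt(m)
        assert np.all(res.pvalues.to_numpy() < 1e-4)

    def test_min_group_size_enforced(self, rng):
        vals = rng.poisson(3.0, size=(8, 8)).astype(float)
        m = make_matrix(vals, labels=["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError):
            zinb_lrt(m)


class TestHurdle:
    def test_detection_only_difference_driven_by_logistic_part(self, rng):
        # same positive-value distribution, very different detection rates
        pos = rng.lognormal(2.0, 0.3, size=(1, 60))
        det_a = np.r_[np.ones(24), np.zeros(6)]
        det_b = np.r_[np.ones(6), np.zeros(24)]
        vals = pos * np.concatenate([det_a, det_b])[None, :]
        m = make_matrix(vals, labels=["a"] * 30 + ["b"] * 30,
                        library_sizes=np.full(60, 1e6))
        res = hurdle_lrt(m)
        assert res.stat_discrete[0] > 10.0
        assert res.stat_continuous[0] < res.stat_discrete[0] * 0.25
        assert res.pvalues.iloc[0] < 0.01

    def test_combined_statistic_is_sum_of_independent_part_fits(self, rng):
        vals = rng.poisson(1.2, size=(25, 30)).astype(float) * rng.uniform(
            0.5, 2.0, size=(25, 30)
        )
        lab = ["a"] * 15 + ["b"] * 15
        m = make_matrix(vals, labels=lab, library_sizes=np.full(30, 1e6))
        res = hurdle_lrt(m)
        y = np.log2(vals + 1.0)
        g = np.r_[np.zeros(15), np.ones(15)]
        for i in range(10):
            det = (vals[i] > 0).astype(float)
            if det.sum() < 2 or res.df[i] == 0:
                continue
            expected = 0.0
            if 0 < det.sum() < 30:
                logit1 = sm.Logit(det, np.column_stack([np.ones(30), g])).fit(disp=0)
                logit0 = sm.Logit(det, np.ones((30, 1))).fit(disp=0)
                expected += 2 * (logit1.llf - logit0.llf)
            pos = det > 0
            if (g[pos] == 0).sum() >= 1 and (g[pos] == 1).sum() >= 1 and pos.sum() >= 3:
                yi = y[i][pos]
                gi = g[pos]
                ss1 = sum(
                    (((yi[gi == k]) - yi[gi == k].mean()) ** 2).sum() for k in (0, 1)
                )
                ss0 = ((yi - yi.mean()) ** 2).sum()
                if ss0 > 1e-12:
                    expected += pos.sum() * np.log(max(ss0, 1e-300) / max(ss1, ss0 * 1e-8))
            assert res.statistics.iloc[i] == pytest.approx(expected, rel=1e-6, abs=1e-8)

    def test_too_few_positive_cells_skipped(self):
        vals = np.zeros((2, 12))
        vals[0, 0] = 5.0  # single positive cell
        vals[1, :] = 3.0
        m = make_matrix(vals, labels=["a"] * 6 + ["b"] * 6,
                        library_sizes=np.full(12, 1e6))
        res = hurdle_lrt(m)
        assert np.isnan(res.pvalues.iloc[0])
        assert "skipped" in res.table["note"].iloc[0]


class TestBP4GLM:
    def _simulate_two_groups(self, rng, lam1_fc, n_per_group, n_iso=60):
        base = BP4Params(2.0, 4.0, 60.0)
        shift = BP4Params(2.0, 4.0, 60.0 * lam1_fc)
        a = np.vstack([bp4_rvs(base, n_per_group, rng) for _ in range(n_iso)])
        b = np.vstack([bp4_rvs(shift, n_per_group, rng) for _ in range(n_iso)])
        vals = np.hstack([a, b])
        return make_matrix(
            vals, labels=["a"] * n_per_group + ["b"] * n_per_group,
            library_sizes=np.full(2 * n_per_group, 1e6),
        )

    def test_effect_recovers_fold_change(self, rng):
        m = self._simulate_two_groups(rng, lam1_fc=2.0, n_per_group=160)
        res = bp4_glm_test(m)
        # lambda1 doubled -> mean doubled -> effect ~ 1 on the log2 scale
        assert np.median(res.table["effect"]) == pytest.approx(1.0, abs=0.15)

    def test_power_increases_with_sample_size(self, rng):
        m_small = self._simulate_two_groups(rng, 2.0, n_per_group=20, n_iso=150)
        m_large = self._simulate_two_groups(rng, 2.0, n_per_group=80, n_iso=150)
        pow_small = np.mean(bp4_glm_test(m_small).pvalues.to_numpy() < 0.05)
        pow_large = np.mean(bp4_glm_test(m_large).pvalues.to_numpy() < 0.05)
        assert pow_large > pow_small

    def test_min_group_size_enforced(self, rng):
        vals = rng.poisson(3.0, size=(8, 8)).astype(float)
        m = make_matrix(vals, labels=["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError):
            bp4_glm_test(m)
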