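"""Seven natively implemented two-group differential-expression tests.

Every test shares the signature ``run(m: CountMatrix) -> DEResult`` and covers
one model family commonly applied to single-cell expression:

==============  ========================================  =================
name            model family                              input
==============  ========================================  =================
ttest           Welch t on log2(CPM+1)                    log2(CPM+1)
wilcoxon        Mann-Whitney rank sum                     log2(CPM+1)
limmatrend      empirical-Bayes moderated t with trend    log2(CPM+1)
nbwald          negative-binomial Wald (trended disp.)    rounded counts
zinb            zero-inflated NB likelihood-ratio test    rounded counts
hurdle          logistic + Gaussian two-part LRT          detection, log2CPM
bp4             beta-Poisson GLM Wald z                   CPM
==============  ========================================  =================

Degenerate rules shared by all tests: an isoform with zero variance in both
groups and equal means gets p = 1; isoforms a test cannot fit carry a missing
p-value with a note and are ranked last by the evaluation layer.  Count-model
likelihoods (nbwald, zinb) require integers and round half-to-even, since
upstream quantifiers produce non-integer expression estimates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import CountMatrix, compute_cpm, log_cpm


@dataclasses.dataclass
class DEResult:
    """Per-isoform p-values, statistics and effects from one method."""

    method: str
    table: pd.DataFrame  # columns: isoform_id, statistic, effect, pvalue, note

    def __post_init__(self) -> None:
        required = {"isoform_id", "statistic", "effect", "pvalue", "note"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"result table missing columns {sorted(missing)}")
        p = self.table["pvalue"].to_numpy(dtype=float)
        ok = np.isfinite(p)
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            self.table["pvalue"].to_numpy(dtype=float),
            index=self.table["isoform_id"].to_numpy(),
        )

    @property
    def statistics(self) -> pd.Series:
        return pd.Series(
            self.table["statistic"].to_numpy(dtype=float),
            index=self.table["isoform_id"].to_numpy(),
        )

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _result(m: CountMatrix, method: str, stat, effect, pval, note=None) -> DEResult:
    n = m.n_isoforms
    return DEResult(
        method,
        pd.DataFrame(
            {
                "isoform_id": m.isoform_ids,
                "statistic": np.asarray(stat, dtype=float),
                "effect": np.asarray(effect, dtype=float),
                "pvalue": np.asarray(pval, dtype=float),
                "note": note if note is not None else [""] * n,
            }
        ),
    )


def _two_groups(m: CountMatrix, min_per_group: int = 1):
    g1, g2 = m.groups()
    m1, m2 = m.group_masks()
    if m1.sum() < min_per_group or m2.sum() < min_per_group:
        raise ValueError(
            f"each group needs at least {min_per_group} cells "
            f"({g1}: {m1.sum()}, {g2}: {m2.sum()})"
        )
    return m1, m2


# -- 1. Welch t-test on log2(CPM+1) ----------------------------------------


def ttest_log_cpm(m: CountMatrix) -> DEResult:
    """Per-isoform two-sided Welch (unequal-variance) t-test on log2(CPM+1)."""
    g1, g2 = _two_groups(m, min_per_group=2)
    y = log_cpm(m)
    a, b = y[:, g1], y[:, g2]
    res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    stat = np.asarray(res.statistic, dtype=float)
    pval = np.asarray(res.pvalue, dtype=float)
    effect = b.mean(axis=1) - a.mean(axis=1)
    # degenerate: zero variance in both groups
    degen = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    eq = degen & np.isclose(effect, 0.0)
    ne = degen & ~np.isclose(effect, 0.0)
    stat[eq], pval[eq] = 0.0, 1.0
    stat[ne], pval[ne] = np.sign(effect[ne]) * np.inf, 0.0
    note = np.where(degen, "degenerate: zero variance in both groups", "")
    return _result(m, "ttest", stat, effect, pval, note)


# -- 2. Wilcoxon / Mann-Whitney rank-sum test ------------------------------


def wilcoxon_test(m: CountMatrix) -> DEResult:
    """Two-sided Mann-Whitney test per isoform on log2(CPM+1).

    Small tie-free samples use exact enumeration; larger ones the
    tie-corrected normal approximation (scipy's ``method='auto'``).
    """
    g1, g2 = _two_groups(m, min_per_group=1)
    y = log_cpm(m)
    a, b = y[:, g1], y[:, g2]
    res = stats.mannwhitneyu(b, a, axis=1, alternative="two-sided", method="auto")
    stat = np.asarray(res.statistic, dtype=float)
    pval = np.asarray(res.pvalue, dtype=float)
    # complete ties: rank variance 0 -> define p = 1
    allsame = np.all(y == y[:, [0]], axis=1)
    pval[allsame] = 1.0
    stat[allsame] = a.shape[1] * b.shape[1] / 2.0
    pval = np.clip(np.nan_to_num(pval, nan=1.0), 0.0, 1.0)
    effect = np.median(b, axis=1) - np.median(a, axis=1)
    note = np.where(allsame, "degenerate: complete ties", "")
    return _result(m, "wilcoxon", stat, effect, pval, note)


# -- 3. Moderated t with mean-variance trend -------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_t_trend(m: CountMatrix, trend_frac: float = 0.4) -> DEResult:
    """Empirical-Bayes moderated t with a mean-variance trend prior.

    Per isoform, a two-group linear model on log2(CPM+1) gives a pooled
    residual variance s^2 on d = n - 2 degrees of freedom.  log(s^2) is
    regressed on average expression by lowess; the moments of the scaled-F
    distribution of s^2 around that trend give a prior df d0 and per-isoform
    prior variances s0^2.  Posterior variances are the convex combination
    (d0 s0^2 + d s^2) / (d0 + d) and the moderated t is referred to a
    t-distribution on d + d0 df.
    """
    g1, g2 = _two_groups(m, min_per_group=2)
    if m.n_isoforms < 50:
        raise ValueError(
            "mean-variance trend needs >= 50 isoforms; "
            "use ttest_log_cpm for small panels"
        )
    y = log_cpm(m)
    a, b = y[:, g1], y[:, g2]
    n1, n2 = a.shape[1], b.shape[1]
    d = n1 + n2 - 2
    mean1, mean2 = a.mean(axis=1), b.mean(axis=1)
    ss = ((a - mean1[:, None]) ** 2).sum(axis=1) + ((b - mean2[:, None]) ** 2).sum(
        axis=1
    )
    s2 = ss / d
    amean = y.mean(axis=1)

    ok = s2 > 1e-12
    if ok.sum() < 10:
        raise ValueError("too few isoforms with positive variance for a trend")
    z = np.log(s2[ok])
    fit = lowess(z, amean[ok], frac=trend_frac, return_sorted=True)
    ztrend = np.interp(amean, fit[:, 0], fit[:, 1])
    resid = z - np.interp(amean[ok], fit[:, 0], fit[:, 1])
    evar = float(np.var(resid, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
    else:
        d0 = np.inf
    # E[log s^2] = log s0^2 + digamma(d/2) - log(d/2)
    log_s0sq = ztrend - special.digamma(d / 2.0) + np.log(d / 2.0)
    s0sq = np.exp(log_s0sq)
    if np.isinf(d0):
        s2_post = s0sq
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d + d0
    effect = mean2 - mean1
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = effect / se
    if np.isinf(df_total):
        pval = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pval = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    degen = se == 0
    eq = degen & np.isclose(effect, 0.0)
    tstat[eq], pval[eq] = 0.0, 1.0
    ne = degen & ~np.isclose(effect, 0.0)
    tstat[ne], pval[ne] = np.sign(effect[ne]) * np.inf, 0.0
    note = np.where(degen, "degenerate: zero posterior variance", "")
    res = _result(m, "limmatrend", tstat, effect, pval, note)
    # expose shrinkage diagnostics for inspection
    res.prior_df = d0  # type: ignore[attr-defined]
    res.prior_var = s0sq  # type: ignore[attr-defined]
    res.posterior_var = s2_post  # type: ignore[attr-defined]
    res.residual_var = s2  # type: ignore[attr-defined]
    return res


# -- 4. Negative-binomial Wald test ----------------------------------------


def _nb_irls_group(
    y: np.ndarray, mask: np.ndarray, offs: np.ndarray, phi: np.ndarray, n_iter: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Group-intercept NB IRLS: returns (coef a_g, sum of IRLS weights).

    Model log mu_ij = a_g + o_j with Var = mu (1 + phi mu); with a single
    group intercept the normal equations decouple to scalar updates.
    """
    ysub = y[:, mask]
    e_o = np.exp(offs[mask])[None, :]
    tot = ysub.sum(axis=1)
    a = np.log((tot + 0.5) / e_o.sum())  # Poisson-flavoured start
    for _ in range(n_iter):
        mu = np.exp(a)[:, None] * e_o
        w = mu / (1.0 + phi[:, None] * mu)
        sw = w.sum(axis=1)
        step = ((ysub - mu) / np.maximum(mu, 1e-300) * w).sum(axis=1) / np.maximum(
            sw, 1e-300
        )
        step = np.clip(step, -5.0, 5.0)
        a = a + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(a)[:, None] * e_o
    w = mu / (1.0 + phi[:, None] * mu)
    return a, w.sum(axis=1)


def nb_wald(
    m: CountMatrix,
    prior_df: float = 10.0,
    disp_trend_frac: float = 0.5,
    fixed_dispersion: float | None = None,
) -> DEResult:
    """Negative-binomial Wald test with trend-shrunk moment dispersions.

    Values are rounded half-to-even to integers.  A log-link NB model with a
    log library-size offset and a group effect is fitted per isoform; the
    dispersion is a Pearson method-of-moments estimate shrunk (in log space,
    with ``prior_df`` pseudo-observations) toward a lowess trend over mean
    expression.  The group coefficient is tested with a Wald z.
    ``fixed_dispersion`` bypasses estimation (0 reduces the model to Poisson
    regression).
    """
    g1, g2 = _two_groups(m, min_per_group=2)
    y = np.rint(m.values)
    offs = np.log(m.library_sizes / np.mean(m.library_sizes))
    n = m.n_cells
    e_o = np.exp(offs)

    tot1 = y[:, g1].sum(axis=1)
    tot2 = y[:, g2].sum(axis=1)
    allzero = (tot1 == 0) & (tot2 == 0)
    onezero = ((tot1 == 0) | (tot2 == 0)) & ~allzero

    # Poisson (group factor + offset) MLE is closed-form: used for dispersion
    with np.errstate(divide="ignore"):
        a1_p = np.log(tot1) - np.log(e_o[g1].sum())
        a2_p = np.log(tot2) - np.log(e_o[g2].sum())
    mu_p = np.where(g1[None, :], np.exp(a1_p)[:, None], np.exp(a2_p)[:, None]) * e_o[None, :]
    mu_p = np.nan_to_num(mu_p, nan=0.0, posinf=0.0, neginf=0.0)
    safe_mu = np.maximum(mu_p, 1e-300)
    with np.errstate(invalid="ignore"):
        contrib = ((y - mu_p) ** 2 - mu_p) / safe_mu**2
    contrib[mu_p == 0] = 0.0
    phi_mom = np.maximum(contrib.sum(axis=1) / max(n - 2, 1), 0.0)

    if fixed_dispersion is not None:
        phi = np.full(m.n_isoforms, float(fixed_dispersion))
    else:
        # trend of log dispersion over log mean count, on usable isoforms
        eps = 1e-4
        mean_count = y.mean(axis=1)
        usable = ~allzero & ~onezero
        logphi = np.log(phi_mom + eps)
        if usable.sum() >= 10:
            fitted = lowess(
                logphi[usable],
                np.log(mean_count[usable] + 0.5),
                frac=disp_trend_frac,
                return_sorted=True,
            )
            logphi_trend = np.interp(
                np.log(mean_count + 0.5), fitted[:, 0], fitted[:, 1]
            )
        else:
            logphi_trend = np.full(
                m.n_isoforms, np.median(logphi[usable]) if usable.any() else 0.0
            )
        d = max(n - 2, 1)
        phi = np.exp((d * logphi + prior_df * logphi_trend) / (d + prior_df)) - eps
        phi = np.maximum(phi, 0.0)

    a1, sw1 = _nb_irls_group(y, g1, offs, phi)
    a2, sw2 = _nb_irls_group(y, g2, offs, phi)
    effect_nat = a2 - a1
    se = np.sqrt(1.0 / np.maximum(sw1, 1e-300) + 1.0 / np.maximum(sw2, 1e-300))
    with np.errstate(invalid="ignore"):
        zstat = effect_nat / se
    pval = 2.0 * stats.norm.sf(np.abs(zstat))

    stat = np.asarray(zstat, dtype=float)
    pval = np.asarray(pval, dtype=float)
    effect = effect_nat / np.log(2.0)
    note = np.array([""] * m.n_isoforms, dtype=object)
    stat[allzero], effect[allzero], pval[allzero] = 0.0, 0.0, 1.0
    note[allzero] = "degenerate: all zero counts"
    stat[onezero] = np.nan
    pval[onezero] = np.nan
    effect[onezero] = np.nan
    note[onezero] = "not fitted: zero total count in one group"
    return _result(m, "nbwald", stat, effect, pval, note)


# -- 5. Zero-inflated NB likelihood-ratio test -----------------------------


def _zinb_nll(theta: np.ndarray, y: np.ndarray) -> float:
    w, lmu, lr = theta
    pi = special.expit(w)
    mu, r = np.exp(lmu), np.exp(lr)
    lp = np.log(r) - np.log(r + mu)
    lq = np.log(mu) - np.log(r + mu)
    lnb0 = r * lp
    zero = y == 0
    ll = np.empty_like(y, dtype=float)
    ll[zero] = np.logaddexp(np.log(pi + 1e-300), np.log1p(-pi) + lnb0)
    ypos = y[~zero]
    ll[~zero] = (
        np.log1p(-pi)
        + special.gammaln(ypos + r)
        - special.gammaln(r)
        - special.gammaln(ypos + 1.0)
        + r * lp
        + ypos * lq
    )
    return -float(ll.sum())


_ZINB_BOUNDS = [(-12.0, 7.0), (np.log(1e-3), None), (np.log(1e-3), np.log(1e5))]


def fit_zinb(y: np.ndarray, starts: list[np.ndarray] | None = None):
    """Maximum-likelihood ZINB fit; returns ((pi, mu, r), loglik)."""
    y = np.asarray(y, dtype=float)
    p0 = float(np.mean(y == 0))
    mpos = float(y.mean())
    v = float(y.var(ddof=1)) if y.size > 1 else mpos
    pi0 = min(max(p0 / 2.0, 0.02), 0.9)
    mu0 = max(mpos / (1.0 - pi0), 1e-2)
    r0 = mu0**2 / max(v - mu0, mu0 / 2.0)
    r0 = min(max(r0, 1e-2), 1e4)
    cand = [np.array([special.logit(pi0), np.log(mu0), np.log(r0)])]
    if starts:
        cand.extend(starts)
    bounds = list(_ZINB_BOUNDS)
    ymax = max(y.max(), 1.0)
    bounds[1] = (np.log(1e-3), np.log(ymax * 10.0 + 10.0))
    best, best_nll = None, np.inf
    for x0 in cand:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] if b[1] is not None else np.inf for b in bounds])
        res = optimize.minimize(
            _zinb_nll, x0, args=(y,), method="L-BFGS-B", bounds=bounds
        )
        if res.fun < best_nll:
            best, best_nll = res.x, float(res.fun)
    pi = float(special.expit(best[0]))
    return (pi, float(np.exp(best[1])), float(np.exp(best[2]))), -best_nll, best


def zinb_lrt(m: CountMatrix) -> DEResult:
    """Zero-inflated NB likelihood-ratio test, df = 3.

    Per isoform, a ZINB model (zero-inflation probability, mean, size) is
    fitted by maximum likelihood to each group and to the pooled cells; the
    statistic 2 (l1 - l0) is referred to chi-square with 3 df (the literal
    free-parameter difference).
    """
    g1, g2 = _two_groups(m, min_per_group=5)
    y = np.rint(m.values)
    n = m.n_isoforms
    stat = np.zeros(n)
    pval = np.ones(n)
    effect = np.zeros(n)
    note = np.array([""] * n, dtype=object)
    for i in range(n):
        yi = y[i]
        if np.all(yi == 0):
            note[i] = "degenerate: all zero counts"
            continue
        if np.all(yi == yi[0]):
            note[i] = "degenerate: constant counts"
            continue
        try:
            (pi0, mu0, r0), ll0, theta0 = fit_zinb(yi)
            (pi1, mu1, r1), ll1a, _ = fit_zinb(yi[g1], starts=[theta0])
            (pi2, mu2, r2), ll1b, _ = fit_zinb(yi[g2], starts=[theta0])
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            stat[i] = np.nan
            pval[i] = np.nan
            effect[i] = np.nan
            note[i] = f"not fitted: {exc}"
            continue
        lrt = max(2.0 * (ll1a + ll1b - ll0), 0.0)
        stat[i] = lrt
        pval[i] = stats.chi2.sf(lrt, df=3)
        m1 = (1.0 - pi1) * mu1
        m2 = (1.0 - pi2) * mu2
        effect[i] = np.log2(m2 / m1) if m1 > 0 and m2 > 0 else np.nan
    return _result(m, "zinb", stat, effect, pval, note)


# -- 6. Hurdle (two-part logistic + Gaussian) LRT --------------------------


def hurdle_lrt(m: CountMatrix, min_positive: int = 2) -> DEResult:
    """Two-part hurdle likelihood-ratio test.

    The discrete part tests the detection rate (value > 0) between groups by a
    logistic-regression LRT (closed form for a binary covariate); the
    continuous part tests log2(CPM+1) among positive cells by a Gaussian LRT
    with a shared variance.  The combined statistic is the sum of the two
    chi-squares on 2 df; a component with no information contributes 0 with the
    df reduced.  Isoforms with fewer than ``min_positive`` positive cells
    overall are skipped (missing p).
    """
    g1, g2 = _two_groups(m, min_per_group=1)
    y = log_cpm(m)
    det = m.values > 0
    n1, n2 = int(g1.sum()), int(g2.sum())
    k1 = det[:, g1].sum(axis=1)
    k2 = det[:, g2].sum(axis=1)
    k = k1 + k2
    n = n1 + n2

    def binom_ll(kk, nn):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = kk / nn
            t1 = np.where(kk > 0, kk * np.log(p), 0.0)
            t2 = np.where(nn - kk > 0, (nn - kk) * np.log(1.0 - p), 0.0)
        return t1 + t2

    stat_d = 2.0 * (binom_ll(k1, n1) + binom_ll(k2, n2) - binom_ll(k, n))
    stat_d = np.maximum(np.nan_to_num(stat_d), 0.0)
    df_d = np.where((k > 0) & (k < n), 1, 0)
    stat_d = np.where(df_d == 1, stat_d, 0.0)

    # continuous part: Gaussian LRT on positive cells, shared variance
    w1 = det[:, g1]
    w2 = det[:, g2]
    y1, y2 = y[:, g1], y[:, g2]
    s1 = (y1 * w1).sum(axis=1)
    s2 = (y2 * w2).sum(axis=1)
    m1 = k1.astype(float)
    m2 = k2.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = s1 / m1
        mean2 = s2 / m2
        mean0 = (s1 + s2) / (m1 + m2)
    ss1 = (w1 * (y1 - np.nan_to_num(mean1)[:, None]) ** 2).sum(axis=1) + (
        w2 * (y2 - np.nan_to_num(mean2)[:, None]) ** 2
    ).sum(axis=1)
    ss0 = (w1 * (y1 - np.nan_to_num(mean0)[:, None]) ** 2).sum(axis=1) + (
        w2 * (y2 - np.nan_to_num(mean0)[:, None]) ** 2
    ).sum(axis=1)
    has_cont = (m1 >= 1) & (m2 >= 1) & (m1 + m2 >= 3)
    mtot = m1 + m2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ss0 / np.maximum(ss1, ss0 * 1e-8)
        stat_c = mtot * np.log(np.maximum(ratio, 1.0))
    stat_c = np.where(has_cont & (ss0 > 1e-12), np.nan_to_num(stat_c), 0.0)
    df_c = np.where(has_cont & (ss0 > 1e-12), 1, 0)

    stat = stat_d + stat_c
    df = df_d + df_c
    pval = np.where(df > 0, stats.chi2.sf(stat, np.maximum(df, 1)), 1.0)
    effect = np.nan_to_num(mean2) - np.nan_to_num(mean1)
    note = np.array([""] * m.n_isoforms, dtype=object)
    note[df == 0] = "degenerate: no informative component"
    skip = k < min_positive
    stat = stat.astype(float)
    pval = pval.astype(float)
    stat[skip] = np.nan
    pval[skip] = np.nan
    note[skip] = f"skipped: fewer than {min_positive} positive cells"
    res = _result(m, "hurdle", stat, effect, pval, note)
    res.stat_discrete = stat_d  # type: ignore[attr-defined]
    res.stat_continuous = stat_c  # type: ignore[attr-defined]
    res.df = df  # type: ignore[attr-defined]
    return res


# -- 7. Beta-Poisson GLM z-test --------------------------------------------


def bp4_glm_test(m: CountMatrix, n_iter: int = 25) -> DEResult:
    """Beta-Poisson GLM with a group effect on lambda1, Wald z-test.

    The model mean on the CPM scale is mu = exp(b0 + b1 * group) with variance
    function V(mu) = mu * lambda2 + mu^2 * phi2, where lambda2 is the known
    per-cell counts-to-CPM scale (1e6 / library size) and phi2 is a pooled
    method-of-moments overdispersion.  Fitting is iterative weighted least
    squares from a moment start; the Wald z on b1 uses a Pearson
    (quasi-likelihood) scale factor.
    """
    g1, g2 = _two_groups(m, min_per_group=5)
    x = compute_cpm(m)
    lam2 = 1e6 / m.library_sizes  # per-cell lattice scale of the CPM values
    n = m.n_cells
    mean_all = x.mean(axis=1)
    var_all = x.var(axis=1, ddof=1)
    phi2 = np.maximum(
        (var_all - mean_all * lam2.mean()) / np.maximum(mean_all**2, 1e-300), 1e-8
    )

    tot1 = x[:, g1].sum(axis=1)
    tot2 = x[:, g2].sum(axis=1)
    allzero = (tot1 == 0) & (tot2 == 0)
    onezero = ((tot1 == 0) | (tot2 == 0)) & ~allzero

    def irls_group(mask):
        xs = x[:, mask]
        nn = int(mask.sum())
        a = np.log(np.maximum(xs.mean(axis=1), 1e-8))
        for _ in range(n_iter):
            mu = np.exp(a)[:, None]
            w = mu / (lam2[None, mask] + phi2[:, None] * mu)
            sw = w.sum(axis=1)
            step = ((xs - mu) / np.maximum(mu, 1e-300) * w).sum(axis=1) / np.maximum(
                sw, 1e-300
            )
            step = np.clip(step, -5.0, 5.0)
            a = a + step
            if np.max(np.abs(step)) < 1e-10:
                break
        mu = np.exp(a)[:, None]
        w = mu / (lam2[None, mask] + phi2[:, None] * mu)
        return a, w.sum(axis=1), mu

    a1, sw1, mu1 = irls_group(g1)
    a2, sw2, mu2 = irls_group(g2)
    # Pearson scale over all cells
    mu_fit = np.where(g1[None, :], np.exp(a1)[:, None], np.exp(a2)[:, None])
    vfun = mu_fit * lam2[None, :] + phi2[:, None] * mu_fit**2
    pearson = ((x - mu_fit) ** 2 / np.maximum(vfun, 1e-300)).sum(axis=1)
    scale = np.maximum(pearson / max(n - 2, 1), 1e-8)

    effect_nat = a2 - a1
    se = np.sqrt(scale * (1.0 / np.maximum(sw1, 1e-300) + 1.0 / np.maximum(sw2, 1e-300)))
    with np.errstate(invalid="ignore"):
        zstat = effect_nat / se
    pval = 2.0 * stats.norm.sf(np.abs(zstat))

    stat = np.asarray(zstat, dtype=float)
    pval = np.asarray(pval, dtype=float)
    effect = effect_nat / np.log(2.0)
    note = np.array([""] * m.n_isoforms, dtype=object)
    const = np.all(x == x[:, [0]], axis=1)
    stat[const], effect[const], pval[const] = 0.0, 0.0, 1.0
    note[const] = "degenerate: constant values"
    stat[allzero], effect[allzero], pval[allzero] = 0.0, 0.0, 1.0
    note[allzero] = "degenerate: all zero"
    stat[onezero] = np.nan
    pval[onezero] = np.nan
    effect[onezero] = np.nan
    note[onezero] = "not fitted: zero total in one group"
    return _result(m, "bp4", stat, effect, pval, note)


METHODS = {
    "ttest": ttest_log_cpm,
    "wilcoxon": wilcoxon_test,
    "limmatrend": moderated_t_trend,
    "nbwald": nb_wald,
    "zinb": zinb_lrt,
    "hurdle": hurdle_lrt,
    "bp4": bp4_glm_test,
}


def run_method(name: str, m: CountMatrix) -> DEResult:
    """Run a registered test by name on a labelled matrix."""
    try:
        fn = METHODS[name]
    except KeyError:
        raise KeyError(f"unknown method {name!r}; choose from {sorted(METHODS)}")
    return fn(m)
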