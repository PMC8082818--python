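"""Null distributions and p-values for the pseudotime DE test.

For each gene the permuted subsamples yield null statistic values
{s^1, ..., s^B'}. The empirical p-value is (#{s^b >= s} + 1)/(B' + 1). For
higher resolution, a gamma distribution and a two-component gamma mixture
are fitted to the null values by maximum likelihood; a likelihood-ratio test
with 3 degrees of freedom at level 0.01 picks between them, and the
parametric p-value is the chosen distribution's right tail at the observed
statistic. In fixed-pseudotime mode an asymptotic chi-squared approximation
replaces the permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from ._nb import GAMControls, compute_statistics_batch, fit_nb_batch, fit_zinb_batch
from ._splines import build_spline_basis

__all__ = [
    "NullFit",
    "ParametricUnavailableError",
    "null_statistics",
    "empirical_pvalue",
    "fit_parametric_null",
    "parametric_pvalue",
    "asymptotic_pvalue",
    "bh_adjust",
]

_P_FLOOR = 1e-300


class ParametricUnavailableError(RuntimeError):
    """No parametric null could be fitted; report the empirical p-value only."""


@dataclass
class NullFit:
    """A gene's fitted null distribution of the test statistic."""

    null_values: np.ndarray
    gamma_params: tuple | None = None           # (alpha, rate beta)
    mixture_params: tuple | None = None         # (gamma, a1, b1, a2, b2)
    loglik_gamma: float = np.nan
    loglik_mixture: float = np.nan
    lrt_stat: float = np.nan
    lrt_p: float = np.nan
    chosen: str = "empirical_only"
    gof_p: float = np.nan
    n_zero: int = 0

    def cdf(self, s):
        if self.chosen == "gamma":
            a, b = self.gamma_params
            return stats.gamma.cdf(s, a, scale=1.0 / b)
        if self.chosen == "mixture":
            g, a1, b1, a2, b2 = self.mixture_params
            return g * stats.gamma.cdf(s, a1, scale=1.0 / b1) + (1 - g) * stats.gamma.cdf(
                s, a2, scale=1.0 / b2
            )
        raise ParametricUnavailableError("no parametric null was selected")

    def sf(self, s):
        if self.chosen == "gamma":
            a, b = self.gamma_params
            return stats.gamma.sf(s, a, scale=1.0 / b)
        if self.chosen == "mixture":
            g, a1, b1, a2, b2 = self.mixture_params
            return g * stats.gamma.sf(s, a1, scale=1.0 / b1) + (1 - g) * stats.gamma.sf(
                s, a2, scale=1.0 / b2
            )
        raise ParametricUnavailableError("no parametric null was selected")


def empirical_pvalue(s: float, nulls) -> float:
    """Permutation p-value (#{null >= s} + 1) / (B' + 1); ties count as >=."""
    nulls = np.asarray(nulls, float)
    if nulls.size == 0:
        raise ValueError("empty null sample")
    return (np.sum(nulls >= s) + 1.0) / (nulls.size + 1.0)


def _weighted_gamma_mle(x, logx, w, a_init=None, n_newton=5):
    """Weighted gamma MLE (shape, rate) via Newton on the shape equation."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    mlx = (w * logx).sum() / sw
    c = np.log(mx) - mlx
    c = max(c, 1e-10)
    if a_init is None:
        # Minka's closed-form start is within ~1% of the root; a few Newton
        # steps reach solver precision
        a = (3.0 - c + np.sqrt((c - 3.0) ** 2 + 24.0 * c)) / (12.0 * c)
    else:
        a = a_init
    for _ in range(n_newton):
        num = np.log(a) - special.psi(a) - c
        den = 1.0 / a - special.zeta(2, a)  # trigamma(a)
        a_new = a - num / den
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-12 * (a + 1.0):
            a = a_new
            break
        a = a_new
    a = float(np.clip(a, 1e-6, 1e6))
    return a, a / mx


def _gamma_logpdf(x, logx, a, b):
    # direct form avoids scipy distribution-object overhead in the EM loop
    return a * np.log(b) - special.gammaln(a) + (a - 1.0) * logx - b * x


def _gamma_mix_loglik(x, params, logx=None):
    g, a1, b1, a2, b2 = params
    if logx is None:
        logx = np.log(x)
    l1 = _gamma_logpdf(x, logx, a1, b1) + np.log(g)
    l2 = _gamma_logpdf(x, logx, a2, b2) + np.log1p(-g)
    return float(np.logaddexp(l1, l2).sum())


def _fit_gamma_mixture(x, gamma_fit, tol=1e-8, maxit=200, n_restarts=5, seed=0):
    """Two-component gamma mixture MLE by EM with multiple restarts.

    One restart starts at the degenerate single-gamma solution, so the
    best mixture log-likelihood can never fall below the gamma one.
    """
    rng = np.random.default_rng(seed)
    logx = np.log(x)
    a0, b0 = gamma_fit
    med = np.median(x)
    inits = [
        _split_init(x, x <= med),
        _split_init(x, x <= x.mean()),
        _split_init(x, x <= np.quantile(x, 0.25)),
        (0.5, a0, b0, a0 * 1.0000001, b0),
        _split_init(x, rng.random(x.size) < 0.5),
    ][: max(n_restarts, 1)]
    best = None
    best_ll = -np.inf
    for init in inits:
        params, ll = _gamma_mix_em(x, logx, init, tol, maxit)
        if ll > best_ll:
            best_ll, best = ll, params
    return best, best_ll


def _split_init(x, mask):
    lo, hi = x[mask], x[~mask]
    if lo.size < 3 or hi.size < 3:
        m, v = x.mean(), x.var() + 1e-12
        a = m * m / v
        return (0.5, a, a / m, a * 2, a * 2 / m)
    out = []
    for part in (lo, hi):
        m, v = part.mean(), part.var() + 1e-12
        a = np.clip(m * m / v, 1e-3, 1e6)
        out += [a, a / part.mean()]
    return (lo.size / x.size, out[0], out[1], out[2], out[3])


def _gamma_mix_em(x, logx, init, tol, maxit):
    g, a1, b1, a2, b2 = init
    g = float(np.clip(g, 0.01, 0.99))
    ll_old = -np.inf
    params = (g, a1, b1, a2, b2)
    for _ in range(maxit):
        l1 = _gamma_logpdf(x, logx, a1, b1) + np.log(g)
        l2 = _gamma_logpdf(x, logx, a2, b2) + np.log1p(-g)
        norm = np.logaddexp(l1, l2)
        ll = float(norm.sum())
        r1 = np.exp(l1 - norm)
        g = float(np.clip(r1.mean(), 0.01, 0.99))
        w2 = 1.0 - r1
        if r1.sum() > 1e-8:
            a1, b1 = _weighted_gamma_mle(x, logx, r1, a_init=a1, n_newton=2)
        if w2.sum() > 1e-8:
            a2, b2 = _weighted_gamma_mle(x, logx, w2, a_init=a2, n_newton=2)
        params = (g, a1, b1, a2, b2)
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            break
        ll_old = ll
    return params, _gamma_mix_loglik(x, params, logx)


def fit_parametric_null(
    nulls,
    lrt_alpha: float = 0.01,
    min_values: int = 50,
    zero_frac_limit: float = 0.1,
    compute_gof: bool = False,
    gof_n_boot: int = 199,
    seed: int = 0,
) -> NullFit:
    """Fit gamma and gamma-mixture nulls to a gene's permutation statistics.

    Exact zeros (degenerate fits) are excluded from the parametric fit but
    retained in the empirical p-value; a gene with more than `zero_frac_limit`
    zeros, or too few values, falls back to the empirical null only. The
    mixture is retained only when the 3-df LRT rejects at `lrt_alpha`.
    """
    nulls = np.asarray(nulls, float)
    nulls = nulls[np.isfinite(nulls)]
    pos = nulls[nulls > 0]
    n_zero = int(nulls.size - pos.size)
    nf = NullFit(null_values=nulls, n_zero=n_zero)
    if nulls.size == 0 or pos.size < min_values or n_zero > zero_frac_limit * nulls.size:
        return nf
    try:
        a, loc, scale = stats.gamma.fit(pos, floc=0)
        gamma_params = (float(a), float(1.0 / scale))
    except Exception:
        return nf
    nf.gamma_params = gamma_params
    nf.loglik_gamma = float(
        stats.gamma.logpdf(pos, gamma_params[0], scale=1.0 / gamma_params[1]).sum()
    )
    try:
        mix, ll_mix = _fit_gamma_mixture(pos, gamma_params, seed=seed)
        nf.mixture_params = tuple(float(v) for v in mix)
        nf.loglik_mixture = ll_mix
        nf.lrt_stat = max(2.0 * (ll_mix - nf.loglik_gamma), 0.0)
        nf.lrt_p = float(stats.chi2.sf(nf.lrt_stat, 3))
        nf.chosen = "mixture" if nf.lrt_p <= lrt_alpha else "gamma"
    except Exception:
        warnings.warn("gamma-mixture EM failed; using single gamma", stacklevel=2)
        nf.chosen = "gamma"
    if compute_gof:
        nf.gof_p = _anderson_darling_p(pos, nf, n_boot=gof_n_boot, seed=seed)
    return nf


def _anderson_darling_p(x, nf: NullFit, n_boot: int = 199, seed: int = 0):
    """Fixed-parameter Monte-Carlo Anderson-Darling p (logged diagnostic)."""

    def ad_stat(sample):
        u = np.clip(np.sort(nf.cdf(sample)), 1e-12, 1 - 1e-12)
        k = u.size
        i = np.arange(1, k + 1)
        return -k - np.mean((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1])))

    obs = ad_stat(x)
    rng = np.random.default_rng(seed)
    if nf.chosen == "gamma":
        a, b = nf.gamma_params
        draw = lambda size: rng.gamma(a, 1.0 / b, size)
    else:
        g, a1, b1, a2, b2 = nf.mixture_params
        def draw(size):
            z = rng.random(size) < g
            return np.where(z, rng.gamma(a1, 1.0 / b1, size), rng.gamma(a2, 1.0 / b2, size))
    boots = np.array([ad_stat(draw(x.size)) for _ in range(n_boot)])
    return float((np.sum(boots >= obs) + 1.0) / (n_boot + 1.0))


def parametric_pvalue(s: float, nf: NullFit) -> float:
    """Right-tail p-value 1 - F(s) under the fitted parametric null."""
    if nf.chosen == "empirical_only":
        raise ParametricUnavailableError("gene has no parametric null; use empirical p")
    return float(max(nf.sf(s), _P_FLOOR))


def asymptotic_pvalue(fit) -> float:
    """Fixed-pseudotime p-value from the chi-squared-type approximation
    to the smooth test statistic (fractional degrees of freedom)."""
    if fit.asymptotic_stat is None or not np.isfinite(fit.asymptotic_stat):
        return np.nan
    return float(stats.chi2.sf(fit.asymptotic_stat, max(fit.asymptotic_df, 1.0)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs are propagated."""
    p = np.asarray(pvals, float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def null_statistics(y, draws, flavor: str = "nb", controls: GAMControls | None = None,
                    bases: list | None = None) -> np.ndarray:
    """Null test-statistic values for one gene across permuted subsamples.

    For each usable subsample the gene's counts are restricted to the
    subsample's cells and the selected model is refitted against the permuted
    pseudotime with the identical configuration used for the observed
    statistic. Subsamples where the restricted counts are all zero (or the
    fit degenerates) are dropped.
    """
    controls = controls or GAMControls()
    y = np.asarray(y, float).ravel()
    out = []
    usable = draws.usable()
    for k, sub in enumerate(usable):
        if sub.permuted is None:
            raise ValueError("draws must be permuted first (permute_pseudotime)")
        ysub = y[sub.indices]
        if ysub.sum() == 0:
            continue
        basis = bases[k] if bases is not None else build_spline_basis(
            sub.permuted.values, controls.knots
        )
        try:
            nb = fit_nb_batch(ysub[:, None], basis, controls)
            fit = nb if flavor == "nb" else fit_zinb_batch(
                ysub[:, None], basis, controls, nb_init=nb
            ) if np.any(ysub == 0) else nb
            s, _ = compute_statistics_batch(fit, basis)
            if np.isfinite(s[0]):
                out.append(float(s[0]))
        except Exception:
            continue
    return np.asarray(out)
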