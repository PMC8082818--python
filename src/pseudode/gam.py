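"""Per-gene NB-GAM / ZINB-GAM spline regressions of expression on pseudotime.

`NBGAM` and `ZINBGAM` are scikit-learn-style estimators for a single gene
(fit(T, y) / predict(T)); the batched engine in `_nb` backs both and is what
the pipeline uses across genes. `select_model` applies the AIC rule for
choosing between the two flavors, and `compute_statistic` evaluates the DE
test statistic s = fhat' Vf^{r-} fhat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._nb import (
    BatchFit,
    GAMControls,
    compute_statistics_batch,
    fit_nb_batch,
    fit_zinb_batch,
    wood_test_batch,
)
from ._splines import SplineBasis, build_spline_basis

__all__ = [
    "GAMFit",
    "NBGAM",
    "ZINBGAM",
    "build_spline_basis",
    "fit_nb_gam",
    "fit_zinb_gam",
    "select_model",
    "compute_statistic",
]

# AIC improvement the ZINB-GAM must achieve before it replaces the NB-GAM
DEFAULT_AIC_DELTA = 10.0


@dataclass
class GAMFit:
    """One gene's fitted smooth model of expression on pseudotime."""

    flavor: str                 # 'nb' or 'zinb'
    beta0: float
    beta: np.ndarray
    phi: float
    fhat: np.ndarray
    loglik: float
    aic: float
    edf: float
    edf_smooth: float
    converged: bool
    basis: SplineBasis
    alpha0: float | None = None
    alpha1: float | None = None
    statistic: float | None = None
    rank: int | None = None
    asymptotic_stat: float | None = None
    asymptotic_df: float | None = None
    zinb_reduced_to_nb: bool = False
    _batch: BatchFit | None = None

    @property
    def Vf(self) -> np.ndarray:
        """Covariance of the fitted smooth at the observed pseudotime."""
        Xc = self.basis.design
        return Xc @ self._batch.Vb[0, 1:, 1:] @ Xc.T


def _fit_to_gamfit(batch: BatchFit, basis: SplineBasis, flavor: str) -> GAMFit:
    s, r = compute_statistics_batch(batch, basis)
    ws, wdf = wood_test_batch(batch, basis)
    return GAMFit(
        flavor=flavor,
        beta0=float(batch.beta[0, 0]),
        beta=batch.beta[0, 1:].copy(),
        phi=float(batch.phi[0]),
        fhat=(basis.design @ batch.beta[0, 1:]),
        loglik=float(batch.loglik[0]),
        aic=float(batch.aic[0]),
        edf=float(batch.edf[0]),
        edf_smooth=float(batch.edf_smooth[0]),
        converged=bool(batch.converged[0]),
        basis=basis,
        alpha0=None if batch.alpha0 is None else float(batch.alpha0[0]),
        alpha1=None if batch.alpha1 is None else float(batch.alpha1[0]),
        statistic=float(s[0]) if np.isfinite(s[0]) else None,
        rank=int(r[0]),
        asymptotic_stat=float(ws[0]) if np.isfinite(ws[0]) else None,
        asymptotic_df=float(wdf[0]) if np.isfinite(wdf[0]) else None,
        _batch=batch,
    )


def fit_nb_gam(y, T, basis: SplineBasis | None = None, controls: GAMControls | None = None) -> GAMFit:
    """Fit the NB-GAM log(mu_i) = beta0 + f(T_i) for one gene."""
    y = np.asarray(y, float).ravel()
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if y.sum() == 0:
        raise ValueError("cannot fit a gene with all-zero counts")
    controls = controls or GAMControls()
    if basis is None:
        basis = build_spline_basis(T, controls.knots)
    if len(y) != basis.design.shape[0]:
        raise ValueError("y and T must have the same length")
    batch = fit_nb_batch(y[:, None], basis, controls)
    return _fit_to_gamfit(batch, basis, "nb")


def fit_zinb_gam(y, T, basis: SplineBasis | None = None, controls: GAMControls | None = None) -> GAMFit:
    """Fit the ZINB-GAM by EM for one gene.

    If the gene has no zero count the zero-inflated model is not
    identifiable and the plain NB fit is returned, flagged.
    """
    y = np.asarray(y, float).ravel()
    if y.sum() == 0:
        raise ValueError("cannot fit a gene with all-zero counts")
    controls = controls or GAMControls()
    if basis is None:
        basis = build_spline_basis(T, controls.knots)
    if not np.any(y == 0):
        fit = fit_nb_gam(y, T, basis, controls)
        fit.zinb_reduced_to_nb = True
        return fit
    nb = fit_nb_batch(y[:, None], basis, controls)
    batch = fit_zinb_batch(y[:, None], basis, controls, nb_init=nb, track_loglik=True)
    fit = _fit_to_gamfit(batch, basis, "zinb")
    if batch.alpha_clipped is not None and batch.alpha_clipped[0]:
        warnings.warn(
            "separation in the zero-inflation logistic step; alpha clipped at bounds",
            stacklevel=2,
        )
    return fit


def select_model(
    nb: GAMFit, zinb: GAMFit | None, mode: str = "auto", delta: float = DEFAULT_AIC_DELTA
) -> GAMFit:
    """Choose between the NB and ZINB fits of one gene.

    In 'auto' mode the ZINB-GAM is selected only when it improves AIC by at
    least `delta` (default 10); an unconverged ZINB fit always falls back to
    the NB fit.
    """
    if mode not in ("auto", "nb", "zinb"):
        raise ValueError("mode must be 'auto', 'nb' or 'zinb'")
    if mode == "nb" or zinb is None:
        return nb
    if mode == "zinb":
        if not zinb.converged:
            warnings.warn("unconverged ZINB-GAM: falling back to NB-GAM", stacklevel=2)
            return nb
        return zinb
    if not zinb.converged:
        warnings.warn("unconverged ZINB-GAM: falling back to NB-GAM", stacklevel=2)
        return nb
    return zinb if (nb.aic - zinb.aic) >= delta else nb


def compute_statistic(fit: GAMFit) -> float:
    """DE test statistic s = fhat' Vf^{r-} fhat (rank-truncated pseudoinverse)."""
    if fit.statistic is None:
        raise ValueError("test statistic undefined: covariance numerically zero")
    return fit.statistic


class NBGAM(BaseEstimator, RegressorMixin):
    """Negative-binomial generalized additive regression of counts on pseudotime.

    Parameters
    ----------
    knots : number of spline knots placed at pseudotime quantiles.
    controls : optional GAMControls overriding the fitting configuration.

    Attributes (after fit)
    ----------------------
    beta0_, coef_, phi_ : intercept, spline coefficients, NB size.
    fhat_ : fitted centered smooth at the training pseudotime.
    statistic_, rank_ : DE test statistic and pseudoinverse rank.
    edf_, aic_, loglik_ : fit summaries.
    """

    _flavor = "nb"

    def __init__(self, knots: int = 6, controls: GAMControls | None = None):
        self.knots = knots
        self.controls = controls

    def _controls(self) -> GAMControls:
        if self.controls is not None:
            return self.controls
        return GAMControls(knots=self.knots)

    def fit(self, X, y):
        T = np.asarray(X, float).ravel()
        ctl = self._controls()
        basis = build_spline_basis(T, self.knots)
        fitter = fit_nb_gam if self._flavor == "nb" else fit_zinb_gam
        res = fitter(y, T, basis=basis, controls=ctl)
        self.basis_ = basis
        self.result_ = res
        self.beta0_ = res.beta0
        self.coef_ = res.beta
        self.phi_ = res.phi
        self.fhat_ = res.fhat
        self.statistic_ = res.statistic
        self.rank_ = res.rank
        self.edf_ = res.edf
        self.aic_ = res.aic
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        if res.flavor == "zinb":
            self.alpha0_ = res.alpha0
            self.alpha1_ = res.alpha1
        return self

    def predict(self, X):
        """Predicted NB mean mu at new pseudotime values."""
        check_is_fitted(self, "result_")
        T = np.asarray(X, float).ravel()
        return np.exp(self.beta0_ + self.basis_.evaluate(T) @ self.coef_)


class ZINBGAM(NBGAM):
    """Zero-inflated NB-GAM fitted by EM (dropout logit linear in log mean)."""

    _flavor = "zinb"
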