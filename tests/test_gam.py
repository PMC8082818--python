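import numpy as np
import pytest
from scipy.stats import kstest
from sklearn.base import clone

from pseudode import (
    NBGAM,
    ZINBGAM,
    build_spline_basis,
    compute_statistic,
    fit_nb_gam,
    fit_zinb_gam,
    select_model,
    simulate_lineage,
    simulate_zero_inflation,
)
from pseudode._nb import pseudoinverse_quadform


def _nb_counts(rng, logmu, phi):
    mu = np.exp(logmu)
    return rng.negative_binomial(phi, phi / (phi + mu)).astype(float)


class TestNBGAM:
    def test_linear_trend_consistency(self):
        """With log mu = 1 + 2T and large n the centered smooth estimate
        approaches 2T - 2*mean(T)."""
        n = 1000
        T = np.linspace(0, 1, n)
        rng = np.random.default_rng(7)
        y = _nb_counts(rng, 1 + 2 * T, 5.0)
        fit = fit_nb_gam(y, T)
        target = 2 * T - 2 * T.mean()
        assert np.abs(fit.fhat - target).max() < 0.15

    def test_equidispersed_data_pushes_phi_large(self):
        """Poisson-generated counts drive the estimated NB size upward
        (vanishing overdispersion)."""
        rng = np.random.default_rng(8)
        T = np.linspace(0, 1, 500)
        y = rng.poisson(np.exp(2.0 + T)).astype(float)
        fit = fit_nb_gam(y, T)
        assert fit.phi > 100.0

    def test_statistic_invariant_under_time_reversal(self):
        rng = np.random.default_rng(5)
        n = 300
        T = rng.uniform(0, 1, n)
        T = (T - T.min()) / (T.max() - T.min())
        y = _nb_counts(rng, 1 + 1.5 * np.sin(2 * np.pi * T), 2.0)
        s1 = fit_nb_gam(y, T).statistic
        s2 = fit_nb_gam(y, 1.0 - T).statistic
        assert abs(s1 - s2) <= 1e-6 * max(abs(s1), 1.0)

    def test_all_zero_gene_rejected(self):
        with pytest.raises(ValueError):
            fit_nb_gam(np.zeros(50, dtype=int), np.linspace(0, 1, 50))

    def test_fhat_centered(self):
        rng = np.random.default_rng(2)
        T = np.linspace(0, 1, 200)
        y = _nb_counts(rng, 1.5 + np.sin(2 * np.pi * T), 3.0)
        fit = fit_nb_gam(y, T)
        assert abs(fit.fhat.mean()) < 1e-8 * (np.abs(fit.fhat).max() + 1)

    def test_estimator_api(self):
        """NBGAM follows the sklearn contract: params, clone, fit, predict."""
        rng = np.random.default_rng(3)
        T = np.linspace(0, 1, 150)
        y = _nb_counts(rng, 2.0 + T, 4.0)
        est = NBGAM(knots=6)
        assert clone(est).get_params()["knots"] == 6
        est.fit(T, y)
        mu_hat = est.predict(T)
        assert mu_hat.shape == (150,)
        # fitted means track the truth within a modest relative error
        assert np.abs(np.log(mu_hat) - (2.0 + T)).mean() < 0.25
        assert est.statistic_ > 0


class TestStatistic:
    def test_zero_smooth_gives_zero(self):
        s, r = pseudoinverse_quadform(np.zeros(4), np.eye(4))
        assert s == 0.0

    def test_identity_covariance(self):
        s, r = pseudoinverse_quadform(np.array([3.0, 4.0]), np.eye(2))
        assert s == pytest.approx(25.0)
        assert r == 2

    def test_matches_eigendecomposition_oracle(self):
        """Rank-deficient PSD covariance with f in its column space: the
        statistic equals the brute-force eigendecomposition pseudoinverse."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            A = rng.normal(size=(6, 3))
            V = A @ A.T
            f = V @ rng.normal(size=6)
            s, r = pseudoinverse_quadform(f, V)
            ev, U = np.linalg.eigh(V)
            keep = ev > np.sqrt(np.finfo(float).eps) * ev.max()
            brute = float(f @ (U[:, keep] @ np.diag(1 / ev[keep]) @ U[:, keep].T) @ f)
            assert abs(s - brute) < 1e-8 * max(brute, 1.0)
            assert r == 3

    def test_degenerate_covariance_raises(self):
        with pytest.raises(ValueError):
            pseudoinverse_quadform(np.ones(3), np.zeros((3, 3)))

    def test_compute_statistic_exposes_fit_value(self):
        rng = np.random.default_rng(1)
        T = np.linspace(0, 1, 120)
        y = _nb_counts(rng, 1.0 + T, 3.0)
        fit = fit_nb_gam(y, T)
        assert compute_statistic(fit) == fit.statistic

    def test_vf_matches_reduced_form(self):
        """The full n x n smooth covariance reproduces the statistic computed
        in coefficient space."""
        rng = np.random.default_rng(4)
        T = np.linspace(0, 1, 80)
        y = _nb_counts(rng, 1.0 + np.sin(np.pi * T), 3.0)
        fit = fit_nb_gam(y, T)
        s_full, r_full = pseudoinverse_quadform(fit.fhat, fit.Vf, edf=fit.edf_smooth)
        assert s_full == pytest.approx(fit.statistic, rel=1e-6)


class TestZINBGAM:
    def test_no_excess_zeros_keep_prob_near_one(self):
        """When dropout is effectively off, the ZINB fit matches the NB fit."""
        ds = simulate_lineage(400, 2, 1.0, "medium", "single", seed=21)
        zi = simulate_zero_inflation(ds, alpha0=20.0, alpha1=0.0, seed=1)
        y = zi.counts[:, 0]
        if not (y == 0).any():  # ensure at least one sampling zero
            y[0] = 0
        nb = fit_nb_gam(y, ds.true_time)
        z = fit_zinb_gam(y, ds.true_time)
        assert z._batch.keep_prob.min() > 0.9
        assert abs(z.loglik - nb.loglik) < 1e-2 * (abs(nb.loglik) + 1)

    def test_no_zero_gene_reduces_to_nb(self):
        rng = np.random.default_rng(0)
        T = np.linspace(0, 1, 100)
        y = rng.poisson(50.0, 100) + 1.0
        fit = fit_zinb_gam(y, T)
        assert fit.zinb_reduced_to_nb and fit.flavor == "nb"

    def test_em_loglik_monotone(self):
        """The tracked penalized observed-data log-likelihood never decreases."""
        ds = simulate_lineage(300, 2, 1.0, "high", "single", seed=22)
        zi = simulate_zero_inflation(ds, alpha0=0.5, alpha1=0.5, seed=2)
        y = zi.counts[:, 0]
        fit = fit_zinb_gam(y, ds.true_time)
        path = np.array([v[0] for v in fit._batch.loglik_path])
        assert len(path) >= 2
        assert (np.diff(path) >= -1e-6 * (np.abs(path[:-1]) + 1)).all()

    def test_zinb_estimator(self):
        ds = simulate_lineage(300, 2, 1.0, "medium", "single", seed=23)
        zi = simulate_zero_inflation(ds, alpha0=1.0, alpha1=0.0, seed=3)
        est = ZINBGAM().fit(ds.true_time, zi.counts[:, 0])
        assert hasattr(est, "alpha0_")


class TestSelectModel:
    def _dummy(self, aic, flavor="nb", converged=True):
        import dataclasses

        from pseudode.gam import GAMFit

        return GAMFit(
            flavor=flavor, beta0=0.0, beta=np.zeros(3), phi=1.0,
            fhat=np.zeros(5), loglik=0.0, aic=aic, edf=2.0, edf_smooth=1.0,
            converged=converged, basis=None,
        )

    def test_aic_margin_rule(self):
        nb = self._dummy(100.0)
        assert select_model(nb, self._dummy(95.0, "zinb")) is nb          # 5 < 10
        zinb = self._dummy(89.0, "zinb")
        assert select_model(nb, zinb) is zinb                             # 11 >= 10
        assert select_model(nb, self._dummy(90.0, "zinb")) is not nb      # exactly 10

    def test_forced_modes(self):
        nb, zinb = self._dummy(100.0), self._dummy(1.0, "zinb")
        assert select_model(nb, zinb, mode="nb") is nb
        assert select_model(nb, zinb, mode="zinb") is zinb

    def test_unconverged_zinb_falls_back(self):
        nb = self._dummy(100.0)
        bad = self._dummy(1.0, "zinb", converged=False)
        with pytest.warns(UserWarning, match="unconverged"):
            assert select_model(nb, bad) is nb
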