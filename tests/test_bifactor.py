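"""Bifactor measurement model: estimation, scoring, degenerate cases."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from twinfactor import (
    BifactorSpec,
    default_generative_config,
    default_odd_spec,
    factor_scores,
    fit_bifactor,
    simulate_symptom_ratings,
)
from twinfactor.bifactor import BifactorFit, _objective
from twinfactor.fitstats import FitStats


def _continuous_items(seed: int, n_pairs: int = 12500, specific_scale: float | None = None):
    cfg = default_generative_config(seed=seed)
    cfg.n_mz = cfg.n_dz = n_pairs
    cfg.discretize = False
    if specific_scale is not None:
        cfg.loadings = cfg.loadings.copy()
        cfg.loadings[:, 1:] *= specific_scale
        cfg.residual_variances = None
        cfg.__post_init__()
    study = simulate_symptom_ratings(cfg)
    return cfg, study.children_frame()[list(cfg.spec.items)]


class TestSpec:
    def test_default_pattern(self):
        spec = default_odd_spec()
        pat = spec.pattern_array
        assert pat[:, 0].all()
        assert pat[:, 1:].sum(axis=1).tolist() == [1] * 8
        assert spec.n_loadings == 16

    def test_item_without_general_loading_rejected(self):
        with pytest.raises(ValueError):
            BifactorSpec(items=("a", "b"), pattern=((True, True, False), (False, True, False)))

    def test_item_on_two_specifics_rejected(self):
        with pytest.raises(ValueError):
            BifactorSpec(items=("a",), pattern=((True, True, True),))


class TestFit:
    def test_known_loadings_recovered(self):
        cfg, items = _continuous_items(seed=31)
        fit = fit_bifactor(items)
        err = np.abs(fit.loadings - cfg.loadings)
        # twin-correlated children roughly halve the effective sample size,
        # so loading SEs are ~.015 at 50k children; allow a generous multiple
        assert err.max() < 0.06
        assert err.mean() < 0.02
        assert np.abs(fit.theta - cfg.residual_variances).max() < 0.06
        assert fit.fitstats.df == 12

    def test_zero_specific_loadings_leave_no_shared_specific_variance(self):
        # with no specific variance a lone specific loading merely trades
        # against the item residual (lambda^2 + theta is what is identified),
        # so the meaningful check is that the specific factors contribute no
        # *shared* covariance and the general column stays accurate
        cfg, items = _continuous_items(seed=32, specific_scale=1e-12)
        fit = fit_bifactor(items)
        spec_cov = fit.loadings[:, 1:] @ fit.loadings[:, 1:].T
        off = spec_cov[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.03
        assert np.abs(fit.loadings[:, 0] - cfg.loadings[:, 0]).max() < 0.05

    def test_exact_model_covariance_gives_zero_chi2(self):
        # color whitened noise so the sample covariance equals the implied one
        cfg, _ = _continuous_items(seed=33, n_pairs=300)
        Sigma = cfg.loadings @ cfg.loadings.T + np.diag(cfg.residual_variances)
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((500, 8))
        Z -= Z.mean(axis=0)
        Sz = np.cov(Z, rowvar=False, bias=True)
        W = np.linalg.inv(np.linalg.cholesky(Sz))
        X = Z @ W.T @ np.linalg.cholesky(Sigma).T
        assert np.allclose(np.cov(X, rowvar=False, bias=True), Sigma, atol=1e-10)
        fit = fit_bifactor(X)
        assert fit.fitstats.chi2 == pytest.approx(0.0, abs=1e-3)

    def test_derivative_free_optimizer_cannot_improve(self):
        # Nelder-Mead started from a jittered copy of the ML solution returns
        # to (numerically) the same optimum
        cfg, items = _continuous_items(seed=34, n_pairs=500)
        fit = fit_bifactor(items)
        S = np.cov(items.to_numpy(), rowvar=False, bias=True)
        pattern = fit.spec.pattern_array
        x_hat = np.concatenate([fit.loadings[pattern], fit.theta])
        rng = np.random.default_rng(1)
        x0 = x_hat * np.exp(rng.normal(0, 0.02, x_hat.shape))
        res = optimize.minimize(_objective, x0, args=(pattern, S), method="Nelder-Mead",
                                options={"maxiter": 60000, "xatol": 1e-10, "fatol": 1e-12})
        assert res.fun >= _objective(x_hat, pattern, S) - 1e-6

    def test_sample_smaller_than_parameters_rejected(self):
        with pytest.raises(ValueError):
            fit_bifactor(np.random.default_rng(0).standard_normal((20, 8)))


class TestFactorScores:
    def test_scores_zero_at_item_means(self):
        _, items = _continuous_items(seed=35, n_pairs=400)
        fit = fit_bifactor(items)
        scores = factor_scores(fit, pd.DataFrame([fit.mu], columns=list(fit.spec.items)))
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_score_variance_shrinks_below_one(self):
        _, items = _continuous_items(seed=36, n_pairs=2000)
        fit = fit_bifactor(items)
        scores = factor_scores(fit, items)
        assert (scores.var(ddof=0) <= 1.0 + 1e-6).all()

    def test_two_item_scores_match_hand_linear_algebra(self):
        spec = BifactorSpec(items=("x1", "x2"),
                            pattern=((True, True, False), (True, False, True)))
        lam = np.array([[0.8, 0.3, 0.0], [0.6, 0.0, 0.4]])
        theta = np.array([0.27, 0.48])
        mu = np.array([1.0, 2.0])
        Sigma = lam @ lam.T + np.diag(theta)
        fit = BifactorFit(spec=spec, loadings=lam, theta=theta, mu=mu, minus2ll=0.0,
                          fitstats=FitStats(0, 0, 0, None, 0, 1, 0, 0, None, None, None, None),
                          converged=True)
        x = np.array([[1.5, 2.5]])
        expected = lam.T @ np.linalg.inv(Sigma) @ (x[0] - mu)
        got = factor_scores(fit, x).to_numpy()[0]
        assert np.allclose(got, expected, atol=1e-12)

    def test_single_item_unit_loading_limit(self):
        # lambda = 1, residual -> 0: the score approaches the centered item
        spec = BifactorSpec(items=("x1", "x2"),
                            pattern=((True, True, False), (True, False, True)))
        lam = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1e-8]])
        theta = np.array([1e-10, 1.0])
        fit = BifactorFit(spec=spec, loadings=lam, theta=theta, mu=np.zeros(2), minus2ll=0.0,
                          fitstats=FitStats(0, 0, 0, None, 0, 1, 0, 0, None, None, None, None),
                          converged=True)
        got = factor_scores(fit, np.array([[0.7, 0.0]])).to_numpy()[0, 0]
        assert got == pytest.approx(0.7, abs=1e-6)

    def test_not_converged_fit_rejected(self):
        _, items = _continuous_items(seed=37, n_pairs=300)
        fit = fit_bifactor(items)
        fit.converged = False
        with pytest.raises(ValueError):
            factor_scores(fit, items)
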