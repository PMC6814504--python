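"""Orthogonal bifactor measurement model for the eight ODD symptoms.

One general factor loads on all eight parent-rated symptoms; a specific
irritability factor loads on temper, touchy and angry; a specific defiant
factor loads on argues, defies, annoys, blames and spiteful.  All three
factors are mutually orthogonal with unit variance (the identification
constraint), so the model-implied covariance is

    Sigma = Lambda Lambda' + Theta,

with Lambda the 8x3 patterned loading matrix and Theta diagonal residual
variances.  Items are treated as continuous and fitted by normal-theory ML
on the sample means and covariance; means are saturated, so they do not
influence the loadings.

Factor scores use the regression method, F = Lambda' Sigma^-1 (x - mu),
whose variance per factor is at most 1 (shrinkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .fitstats import (
    FitStats,
    LikelihoodRecord,
    compute_fit_stats,
    group_discrepancy,
    saturated_minus2ll,
    standardized_residual_rms,
)

__all__ = ["BifactorSpec", "BifactorFit", "default_odd_spec", "fit_bifactor", "factor_scores"]

#: DSM-IV ODD symptoms in conventional order
ODD_ITEMS = ["temper", "argues", "defies", "annoys", "blames", "touchy", "angry", "spiteful"]
IRRITABILITY_ITEMS = ["temper", "touchy", "angry"]
DEFIANT_ITEMS = ["argues", "defies", "annoys", "blames", "spiteful"]
FACTOR_NAMES = ["general", "irritability", "defiant"]


@dataclass(frozen=True)
class BifactorSpec:
    """Loading pattern of the bifactor model: which items load on which factor."""

    items: tuple[str, ...]
    pattern: tuple[tuple[bool, bool, bool], ...]  # rows: items; cols: general, irr, def

    def __post_init__(self) -> None:
        if len(self.items) != len(self.pattern):
            raise ValueError("pattern must have one row per item")
        for item, row in zip(self.items, self.pattern):
            if not row[0]:
                raise ValueError(f"every item must load on the general factor ({item} does not)")
            if sum(row[1:]) != 1:
                raise ValueError(f"each item must load on exactly one specific factor ({item})")

    @property
    def pattern_array(self) -> np.ndarray:
        return np.array(self.pattern, dtype=bool)

    @property
    def n_loadings(self) -> int:
        return int(self.pattern_array.sum())


def default_odd_spec() -> BifactorSpec:
    """The 8-symptom ODD layout: general on all items, irritability on
    temper/touchy/angry, defiant on the remaining five."""
    pattern = tuple(
        (True, item in IRRITABILITY_ITEMS, item in DEFIANT_ITEMS) for item in ODD_ITEMS
    )
    return BifactorSpec(items=tuple(ODD_ITEMS), pattern=pattern)


@dataclass
class BifactorFit:
    """Estimated bifactor model: loadings, residuals, means and fit record."""

    spec: BifactorSpec
    loadings: np.ndarray        # 8x3, zeros where the pattern forbids a loading
    theta: np.ndarray           # 8 residual variances
    mu: np.ndarray              # 8 item means (saturated)
    minus2ll: float
    fitstats: FitStats
    converged: bool

    @property
    def implied_covariance(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.theta)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=list(self.spec.items), columns=FACTOR_NAMES)


def _build(theta_vec: np.ndarray, pattern: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = pattern.shape[0]
    nl = int(pattern.sum())
    lam = np.zeros((p, 3))
    lam[pattern] = theta_vec[:nl]
    resid = theta_vec[nl:]
    return lam, resid


def _objective(theta_vec, pattern, S):
    lam, resid = _build(theta_vec, pattern)
    Sigma = lam @ lam.T + np.diag(resid)
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return 1e12
    try:
        Si = np.linalg.inv(Sigma)
    except np.linalg.LinAlgError:
        return 1e12
    _, logdetS = np.linalg.slogdet(S)
    val = logdet + float(np.trace(S @ Si)) - logdetS - p
    return val if np.isfinite(val) else 1e12


def fit_bifactor(
    symptoms: pd.DataFrame | np.ndarray,
    spec: BifactorSpec | None = None,
    *,
    n_starts: int = 5,
    seed: int = 0,
) -> BifactorFit:
    """Normal-theory ML fit of the orthogonal bifactor model.

    ``symptoms`` is an n x 8 table (children in rows; both twins of a pair
    may be stacked — the pair structure is handled downstream at the
    biometric stage).  Multi-start optimization with sign fixing: the first
    loading of each factor is constrained positive by flipping columns.

    Raises RuntimeError if no start converges.
    """
    spec = spec or default_odd_spec()
    if isinstance(symptoms, pd.DataFrame):
        X = symptoms[list(spec.items)].to_numpy(dtype=float)
    else:
        X = np.asarray(symptoms, dtype=float)
    n, p = X.shape
    if p != len(spec.items):
        raise ValueError(f"expected {len(spec.items)} items, got {p}")
    pattern = spec.pattern_array
    n_free = spec.n_loadings + p
    if n <= n_free:
        raise ValueError("sample size must exceed the free-parameter count")

    S = np.cov(X, rowvar=False, bias=True)
    mu = X.mean(axis=0)
    sd = np.sqrt(np.diag(S))

    rng = np.random.default_rng(seed)
    base = np.concatenate([
        np.full(spec.n_loadings, 0.5) * np.repeat(sd.mean(), spec.n_loadings),
        0.5 * np.diag(S),
    ])
    best = None
    for k in range(n_starts):
        x0 = base.copy()
        if k > 0:
            x0[: spec.n_loadings] *= np.exp(rng.normal(0, 0.3, spec.n_loadings))
            x0[spec.n_loadings:] *= np.exp(rng.normal(0, 0.3, p))
        bounds = [(None, None)] * spec.n_loadings + [(1e-6, None)] * p
        res = optimize.minimize(
            _objective, x0, args=(pattern, S), method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 5000},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("bifactor estimation failed to converge from any start")

    lam, resid = _build(best.x, pattern)
    # sign fix: first loading of each factor positive
    for j in range(3):
        nz = np.nonzero(pattern[:, j])[0]
        if len(nz) and lam[nz[0], j] < 0:
            lam[:, j] *= -1.0

    sat = LikelihoodRecord(saturated_minus2ll([(S, n)]), n_params=p * (p + 1) // 2 + p)
    m2ll = n * best.fun + sat.minus2ll
    n_params = n_free + p  # loadings + residuals + saturated means
    # independence baseline: free variances and means, zero covariances
    _, logdetS = np.linalg.slogdet(S)
    base_m2ll = n * (np.log(np.diag(S)).sum() - logdetS) + sat.minus2ll
    baseline = LikelihoodRecord(base_m2ll, n_params=2 * p)
    Sigma = lam @ lam.T + np.diag(resid)
    rmsr = standardized_residual_rms([(S, Sigma, None, None)])
    fstats = compute_fit_stats(LikelihoodRecord(m2ll, n_params), sat, baseline, [n], rmsr=rmsr)
    return BifactorFit(
        spec=spec, loadings=lam, theta=resid, mu=mu,
        minus2ll=float(m2ll), fitstats=fstats, converged=True,
    )


def factor_scores(fit: BifactorFit, symptoms: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Regression-method factor scores, F = Lambda' Sigma^-1 (x - mu).

    With the factor covariance fixed to the identity, the score covariance is
    Lambda' Sigma^-1 Lambda, whose diagonal is at most 1 (shrinkage toward 0).
    """
    if not fit.converged:
        raise ValueError("cannot score from a non-converged fit")
    if isinstance(symptoms, pd.DataFrame):
        X = symptoms[list(fit.spec.items)].to_numpy(dtype=float)
    else:
        X = np.asarray(symptoms, dtype=float)
    Sigma = fit.implied_covariance
    cond = np.linalg.cond(Sigma)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"model-implied covariance is singular (condition number {cond:.2e}); "
            "factor scores are undefined"
        )
    W = np.linalg.solve(Sigma, fit.loadings)  # Sigma^-1 Lambda
    F = (X - fit.mu) @ W
    return pd.DataFrame(F, columns=FACTOR_NAMES)
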