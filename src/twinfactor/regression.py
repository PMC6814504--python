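"""Phenotypic external validation: regression of each symptom dimension on
the three ODD factor scores.

Every outcome is regressed simultaneously on the general, irritability and
defiant factor scores plus a caller-specified covariate set (sex, age and
polynomial/interaction terms).  All variables are standardized before
fitting, so the coefficients are standardized betas; the variance explained
by the ODD factors is reported as the R-squared increment over the
covariate-only model (identical to the plain R-squared when there are no
covariates, and to the sum of squared betas when the factors are
orthogonal).

A sex-invariance comparison contrasts a model in which the three ODD
coefficients are equated for boys and girls with one in which they vary by
sex, via a likelihood-ratio test (df = 3) and both models' BICs.

Point estimates come from pooled OLS; because twins are not independent
observations, a cluster-robust covariance (pairs as clusters) is available
for the standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["RegressionResult", "SexInvarianceResult", "fit_external_regression", "test_sex_invariance"]

FACTORS = ["general", "irritability", "defiant"]
MAX_CONDITION = 1e8


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _design(scores: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    X = pd.DataFrame({f: _standardize(scores[f].to_numpy(dtype=float)) for f in FACTORS})
    if covariates is not None and len(covariates.columns):
        for c in covariates.columns:
            X[c] = _standardize(covariates[c].to_numpy(dtype=float))
    return X


@dataclass
class RegressionResult:
    """Standardized coefficients and variance explained for one outcome."""

    beta: pd.Series                  # the three ODD coefficients
    beta_ci: pd.DataFrame            # 95% CIs, rows = factors
    covariate_beta: pd.Series
    r2_odd: float                    # increment over the covariate-only model
    r2_full: float
    r2_covariates: float
    nobs: int
    condition_number: float


def fit_external_regression(
    scores: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    cluster: np.ndarray | None = None,
) -> RegressionResult:
    """OLS of one standardized outcome on the three ODD factors + covariates.

    ``cluster`` (pair identifiers) switches the coefficient covariance to a
    cluster-robust estimator; the point estimates are unchanged.
    Raises on near-collinear designs (condition number above 1e8).
    """
    y = _standardize(np.asarray(outcome, dtype=float))
    X = _design(scores, covariates)
    cond = np.linalg.cond(X.to_numpy())
    if cond > MAX_CONDITION:
        raise ValueError(
            f"design matrix is near-collinear (condition number {cond:.3g}); "
            "center/rescale covariates before squaring or drop redundant terms"
        )
    Xc = sm.add_constant(X)
    if cluster is not None:
        model = sm.OLS(y, Xc).fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster)})
    else:
        model = sm.OLS(y, Xc).fit()
    ci = model.conf_int(alpha=0.05)
    ci.columns = ["lo", "hi"]

    if covariates is not None and len(covariates.columns):
        cov_cols = list(covariates.columns)
        X0 = sm.add_constant(X[cov_cols])
        r2_cov = float(sm.OLS(y, X0).fit().rsquared)
    else:
        cov_cols = []
        r2_cov = 0.0
    r2_full = float(model.rsquared)

    return RegressionResult(
        beta=model.params[FACTORS],
        beta_ci=ci.loc[FACTORS],
        covariate_beta=model.params[cov_cols],
        r2_odd=r2_full - r2_cov,
        r2_full=r2_full,
        r2_covariates=r2_cov,
        nobs=int(model.nobs),
        condition_number=float(cond),
    )


def _ols_minus2ll(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """-2 lnL of a Gaussian regression at its MLE, and the parameter count."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n
    m2ll = n * (np.log(2 * np.pi * sigma2) + 1.0)
    return m2ll, X.shape[1] + 1  # + residual variance


@dataclass
class SexInvarianceResult:
    """Equated vs by-sex comparison of the three ODD coefficients."""

    chi2: float
    df: int
    pvalue: float
    bic_equated: float
    bic_by_sex: float
    rmsea: float
    beta_equated: pd.Series
    beta_by_sex: pd.DataFrame  # rows: the two sex groups
    preferred: str             # 'equated' or 'by_sex', by BIC


def test_sex_invariance(
    scores: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    sex: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> SexInvarianceResult:
    """Likelihood-ratio test of equal ODD coefficients across the sexes.

    The equated model shares the three ODD coefficients between groups; the
    by-sex model adds sex-specific deviations (df = 3).  Covariate
    coefficients are shared in both models.  Both BICs are returned so that
    the caller sees disagreements between criteria rather than a silent
    verdict.
    """
    sex = np.asarray(sex, dtype=float)
    groups = np.unique(sex)
    if len(groups) != 2:
        raise ValueError("sex must be binary")
    y = _standardize(np.asarray(outcome, dtype=float))
    X = _design(scores, covariates)
    n = len(y)
    k_by = X.shape[1] + 3 + 2  # + interactions + intercept + sigma
    for g in groups:
        if (sex == g).sum() <= k_by:
            raise ValueError("a sex group is smaller than the by-sex parameter count")

    ind = (sex == groups[1]).astype(float)
    Xeq = np.column_stack([np.ones(n), X.to_numpy()])
    inter = X[FACTORS].to_numpy() * ind[:, None]
    Xby = np.column_stack([Xeq, inter])

    m2ll_eq, k_eq = _ols_minus2ll(y, Xeq)
    m2ll_by, k_by = _ols_minus2ll(y, Xby)
    chi2 = max(m2ll_eq - m2ll_by, 0.0)
    df = 3
    pvalue = float(stats.chi2.sf(chi2, df))
    bic_eq = m2ll_eq + k_eq * np.log(n)
    bic_by = m2ll_by + k_by * np.log(n)
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n)))

    beta_eq, *_ = np.linalg.lstsq(Xeq, y, rcond=None)
    beta_by, *_ = np.linalg.lstsq(Xby, y, rcond=None)
    names = ["const"] + list(X.columns)
    eq = pd.Series(beta_eq, index=names)[FACTORS]
    base = pd.Series(beta_by[: len(names)], index=names)[FACTORS]
    delta = pd.Series(beta_by[len(names):], index=FACTORS)
    by = pd.DataFrame([base, base + delta], index=[f"sex={groups[0]:g}", f"sex={groups[1]:g}"])

    return SexInvarianceResult(
        chi2=float(chi2), df=df, pvalue=pvalue,
        bic_equated=float(bic_eq), bic_by_sex=float(bic_by), rmsea=rmsea,
        beta_equated=eq, beta_by_sex=by,
        preferred="equated" if bic_eq <= bic_by else "by_sex",
    )
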