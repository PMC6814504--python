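"""Normal-theory fit statistics shared by every modelling stage.

All covariance-structure models in this package are compared against a
saturated model (free means and covariances per group) via the maximum
likelihood discrepancy, yielding a chi-square statistic, and against an
independence baseline for the Tucker-Lewis index.  Information criteria
use the absolute -2 log-likelihood so that values are comparable across
non-nested models fitted to the same data.

Conventions (fixed, so that statistics are reproducible):

* sample covariances use the biased (1/N) divisor and each group's
  discrepancy is multiplied by N_g, not N_g - 1;
* BIC and RMSEA use the total number of sampling units summed over
  groups (pairs, for twin models; children, for pooled models);
* RMSEA = sqrt(max(chi2 - df, 0) / (df * N)), with a confidence interval
  obtained by inverting the noncentral chi-square distribution;
* RMSR is the root mean square of standardized residual moments
  (covariances and, where modelled, means).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LikelihoodRecord",
    "FitStats",
    "compute_fit_stats",
    "model_selection",
    "SelectionReport",
    "group_discrepancy",
    "saturated_minus2ll",
    "standardized_residual_rms",
]


@dataclass(frozen=True)
class LikelihoodRecord:
    """Minimal summary of a fitted model: -2 lnL and its free-parameter count."""

    minus2ll: float
    n_params: int


@dataclass
class FitStats:
    """The full fit-index battery for one fitted covariance-structure model."""

    minus2ll: float
    chi2: float
    df: int
    pvalue: float | None
    n_params: int
    n_total: int
    aic: float
    bic: float
    rmsea: float | None
    rmsea_ci: tuple[float, float] | None
    tli: float | None
    rmsr: float | None

    def to_dict(self) -> dict:
        d = {
            "minus2ll": self.minus2ll,
            "chi2": self.chi2,
            "df": self.df,
            "p": self.pvalue,
            "n_params": self.n_params,
            "n": self.n_total,
            "aic": self.aic,
            "bic": self.bic,
            "rmsea": self.rmsea,
            "rmsea_lo": None if self.rmsea_ci is None else self.rmsea_ci[0],
            "rmsea_hi": None if self.rmsea_ci is None else self.rmsea_ci[1],
            "tli": self.tli,
            "rmsr": self.rmsr,
        }
        return d


def group_discrepancy(
    S: np.ndarray,
    mbar: np.ndarray,
    Sigma: np.ndarray,
    mu: np.ndarray,
    n: int,
) -> float:
    """N-weighted ML discrepancy of one group.

    F_g = N_g * [ln|Sigma| + tr(S Sigma^-1) + (mbar-mu)' Sigma^-1 (mbar-mu)
                 - ln|S| - p]

    Returns +inf for a non-positive-definite model covariance so that
    optimizers simply step away from inadmissible regions.
    """
    S = np.atleast_2d(S)
    Sigma = np.atleast_2d(Sigma)
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0 or not np.isfinite(logdet):
        return np.inf
    try:
        Si = np.linalg.inv(Sigma)
    except np.linalg.LinAlgError:
        return np.inf
    diff = np.asarray(mbar, dtype=float) - np.asarray(mu, dtype=float)
    signS, logdetS = np.linalg.slogdet(S)
    val = logdet + float(np.trace(S @ Si)) + float(diff @ Si @ diff) - logdetS - p
    return n * val


def saturated_minus2ll(groups: Iterable[tuple[np.ndarray, int]]) -> float:
    """-2 lnL of the saturated model: Sigma_g = S_g, mu_g = mbar_g.

    ``groups`` yields (S_g, n_g) pairs with S_g the biased covariance.
    """
    total = 0.0
    for S, n in groups:
        S = np.atleast_2d(S)
        p = S.shape[0]
        _, logdetS = np.linalg.slogdet(S)
        total += n * (logdetS + p + p * np.log(2 * np.pi))
    return total


def _ncx2_cdf(x: float, df: int, nc: float) -> float:
    if nc <= 0:
        return stats.chi2.cdf(x, df)
    return stats.ncx2.cdf(x, df, nc)


def _rmsea_ci(chi2: float, df: int, n_total: int, level: float) -> tuple[float, float]:
    """Invert the noncentral chi-square to bound the RMSEA noncentrality."""
    alpha = 1.0 - level
    lo_target, hi_target = 1.0 - alpha / 2.0, alpha / 2.0

    def bound(target: float) -> float:
        # cdf(chi2; df, nc) is decreasing in nc
        if _ncx2_cdf(chi2, df, 0.0) < target:
            return 0.0
        hi = max(chi2, 1.0)
        while _ncx2_cdf(chi2, df, hi) > target:
            hi *= 2.0
            if hi > 1e8:
                break
        nc = optimize.brentq(lambda l: _ncx2_cdf(chi2, df, l) - target, 0.0, hi)
        return nc

    nc_lo = bound(lo_target)
    nc_hi = bound(hi_target)
    lo = np.sqrt(nc_lo / (df * n_total))
    hi = np.sqrt(nc_hi / (df * n_total))
    return (float(lo), float(hi))


def compute_fit_stats(
    model: LikelihoodRecord,
    saturated: LikelihoodRecord,
    baseline: LikelihoodRecord | None,
    n_per_group: Sequence[int],
    rmsr: float | None = None,
    ci_level: float = 0.95,
) -> FitStats:
    """Assemble the fit-index battery from likelihood records.

    ``saturated.n_params`` must equal the number of observed moments, so the
    model's degrees of freedom are ``saturated.n_params - model.n_params``.
    ``baseline`` is the independence model (zero covariances); it drives the
    TLI and may be omitted (TLI reported as None).
    """
    n_total = int(np.sum(n_per_group))
    chi2 = max(model.minus2ll - saturated.minus2ll, 0.0)
    df = saturated.n_params - model.n_params
    if df < 0:
        raise ValueError("model has more free parameters than observed moments")
    pvalue = float(stats.chi2.sf(chi2, df)) if df > 0 else None
    aic = model.minus2ll + 2 * model.n_params
    bic = model.minus2ll + model.n_params * np.log(n_total)

    if df > 0:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n_total)))
        rmsea_ci = _rmsea_ci(chi2, df, n_total, ci_level)
    else:
        rmsea, rmsea_ci = None, None

    tli = None
    if baseline is not None and df > 0:
        chi2_b = max(baseline.minus2ll - saturated.minus2ll, 0.0)
        df_b = saturated.n_params - baseline.n_params
        if df_b > 0 and chi2_b / df_b > 1.0:
            tli = float(((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0))

    return FitStats(
        minus2ll=float(model.minus2ll),
        chi2=float(chi2),
        df=int(df),
        pvalue=pvalue,
        n_params=model.n_params,
        n_total=n_total,
        aic=float(aic),
        bic=float(bic),
        rmsea=rmsea,
        rmsea_ci=rmsea_ci,
        tli=tli,
        rmsr=rmsr,
    )


def standardized_residual_rms(
    groups: Iterable[tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray | None]],
) -> float:
    """Root mean square standardized residual over all groups.

    Each group contributes (S, Sigma, mbar, mu); covariance residuals are
    standardized by the observed standard deviations, mean residuals (when a
    mean structure is modelled, i.e. mu is not None) by the observed SD.
    """
    res: list[float] = []
    for S, Sigma, mbar, mu in groups:
        S = np.atleast_2d(S)
        Sigma = np.atleast_2d(Sigma)
        sd = np.sqrt(np.diag(S))
        p = S.shape[0]
        for i in range(p):
            for j in range(i, p):
                res.append((S[i, j] - Sigma[i, j]) / (sd[i] * sd[j]))
        if mu is not None and mbar is not None:
            for i in range(p):
                res.append((mbar[i] - mu[i]) / sd[i])
    arr = np.asarray(res)
    return float(np.sqrt(np.mean(arr**2)))


@dataclass
class SelectionReport:
    """Per-criterion winners of a model comparison; disagreements surfaced."""

    winners: dict[str, str]
    unanimous: bool
    table: pd.DataFrame


def model_selection(
    fits: Mapping[str, FitStats],
    criteria: Sequence[str] = ("aic", "bic"),
) -> SelectionReport:
    """Rank fitted models per criterion (smaller is better for all supported).

    Supported criteria: aic, bic, chi2, rmsea.  Models with a missing value
    for a criterion are excluded from that criterion's ranking.  When the
    criteria disagree, every winner is reported; no silent tie-break.
    """
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fitted models")
    rows = {name: fs.to_dict() for name, fs in fits.items()}
    table = pd.DataFrame.from_dict(rows, orient="index")
    winners: dict[str, str] = {}
    for crit in criteria:
        if crit not in table.columns:
            raise ValueError(f"unknown criterion: {crit}")
        col = table[crit].dropna()
        if len(col):
            winners[crit] = str(col.idxmin())
    unanimous = len(set(winners.values())) == 1
    return SelectionReport(winners=winners, unanimous=unanimous, table=table)
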