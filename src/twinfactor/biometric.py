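"""Univariate twin variance-component models (ACE / ADE / AE / CE, each
optionally with a sibling-interaction / rater-contrast parameter s).

Model
-----
Each twin's pre-interaction phenotype is a linear combination of latent
standard-normal components,

    P* = a·A + c·C + d·D + e·E,

where A correlates 1 across MZ co-twins and 0.5 across DZ co-twins,
D correlates 1 (MZ) and 0.25 (DZ), C is shared within a pair and E is
twin-specific.  A reciprocal sibling-interaction (equivalently, a rater
contrast) path s couples the observed pair vector:

    P = (I - B)^-1 P*,     B = [[0, s], [s, 0]].

With s = 0 this reduces to the classical biometric covariance algebra; a
nonzero s makes the observed phenotypic variance zygosity-dependent, which
is what identifies it.

Estimation is full-information normal-theory ML on the two zygosity groups'
means and covariances.  Both means and variances are equated across twin
order and zygosity (one free mean), so the ten observed statistics (two
means + three covariance entries per group) leave df = 10 - k.

Standardization convention for variance components: without a contrast,
h2 = a^2 / (a^2+c^2+d^2+e^2) and analogously for the other components,
summing to 1.  With a contrast the reported components are the *raw*
squared paths (which equal pre-contrast variance shares only when the
generating pre-contrast variance is 1); they need not sum to 1 because the
contrast inflates or deflates observed variance asymmetrically by
zygosity.  Raw squared paths are always available alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import TwinStudy
from .fitstats import (
    FitStats,
    LikelihoodRecord,
    compute_fit_stats,
    group_discrepancy,
    model_selection,
    saturated_minus2ll,
    standardized_residual_rms,
)

__all__ = [
    "BiometricParams",
    "BiometricFit",
    "expected_covariance",
    "fit_biometric",
    "profile_ci",
    "compare_biometric_models",
    "parse_model",
]

#: additive / dominance cross-twin correlations by zygosity
ZYGOSITY_R = {"MZ": (1.0, 1.0), "DZ": (0.5, 0.25)}

_MODEL_PATHS = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}


def parse_model(name: str) -> tuple[tuple[str, ...], bool]:
    """Split a model label like ``"AE+s"`` into free paths and a contrast flag."""
    base = name.strip()
    contrast = False
    if base.endswith("+s"):
        contrast = True
        base = base[:-2].strip()
    base = base.upper()
    if base not in _MODEL_PATHS:
        raise ValueError(f"unknown biometric model {name!r}; choose from "
                         f"{sorted(_MODEL_PATHS)} optionally suffixed with '+s'")
    return _MODEL_PATHS[base], contrast


@dataclass(frozen=True)
class BiometricParams:
    """Path coefficients of the univariate biometric model."""

    a: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = 0.0
    s: float = 0.0

    def __post_init__(self) -> None:
        if self.c != 0.0 and self.d != 0.0:
            raise ValueError(
                "shared environment (c) and dominance (d) cannot both be nonzero: "
                "the model is not identified with twin data alone"
            )
        if abs(self.s) >= 1.0:
            raise ValueError("|s| must be < 1 for the contrast transformation to be invertible")

    @property
    def total_variance(self) -> float:
        """Pre-contrast phenotypic variance a^2 + c^2 + d^2 + e^2."""
        return self.a**2 + self.c**2 + self.d**2 + self.e**2

    def contrast_matrix(self) -> np.ndarray:
        """(I - B)^-1 for the 2x2 symmetric contrast matrix B with off-diagonal s."""
        B = np.array([[0.0, self.s], [self.s, 0.0]])
        return np.linalg.inv(np.eye(2) - B)


def expected_covariance(params: BiometricParams, zygosity: str) -> np.ndarray:
    """Model-implied 2x2 twin-pair covariance matrix for one zygosity group."""
    if zygosity not in ZYGOSITY_R:
        raise ValueError("zygosity must be 'MZ' or 'DZ'")
    r_a, r_d = ZYGOSITY_R[zygosity]
    v = params.total_variance
    w = r_a * params.a**2 + params.c**2 + r_d * params.d**2
    G = np.array([[v, w], [w, v]])
    if params.s == 0.0:
        return G
    M = params.contrast_matrix()
    return M @ G @ M.T


def _implied(theta: np.ndarray, free: tuple[str, ...], contrast: bool):
    """Unpack a parameter vector into (params, mu) following the fit layout."""
    vals = dict(zip(free, theta[: len(free)]))
    k = len(free)
    s = theta[k] if contrast else 0.0
    mu = theta[k + int(contrast)]
    params = BiometricParams(
        a=vals.get("a", 0.0), c=vals.get("c", 0.0),
        d=vals.get("d", 0.0), e=vals.get("e", 0.0), s=s,
    )
    return params, mu


def _objective(theta, free, contrast, moments):
    params, mu = _implied(theta, free, contrast)
    total = 0.0
    mu2 = np.array([mu, mu])
    for zyg, (S, mbar, n) in moments.items():
        Sigma = expected_covariance(params, zyg)
        total += group_discrepancy(S, mbar, Sigma, mu2, n)
        if not np.isfinite(total):
            return 1e12
    return total


def _moments(study: TwinStudy, variable: str) -> dict:
    out = {}
    for g in study.groups:
        X = g.pair_array(variable)
        if len(X) < 3:
            raise ValueError("each zygosity group needs at least 3 pairs")
        S = np.cov(X, rowvar=False, bias=True)
        out[g.zygosity] = (np.atleast_2d(S), X.mean(axis=0), len(X))
    return out


def _baseline_minus2ll(moments: dict) -> LikelihoodRecord:
    """Independence baseline (zero twin covariance, one variance, one mean).

    This is the E-only model, whose ML solution is available in closed form:
    the grand mean and the pooled mean squared deviation around it.
    """
    n_tot = sum(n for _, _, n in moments.values())
    mu = sum(n * mbar.mean() for _, mbar, n in moments.values()) / n_tot
    ss = 0.0
    for S, mbar, n in moments.values():
        ss += n * (np.trace(S) + float(((mbar - mu) ** 2).sum()))
    v = ss / (2 * n_tot)
    m2ll = 0.0
    for S, mbar, n in moments.values():
        Sigma = v * np.eye(2)
        m2ll += group_discrepancy(S, mbar, Sigma, np.array([mu, mu]), n)
    m2ll += saturated_minus2ll((S, n) for S, _, n in moments.values())
    return LikelihoodRecord(minus2ll=m2ll, n_params=2)


@dataclass
class BiometricFit:
    """Result of a univariate biometric fit."""

    model: str
    params: BiometricParams
    mu: float
    components: dict[str, float]
    raw_squared_paths: dict[str, float]
    fitstats: FitStats
    converged: bool
    objective: float
    variable: str = ""
    ci: dict[str, tuple[float, float]] | None = None

    @property
    def h2(self) -> float:
        return self.components.get("h2", 0.0)

    @property
    def c2(self) -> float:
        return self.components.get("c2", 0.0)

    @property
    def d2(self) -> float:
        return self.components.get("d2", 0.0)

    @property
    def e2(self) -> float:
        return self.components.get("e2", 0.0)


def _components(params: BiometricParams, free: tuple[str, ...], contrast: bool) -> tuple[dict, dict]:
    raw = {f"{p}2": getattr(params, p) ** 2 for p in ("a", "c", "d", "e")}
    label = {"a2": "h2", "c2": "c2", "d2": "d2", "e2": "e2"}
    if contrast:
        comps = {label[k]: v for k, v in raw.items() if k[0] in free}
        comps["s"] = params.s
    else:
        tot = params.total_variance
        comps = {label[k]: (v / tot if tot > 0 else 0.0) for k, v in raw.items() if k[0] in free}
    return comps, raw


def _starts(moments: dict, free, contrast, n_starts: int, seed: int) -> list[np.ndarray]:
    """Moment-based starting point plus jittered variants."""
    (Sm, mm, nm) = moments["MZ"]
    (Sd, md, nd) = moments["DZ"]
    v = 0.5 * (np.trace(Sm) / 2 + np.trace(Sd) / 2)
    r_mz = Sm[0, 1] / np.sqrt(Sm[0, 0] * Sm[1, 1])
    r_dz = Sd[0, 1] / np.sqrt(Sd[0, 0] * Sd[1, 1])
    a2 = float(np.clip(2 * (r_mz - r_dz), 0.05, 0.9)) * v
    c2 = float(np.clip(2 * r_dz - r_mz, 0.05, 0.9)) * v
    base_vals = {"a": np.sqrt(a2), "c": np.sqrt(c2), "d": np.sqrt(max(v * 0.1, 1e-3)),
                 "e": np.sqrt(max(v - a2 - c2, 0.05 * v))}
    base = [base_vals[p] for p in free]
    if contrast:
        base.append(0.0)
    mu0 = (nm * mm.mean() + nd * md.mean()) / (nm + nd)
    base.append(mu0)
    base = np.asarray(base, dtype=float)
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(n_starts - 1):
        jit = base.copy()
        k = len(free)
        jit[:k] *= np.exp(rng.normal(0, 0.4, size=k))
        if contrast:
            jit[k] = rng.uniform(-0.3, 0.3)
        jit[-1] += rng.normal(0, 0.2) * np.sqrt(v)
        starts.append(jit)
    return starts


def _minimize(moments, free, contrast, starts, sd_scale, ftol=1e-10):
    bounds = [(0.0, 20.0 * sd_scale)] * len(free)
    if contrast:
        bounds.append((-0.95, 0.95))
    bounds.append((None, None))
    best, best_ok = None, None
    for x0 in starts:
        res = optimize.minimize(
            _objective, x0, args=(free, contrast, moments),
            method="L-BFGS-B", bounds=bounds,
            options={"ftol": ftol, "gtol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and (best_ok is None or res.fun < best_ok.fun):
            best_ok = res
    # prefer a cleanly converged run unless it is materially worse
    if best_ok is not None and best_ok.fun <= best.fun + 1e-6 * max(1.0, abs(best.fun)):
        return best_ok
    return best


def fit_biometric(
    study: TwinStudy,
    variable: str | None = None,
    model: str = "ACE",
    *,
    n_starts: int = 5,
    seed: int = 0,
    compute_ci: bool = False,
    ci_level: float = 0.95,
) -> BiometricFit:
    """ML fit of one univariate biometric model to MZ/DZ group moments.

    The objective is the two-group normal-theory discrepancy
    sum_g N_g [ln|Sigma_g| + tr(S_g Sigma_g^-1) + (mbar_g-mu)' Sigma_g^-1
    (mbar_g-mu) - ln|S_g| - 2] with one mean equated across twin order and
    zygosity.  Five jittered starting points guard against local minima.
    Boundary solutions (a path estimated at 0) are reported as-is.
    """
    if variable is None:
        if len(study.variables) != 1:
            raise ValueError("specify `variable` for a multi-variable study")
        variable = study.variables[0]
    free, contrast = parse_model(model)
    moments = _moments(study, variable)
    sd_scale = float(np.sqrt(np.mean([np.trace(S) / 2 for S, _, _ in moments.values()])))
    starts = _starts(moments, free, contrast, n_starts, seed)
    best = _minimize(moments, free, contrast, starts, sd_scale)

    params, mu = _implied(best.x, free, contrast)
    converged = bool(best.success) and np.isfinite(best.fun)

    n_params = len(free) + int(contrast) + 1
    sat = LikelihoodRecord(
        minus2ll=saturated_minus2ll((S, n) for S, _, n in moments.values()),
        n_params=10,
    )
    m2ll = best.fun + sat.minus2ll
    baseline = _baseline_minus2ll(moments)
    rmsr = standardized_residual_rms(
        (S, expected_covariance(params, z), mbar, np.array([mu, mu]))
        for z, (S, mbar, n) in moments.items()
    )
    fstats = compute_fit_stats(
        LikelihoodRecord(m2ll, n_params), sat, baseline,
        [n for _, _, n in moments.values()], rmsr=rmsr,
    )
    comps, raw = _components(params, free, contrast)
    fit = BiometricFit(
        model=model, params=params, mu=mu, components=comps,
        raw_squared_paths=raw, fitstats=fstats, converged=converged,
        objective=float(best.fun), variable=variable,
    )
    if compute_ci:
        fit.ci = {p: profile_ci(study, variable, model, fit, p, level=ci_level)
                  for p in free + (("s",) if contrast else ())}
    return fit


def profile_ci(
    study: TwinStudy,
    variable: str,
    model: str,
    fit: BiometricFit,
    target: str,
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood CI for one path (or s): objective rise of chi2_crit.

    The target parameter is fixed on a grid bracketed by bisection while all
    other parameters are re-optimized.
    """
    free, contrast = parse_model(model)
    if target != "s" and target not in free:
        raise ValueError(f"{target!r} is not a free path of model {model!r}")
    moments = _moments(study, variable)
    sd_scale = float(np.sqrt(np.mean([np.trace(S) / 2 for S, _, _ in moments.values()])))
    crit = stats.chi2.ppf(level, 1)
    cutoff = fit.objective + crit

    names = list(free) + (["s"] if contrast else []) + ["mu"]
    i_target = names.index(target)
    theta_hat = np.array(
        [getattr(fit.params, p) for p in free]
        + ([fit.params.s] if contrast else []) + [fit.mu]
    )

    def profiled(value: float) -> float:
        def obj(rest):
            theta = np.insert(rest, i_target, value)
            return _objective(theta, free, contrast, moments)

        x0 = np.delete(theta_hat, i_target)
        bnds = []
        for j, nm in enumerate(names):
            if j == i_target:
                continue
            if nm == "mu":
                bnds.append((None, None))
            elif nm == "s":
                bnds.append((-0.95, 0.95))
            else:
                bnds.append((0.0, 20.0 * sd_scale))
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bnds,
                                options={"ftol": 1e-10, "maxiter": 1000})
        return res.fun

    mle = theta_hat[i_target]
    lo_bound = -0.95 if target == "s" else 0.0
    hi_bound = 0.95 if target == "s" else 20.0 * sd_scale

    def edge(direction: int) -> float:
        limit = hi_bound if direction > 0 else lo_bound
        step = max(0.05 * sd_scale, 0.02)
        x = mle
        while True:
            x_next = x + direction * step
            if (direction > 0 and x_next >= limit) or (direction < 0 and x_next <= limit):
                if profiled(limit) <= cutoff:
                    return limit
                x_next = limit
                break
            if profiled(x_next) > cutoff:
                break
            x = x_next
            step *= 1.8
        return optimize.brentq(lambda v: profiled(v) - cutoff, min(x, x_next), max(x, x_next),
                               xtol=1e-5)

    return (float(edge(-1)), float(edge(+1)))


def compare_biometric_models(
    study: TwinStudy,
    variable: str | None = None,
    models: list[str] = ("ACE", "ADE", "AE", "CE", "AE+s"),
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit a ladder of biometric models to one trait and tabulate fit indices.

    One row per model: chi-square, df, p, AIC, BIC, RMSEA (+CI), TLI, RMSR,
    s and variance components, with per-criterion best-model flags.  The
    criteria may disagree; no single winner is imposed.  A model that fails
    outright contributes a row with status 'failed'.
    """
    rows = []
    fits: dict[str, FitStats] = {}
    for m in models:
        try:
            fit = fit_biometric(study, variable, m, seed=seed)
        except Exception as exc:  # propagate per-row, keep the ladder going
            rows.append({"model": m, "status": f"failed: {exc}"})
            continue
        fs = fit.fitstats
        fits[m] = fs
        row = {"model": m, "status": "ok" if fit.converged else "not converged"}
        row.update(fs.to_dict())
        row["s"] = fit.params.s if m.endswith("+s") else np.nan
        for key in ("h2", "c2", "d2", "e2"):
            row[key] = fit.components.get(key, np.nan)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("model")
    if len(fits) >= 2:
        report = model_selection(fits, criteria=("aic", "bic"))
        for crit, winner in report.winners.items():
            table[f"best_{crit}"] = [name == winner for name in table.index]
    return table
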