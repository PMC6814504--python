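"""Multivariate twin Cholesky decompositions.

Four observed variables per twin — the ODD general factor score, the two
specific factor scores, and one external symptom dimension, with the
general factor first and the external dimension last — are decomposed into
triangular additive-genetic (A), shared-environment (C) and nonshared-
environment (E) factor systems:

    Sigma_A = L_A L_A',   Sigma_C = L_C L_C',   Sigma_E = L_E L_E'.

Within-twin covariance is W = Sigma_A + Sigma_C + Sigma_E; the cross-twin
block is r_A Sigma_A + Sigma_C with r_A = 1 (MZ) or 0.5 (DZ).  Positive
semi-definiteness of every component holds by construction at every
optimizer iterate.  An optional rater-contrast path s couples the two
twins' external variable through the 8x8 (I - B)^-1 transformation.

The C structure may be full, restricted to a single loading on the first
variable ("C only on the general factor"), or absent.  A further
restriction zeroes the general factor's A and E loadings on the two
specific factors, which must fit dramatically worse whenever the data
really contain a general factor — a structural test of the bifactor
hypothesis at the etiological level.

Because the phenotypes at this stage are standardized factor scores, the
means are fixed at zero by default (88 observed statistics across the two
groups; df = 88 - k); free means are available for non-centered data.

The variance of the external (fourth) variable is decomposed into squared
standardized loadings: the share through the factor anchored at each
earlier variable plus a unique residual share, per component.  The total
per-component share of the external variable is invariant to swapping the
order of the two specific factors (a Cholesky reparameterization), while
the third-position ("unique") shares are exactly the order-dependent
quantities of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

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
    "CholeskySpec",
    "CholeskyParams",
    "CholeskyFit",
    "VarianceDecomposition",
    "expected_covariance_mv",
    "fit_cholesky",
    "reorder_and_refit",
    "compare_cholesky_models",
]

ZYGOSITY_RA = {"MZ": 1.0, "DZ": 0.5}
C_PATTERNS = ("full", "general_only", "none")


@dataclass(frozen=True)
class CholeskySpec:
    """Structure of one 4-variable Cholesky model.

    variables: ordered names; position 0 is the shared anchor (general
    factor) and position 3 the external dimension.  c_pattern restricts the
    shared-environment structure; drop_general_on_specifics zeroes the A and
    E loadings of factor 1 on variables 2 and 3 (the "no general loadings"
    restriction); contrast adds a rater-contrast path on the external
    variable.
    """

    variables: tuple[str, str, str, str]
    c_pattern: str = "full"
    contrast: bool = False
    drop_general_on_specifics: bool = False
    free_means: bool = False

    def __post_init__(self) -> None:
        if len(self.variables) != 4 or len(set(self.variables)) != 4:
            raise ValueError("need 4 distinct ordered variable names")
        if self.c_pattern not in C_PATTERNS:
            raise ValueError(f"c_pattern must be one of {C_PATTERNS}")

    def _mask(self, which: str) -> np.ndarray:
        tril = np.tril(np.ones((4, 4), dtype=bool))
        if which == "C":
            if self.c_pattern == "none":
                return np.zeros((4, 4), dtype=bool)
            if self.c_pattern == "general_only":
                m = np.zeros((4, 4), dtype=bool)
                m[0, 0] = True
                return m
            return tril
        m = tril.copy()
        if self.drop_general_on_specifics:
            m[1, 0] = False
            m[2, 0] = False
        return m

    @property
    def masks(self) -> dict[str, np.ndarray]:
        return {w: self._mask(w) for w in ("A", "C", "E")}

    @property
    def n_params(self) -> int:
        n = sum(int(m.sum()) for m in self.masks.values())
        return n + int(self.contrast) + (4 if self.free_means else 0)

    def swapped(self) -> "CholeskySpec":
        """Spec with the two middle (specific-factor) variables exchanged."""
        v = self.variables
        return replace(self, variables=(v[0], v[2], v[1], v[3]))


@dataclass(frozen=True)
class CholeskyParams:
    """Lower-triangular component loading matrices (and optional contrast)."""

    L_A: np.ndarray
    L_C: np.ndarray
    L_E: np.ndarray
    s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("L_A", "L_C", "L_E"):
            L = np.asarray(getattr(self, name), dtype=float)
            if L.shape != (4, 4) and L.shape[0] != L.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(L, np.tril(L)):
                raise ValueError(f"{name} must be lower-triangular")
            object.__setattr__(self, name, L)
        if abs(self.s) >= 1.0:
            raise ValueError("|s| must be < 1")

    @property
    def p(self) -> int:
        return self.L_A.shape[0]

    def component_covariances(self) -> dict[str, np.ndarray]:
        return {"A": self.L_A @ self.L_A.T, "C": self.L_C @ self.L_C.T,
                "E": self.L_E @ self.L_E.T}


def _contrast_transform(p: int, s: float) -> np.ndarray:
    """(I - B)^-1 for the 2p x 2p contrast coupling the twins' last variable."""
    B = np.zeros((2 * p, 2 * p))
    B[p - 1, 2 * p - 1] = s
    B[2 * p - 1, p - 1] = s
    return np.linalg.inv(np.eye(2 * p) - B)


def expected_covariance_mv(params: CholeskyParams, zygosity: str) -> np.ndarray:
    """Model-implied 2p x 2p twin-pair covariance (variables of twin 1, then twin 2)."""
    if zygosity not in ZYGOSITY_RA:
        raise ValueError("zygosity must be 'MZ' or 'DZ'")
    r_a = ZYGOSITY_RA[zygosity]
    comp = params.component_covariances()
    W = comp["A"] + comp["C"] + comp["E"]
    X = r_a * comp["A"] + comp["C"]
    Sigma = np.block([[W, X], [X, W]])
    if params.s != 0.0:
        M = _contrast_transform(params.p, params.s)
        Sigma = M @ Sigma @ M.T
    return Sigma


@dataclass
class VarianceDecomposition:
    """Common/unique variance shares of the external (last) variable.

    ``shares`` is a 3 x 4 table: rows A, C, E; the first three columns are
    the squared standardized loadings through the factors anchored at each
    earlier variable, the last column the component-specific residual share.
    Shares across all fitted components sum to 1 (no-contrast models).
    """

    variable: str
    shares: pd.DataFrame
    ci: dict[tuple[str, str], tuple[float, float]] | None = None

    def component_total(self, component: str) -> float:
        return float(self.shares.loc[component].sum())

    @property
    def a_shares(self) -> pd.Series:
        return self.shares.loc["A"]


def _decompose(params: CholeskyParams, variables: tuple[str, ...]) -> VarianceDecomposition:
    comp = params.component_covariances()
    total = sum(M[3, 3] for M in comp.values())
    cols = [f"via_{variables[0]}", f"via_{variables[1]}", f"via_{variables[2]}", "residual"]
    rows = {}
    for name, L in (("A", params.L_A), ("C", params.L_C), ("E", params.L_E)):
        rows[name] = (L[3, :] ** 2) / total
    shares = pd.DataFrame(rows).T
    shares.columns = cols
    return VarianceDecomposition(variable=variables[3], shares=shares)


# ---------------------------------------------------------------------------
# fitting

def _pack_bounds(spec: CholeskySpec, scale: float) -> list[tuple]:
    bounds: list[tuple] = []
    for w in ("A", "C", "E"):
        m = spec.masks[w]
        for i in range(4):
            for j in range(i + 1):
                if m[i, j]:
                    bounds.append((0.0, 20.0 * scale) if i == j else (None, None))
    if spec.contrast:
        bounds.append((-0.95, 0.95))
    if spec.free_means:
        bounds.extend([(None, None)] * 4)
    return bounds


def _unpack(theta: np.ndarray, spec: CholeskySpec) -> tuple[CholeskyParams, np.ndarray]:
    k = 0
    Ls = {}
    for w in ("A", "C", "E"):
        m = spec.masks[w]
        L = np.zeros((4, 4))
        idx = [(i, j) for i in range(4) for j in range(i + 1) if m[i, j]]
        for (i, j) in idx:
            L[i, j] = theta[k]
            k += 1
        Ls[w] = L
    s = 0.0
    if spec.contrast:
        s = float(theta[k])
        k += 1
    mu = np.zeros(4)
    if spec.free_means:
        mu = np.asarray(theta[k:k + 4], dtype=float)
    params = CholeskyParams(L_A=Ls["A"], L_C=Ls["C"], L_E=Ls["E"], s=s)
    return params, mu


def _pack(params: CholeskyParams, spec: CholeskySpec, mu: np.ndarray | None = None) -> np.ndarray:
    vals = []
    for w, L in (("A", params.L_A), ("C", params.L_C), ("E", params.L_E)):
        m = spec.masks[w]
        for i in range(4):
            for j in range(i + 1):
                if m[i, j]:
                    vals.append(L[i, j])
    if spec.contrast:
        vals.append(params.s)
    if spec.free_means:
        vals.extend((mu if mu is not None else np.zeros(4)).tolist())
    return np.asarray(vals, dtype=float)


def _mv_objective(theta, spec, moments):
    params, mu = _unpack(theta, spec)
    mu8 = np.concatenate([mu, mu])
    total = 0.0
    for zyg, (S, mbar, n) in moments.items():
        Sigma = expected_covariance_mv(params, zyg)
        total += group_discrepancy(S, mbar, Sigma, mu8, n)
        if not np.isfinite(total):
            return 1e12
    return total


def _mv_moments(study: TwinStudy, variables: tuple[str, ...]) -> dict:
    sub = study.select(list(variables))
    out = {}
    for g in sub.groups:
        S, mbar, n = g.moments()
        out[g.zygosity] = (S, mbar, n)
    return out


def _nearest_psd_chol(M: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    w = np.clip(w, floor, None)
    return np.linalg.cholesky(V @ np.diag(w) @ V.T)


def _moment_start(spec: CholeskySpec, moments: dict) -> np.ndarray:
    """Initialize from the classical moment decomposition of the saturated blocks."""
    Sm, mm, nm = moments["MZ"]
    Sd, md, nd = moments["DZ"]
    Wm = 0.5 * (Sm[:4, :4] + Sm[4:, 4:])
    Wd = 0.5 * (Sd[:4, :4] + Sd[4:, 4:])
    Xm = 0.5 * (Sm[:4, 4:] + Sm[4:, :4].T)
    Xd = 0.5 * (Sd[:4, 4:] + Sd[4:, :4].T)
    W = (nm * Wm + nd * Wd) / (nm + nd)
    SigA = 2.0 * (Xm - Xd)
    SigC = 2.0 * Xd - Xm
    SigE = W - Xm
    L_A = _nearest_psd_chol(SigA)
    L_E = _nearest_psd_chol(SigE)
    L_C = np.zeros((4, 4))
    if spec.c_pattern == "full":
        L_C = _nearest_psd_chol(SigC, floor=1e-4)
    elif spec.c_pattern == "general_only":
        L_C[0, 0] = np.sqrt(max(SigC[0, 0], 1e-3))
    if spec.drop_general_on_specifics:
        L_A[1, 0] = L_A[2, 0] = 0.0
        L_E[1, 0] = L_E[2, 0] = 0.0
    params = CholeskyParams(L_A=L_A, L_C=L_C, L_E=L_E, s=0.0)
    mu0 = (nm * mm[:4] + nd * md[:4]) / (nm + nd) if spec.free_means else None
    return _pack(params, spec, mu0)


@dataclass
class CholeskyFit:
    """Fitted 4-variable Cholesky model."""

    spec: CholeskySpec
    params: CholeskyParams
    mu: np.ndarray
    decomposition: VarianceDecomposition
    fitstats: FitStats
    converged: bool
    identified: bool | None
    objective: float
    status: str = "ok"


def _baseline_record(moments: dict, free_means: bool) -> LikelihoodRecord:
    """Independence baseline: diagonal covariance, variances equated across
    twins and zygosity, means per the model's convention (zero or free)."""
    n_tot = sum(n for _, _, n in moments.values())
    p = 4
    v = np.zeros(p)
    mu = np.zeros(p)
    if free_means:
        for S, mbar, n in moments.values():
            mu += n * 0.5 * (mbar[:p] + mbar[p:])
        mu /= n_tot
    for S, mbar, n in moments.values():
        d = np.diag(S)
        m2 = (mbar[:p] - mu) ** 2 + (mbar[p:] - mu) ** 2
        v += n * (d[:p] + d[p:] + m2)
    v /= 2 * n_tot
    m2ll = 0.0
    mu8 = np.concatenate([mu, mu])
    for S, mbar, n in moments.values():
        Sigma = np.diag(np.concatenate([v, v]))
        m2ll += group_discrepancy(S, mbar, Sigma, mu8, n)
    m2ll += saturated_minus2ll((S, n) for S, _, n in moments.values())
    return LikelihoodRecord(m2ll, n_params=p + (p if free_means else 0))


def _hessian_identified(fun, x, scale: float = 1e-4, tol: float = 1e-6) -> bool:
    """Crude local-identification check: the finite-difference Hessian of the
    discrepancy at the optimum must be numerically full rank."""
    k = len(x)
    H = np.zeros((k, k))
    h = np.maximum(np.abs(x), 1.0) * scale
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            xi, xj = np.zeros(k), np.zeros(k)
            xi[i] = h[i]
            xj[j] = h[j]
            fpp = fun(x + xi + xj)
            fpm = fun(x + xi - xj)
            fmp = fun(x - xi + xj)
            fmm = fun(x - xi - xj)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    w = np.linalg.eigvalsh(0.5 * (H + H.T))
    wmax = max(np.max(np.abs(w)), 1.0)
    return bool(np.min(w) > tol * wmax)


def fit_cholesky(
    study: TwinStudy,
    spec: CholeskySpec,
    *,
    n_starts: int = 5,
    seed: int = 0,
    init: np.ndarray | None = None,
    check_identification: bool = True,
) -> CholeskyFit:
    """ML fit of one Cholesky model to the two-group 8-variate moments.

    Starts from the classical moment decomposition of the saturated MZ/DZ
    blocks (plus jittered variants).  A non-identified specification —
    detected from a rank-deficient Hessian at the optimum — is reported via
    ``status='not identified'`` with the decomposition withheld rather than
    returning bogus estimates.
    """
    moments = _mv_moments(study, spec.variables)
    scale = float(np.sqrt(np.mean([np.trace(S) / 8 for S, _, _ in moments.values()])))
    bounds = _pack_bounds(spec, scale)

    starts = []
    if init is not None:
        starts.append(np.asarray(init, dtype=float))
    base = _moment_start(spec, moments)
    starts.append(base)
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts + (init is not None):
        jit = base + rng.normal(0, 0.05 * scale, size=base.shape)
        if spec.contrast:
            jit[-1 - (4 if spec.free_means else 0)] = rng.uniform(-0.2, 0.2)
        starts.append(jit)

    best, best_ok = None, None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] if b[0] is not None else -np.inf for b in bounds],
                     [b[1] if b[1] is not None else np.inf for b in bounds])
        res = optimize.minimize(
            _mv_objective, x0, args=(spec, moments), method="L-BFGS-B",
            bounds=bounds, options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 10000},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and (best_ok is None or res.fun < best_ok.fun):
            best_ok = res
    if best_ok is not None and best_ok.fun <= best.fun + 1e-6 * max(1.0, abs(best.fun)):
        best = best_ok

    params, mu = _unpack(best.x, spec)
    converged = bool(best.success) and np.isfinite(best.fun)

    identified: bool | None = None
    status = "ok"
    if check_identification:
        identified = _hessian_identified(lambda t: _mv_objective(t, spec, moments), best.x)
        if not identified:
            status = "not identified"
    if not converged:
        status = "did not converge"

    sat = LikelihoodRecord(
        saturated_minus2ll((S, n) for S, _, n in moments.values()), n_params=2 * (36 + 8)
    )
    m2ll = best.fun + sat.minus2ll
    baseline = _baseline_record(moments, spec.free_means)
    mu8 = np.concatenate([mu, mu])
    rmsr = standardized_residual_rms(
        (S, expected_covariance_mv(params, z), mbar, mu8)
        for z, (S, mbar, n) in moments.items()
    )
    fstats = compute_fit_stats(
        LikelihoodRecord(m2ll, spec.n_params), sat, baseline,
        [n for _, _, n in moments.values()], rmsr=rmsr,
    )
    decomp = _decompose(params, spec.variables)
    return CholeskyFit(
        spec=spec, params=params, mu=mu, decomposition=decomp,
        fitstats=fstats, converged=converged, identified=identified,
        objective=float(best.fun), status=status,
    )


def _permuted_init(fit: CholeskyFit, swapped: CholeskySpec) -> np.ndarray | None:
    """Re-Cholesky the fitted component covariances under the swapped order.

    The swapped-order model spans the same covariance structures, so the
    permuted re-factorization of the optimum is (numerically) the swapped
    optimum itself — used as the primary starting point.
    """
    P = np.eye(4)[[0, 2, 1, 3]]
    try:
        comp = fit.params.component_covariances()
        L_A = _nearest_psd_chol(P @ comp["A"] @ P.T, floor=1e-10)
        L_E = _nearest_psd_chol(P @ comp["E"] @ P.T, floor=1e-10)
        L_C = np.zeros((4, 4))
        if swapped.c_pattern == "full":
            L_C = _nearest_psd_chol(P @ comp["C"] @ P.T, floor=1e-10)
        elif swapped.c_pattern == "general_only":
            L_C[0, 0] = fit.params.L_C[0, 0]
        params = CholeskyParams(L_A=L_A, L_C=L_C, L_E=L_E, s=fit.params.s)
        return _pack(params, swapped, fit.mu if swapped.free_means else None)
    except np.linalg.LinAlgError:
        return None


@dataclass
class ReorderReport:
    """Paired fits under both orderings of the two specific factors."""

    fit: CholeskyFit
    fit_swapped: CholeskyFit
    unique_shares: pd.DataFrame  # third-position shares per component per ordering
    total_shares: pd.DataFrame   # per-component totals of the external variable

    def max_total_discrepancy(self) -> float:
        return float(np.abs(self.total_shares.iloc[:, 0] - self.total_shares.iloc[:, 1]).max())


def reorder_and_refit(study: TwinStudy, spec: CholeskySpec, **fit_kwargs) -> ReorderReport:
    """Fit the model under both specific-factor orderings.

    Reports the third-position (unique) share of each specific factor and
    checks the reparameterization invariant: the external variable's total
    per-component shares must agree across orderings.
    """
    fit1 = fit_cholesky(study, spec, **fit_kwargs)
    swapped = spec.swapped()
    init = _permuted_init(fit1, swapped)
    fit2 = fit_cholesky(study, swapped, init=init, **fit_kwargs)

    rows = {}
    for f in (fit1, fit2):
        third = f.spec.variables[2]
        rows[f"{third} third"] = f.decomposition.shares.iloc[:, 2]
    unique = pd.DataFrame(rows)

    totals = pd.DataFrame({
        "->".join(fit1.spec.variables[1:3]): fit1.decomposition.shares.sum(axis=1),
        "->".join(fit2.spec.variables[1:3]): fit2.decomposition.shares.sum(axis=1),
    })
    return ReorderReport(fit=fit1, fit_swapped=fit2, unique_shares=unique, total_shares=totals)


#: the four-model ladder fitted per external dimension
LADDER = (
    ("full", {"c_pattern": "full"}),
    ("c_general_only", {"c_pattern": "general_only"}),
    ("no_c", {"c_pattern": "none"}),
    ("no_general_on_specifics", {"c_pattern": "none", "drop_general_on_specifics": True}),
)


def compare_cholesky_models(
    study: TwinStudy,
    variables: tuple[str, str, str, str],
    *,
    contrast: bool = False,
    free_means: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the standard model ladder and tabulate fit indices + decompositions.

    Ladder: full model; C restricted to the general factor; no C; no C and no
    general-factor A/E loadings on the specific factors.  When ``contrast``
    is set (for external dimensions whose univariate best model carries s),
    every rung includes the contrast and an extra contrast-free full model
    rung is added, mirroring the treatment of full models that fail to
    identify with a contrast.
    """
    rungs: list[tuple[str, dict]] = []
    for name, kw in LADDER:
        rungs.append((name, dict(kw, contrast=contrast)))
        if name == "full" and contrast:
            rungs.append(("full_no_s", dict(kw, contrast=False)))
    rows = []
    fits: dict[str, FitStats] = {}
    for name, kw in rungs:
        spec = CholeskySpec(variables=variables, free_means=free_means, **kw)
        try:
            fit = fit_cholesky(study, spec, seed=seed)
        except Exception as exc:
            rows.append({"model": name, "status": f"failed: {exc}"})
            continue
        row = {"model": name, "status": fit.status}
        row.update(fit.fitstats.to_dict())
        if fit.status == "ok":
            fits[name] = fit.fitstats
            for comp in ("A", "C", "E"):
                for col, val in fit.decomposition.shares.loc[comp].items():
                    row[f"{comp}_{col}"] = val
        rows.append(row)
    table = pd.DataFrame(rows).set_index("model")
    if len(fits) >= 2:
        report = model_selection(fits, criteria=("aic", "bic"))
        for crit, winner in report.winners.items():
            table[f"best_{crit}"] = [name == winner for name in table.index]
    return table
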