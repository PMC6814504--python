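"""Synthetic twin-pair data with known bifactor, biometric and regression
structure.

Every downstream stage of the package (measurement, regression, univariate
and multivariate biometrics) can be validated by parameter recovery against
the generating values produced here.  The generator emulates the structure
of a parent-rated community twin cohort: MZ/DZ pairs of children aged 6-18,
eight oppositional symptoms rated 0-4, and five co-rated external symptom
dimensions.  Defaults use 392 MZ and 454 DZ pairs, same-sex pairs, and
right-skewed ordinal symptom distributions.

The latent machinery is exact: additive-genetic deviates correlate 1 / 0.5
across MZ / DZ co-twins (0.25 for dominance), shared environment is common
to a pair, nonshared environment is twin-specific, and a nonzero contrast
parameter transforms each observed pair vector by (I - B)^-1.  Identical
seeds give bit-identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bifactor import BifactorSpec, FACTOR_NAMES, default_odd_spec
from .biometric import BiometricParams, ZYGOSITY_R
from .cholesky import CholeskyParams, ZYGOSITY_RA, _contrast_transform
from .data import TwinSample, TwinStudy

__all__ = [
    "GenerativeConfig",
    "default_generative_config",
    "simulate_univariate_twin_sample",
    "simulate_multivariate_twin_sample",
    "simulate_symptom_ratings",
    "simulate_study",
    "simulate_regression_dataset",
    "example_cholesky_truth",
]


def _default_loadings(spec: BifactorSpec) -> np.ndarray:
    """Moderate, item-varying loadings respecting the bifactor pattern."""
    general = [0.65, 0.60, 0.70, 0.55, 0.50, 0.60, 0.70, 0.55]
    specific = [0.45, 0.50, 0.40, 0.45, 0.35, 0.50, 0.40, 0.55]
    pat = spec.pattern_array
    lam = np.zeros((len(spec.items), 3))
    for i in range(len(spec.items)):
        lam[i, 0] = general[i % len(general)]
        j = 1 if pat[i, 1] else 2
        lam[i, j] = specific[i % len(specific)]
    return lam


def _pair_covariates(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Same-sex pairs; ages uniform on the 6-18 cohort range."""
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(6.0, 18.0, size=n)
    return sex, age


def _correlated_pairs(rng: np.random.Generator, n: int, r: float, k: int = 1) -> np.ndarray:
    """(n, 2, k) standard-normal deviates with cross-twin correlation r."""
    z1 = rng.standard_normal((n, k))
    z2 = rng.standard_normal((n, k))
    t2 = r * z1 + np.sqrt(max(1.0 - r * r, 0.0)) * z2
    return np.stack([z1, t2], axis=1)


def _latent_pair(
    rng: np.random.Generator, params: BiometricParams, n: int, zygosity: str
) -> np.ndarray:
    """(n, 2) pre-contrast latent trait values for one zygosity group."""
    r_a, r_d = ZYGOSITY_R[zygosity]
    y = np.zeros((n, 2))
    if params.a:
        y += params.a * _correlated_pairs(rng, n, r_a)[:, :, 0]
    if params.d:
        y += params.d * _correlated_pairs(rng, n, r_d)[:, :, 0]
    if params.c:
        y += params.c * rng.standard_normal((n, 1))
    if params.e:
        y += params.e * rng.standard_normal((n, 2))
    return y


def simulate_univariate_twin_sample(
    params: BiometricParams,
    n_mz: int,
    n_dz: int,
    seed: int,
    variable: str = "trait",
) -> TwinStudy:
    """One continuous trait per twin under a known biometric decomposition.

    MZ additive deviates correlate 1, DZ 0.5 (0.25 for dominance); C is
    shared within a pair; E is independent.  If s is nonzero each observed
    pair vector is (I - B)^-1 times the latent pair vector.
    """
    if n_mz < 1 or n_dz < 1:
        raise ValueError("need at least one pair per zygosity group")
    rng = np.random.default_rng(seed)
    M = params.contrast_matrix() if params.s else None
    samples = {}
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        y = _latent_pair(rng, params, n, zyg)
        if M is not None:
            y = y @ M.T
        sex, age = _pair_covariates(rng, n)
        samples[zyg] = TwinSample(zyg, y[:, :, None], [variable], sex, age)
    return TwinStudy(mz=samples["MZ"], dz=samples["DZ"])


def simulate_multivariate_twin_sample(
    params: CholeskyParams,
    n_mz: int,
    n_dz: int,
    seed: int,
    variables: tuple[str, ...] = ("general", "defiant", "irritability", "external"),
) -> TwinStudy:
    """Multi-trait twin sample under a known Cholesky decomposition.

    Per twin, y = L_A a + L_C c + L_E e with a correlated r_A across
    co-twins, c shared and e independent.  A nonzero contrast couples the
    two twins' last variable exactly as in the fitted model.
    """
    if n_mz < 1 or n_dz < 1:
        raise ValueError("need at least one pair per zygosity group")
    p = params.p
    if len(variables) != p:
        raise ValueError("variable-name count must match the loading matrices")
    rng = np.random.default_rng(seed)
    samples = {}
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        r_a = ZYGOSITY_RA[zyg]
        A = _correlated_pairs(rng, n, r_a, p)            # (n, 2, p)
        C = np.repeat(rng.standard_normal((n, 1, p)), 2, axis=1)
        E = rng.standard_normal((n, 2, p))
        y = A @ params.L_A.T + C @ params.L_C.T + E @ params.L_E.T
        if params.s:
            M2 = np.linalg.inv(np.eye(2) - np.array([[0.0, params.s], [params.s, 0.0]]))
            y[:, :, p - 1] = y[:, :, p - 1] @ M2.T
        sex, age = _pair_covariates(rng, n)
        samples[zyg] = TwinSample(zyg, y, list(variables), sex, age)
    return TwinStudy(mz=samples["MZ"], dz=samples["DZ"])


@dataclass
class GenerativeConfig:
    """Complete specification of a synthetic twin study.

    biometric maps each latent ODD factor (and, optionally, the residual of
    each external dimension) to its variance decomposition; loadings and
    residual_variances define the item measurement model; thresholds are the
    ordered cut-points mapping liabilities to 0-4 ratings; regression gives
    each external dimension's coefficients on the three (orthogonal, unit
    variance) ODD factors.
    """

    n_mz: int = 392
    n_dz: int = 454
    biometric: dict[str, BiometricParams] = field(default_factory=dict)
    loadings: np.ndarray | None = None            # 8 x 3
    residual_variances: np.ndarray | None = None  # 8
    thresholds: np.ndarray | None = None          # 4 increasing cut-points
    regression: dict[str, np.ndarray] = field(default_factory=dict)
    discretize: bool = True
    seed: int = 0
    spec: BifactorSpec = field(default_factory=default_odd_spec)

    def __post_init__(self) -> None:
        if self.n_mz < 1 or self.n_dz < 1:
            raise ValueError("need at least one pair per zygosity group")
        if self.loadings is None:
            # varied loadings: a constant-loading bifactor pattern is
            # empirically underidentified (general/specific trade-off)
            self.loadings = _default_loadings(self.spec)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape != (len(self.spec.items), 3):
            raise ValueError("loadings must be items x 3")
        if ((self.loadings != 0) & ~self.spec.pattern_array).any():
            raise ValueError("nonzero loadings must follow the bifactor pattern")
        if self.residual_variances is None:
            common = (self.loadings**2).sum(axis=1)
            self.residual_variances = np.clip(1.0 - common, 0.05, None)
        self.residual_variances = np.asarray(self.residual_variances, dtype=float)
        if (self.residual_variances < 0).any():
            raise ValueError("residual variances must be nonnegative")
        if self.thresholds is None:
            # right-skewed ratings: most children score 0, few score 4
            self.thresholds = np.array([0.25, 0.85, 1.5, 2.1])
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if len(self.thresholds) != 4 or (np.diff(self.thresholds) <= 0).any():
            raise ValueError("thresholds must be 4 strictly increasing cut-points")
        for name, beta in self.regression.items():
            beta = np.asarray(beta, dtype=float)
            if float(beta @ beta) > 1.0:
                raise ValueError(
                    f"{name}: sum of squared coefficients exceeds 1; "
                    "residual variance would be negative"
                )
            self.regression[name] = beta
        for name in ("general", "irritability", "defiant"):
            self.biometric.setdefault(name, BiometricParams(a=np.sqrt(0.5), e=np.sqrt(0.5)))


def default_generative_config(seed: int = 0) -> GenerativeConfig:
    """Study conditions mirroring the published best-fitting estimates.

    392 MZ / 454 DZ pairs; ODD general factor ACE (.41/.13/.46), specific
    irritability AE (.64/.36) and defiant AE (.68/.32); external dimensions
    regressed on the factors with the published standardized coefficients,
    their residuals decomposed AE with heritabilities matching the
    univariate fits of the respective dimensions.
    """
    sq = np.sqrt
    biometric = {
        "general": BiometricParams(a=sq(0.41), c=sq(0.13), e=sq(0.46)),
        "irritability": BiometricParams(a=sq(0.64), e=sq(0.36)),
        "defiant": BiometricParams(a=sq(0.68), e=sq(0.32)),
        "cd": BiometricParams(a=sq(0.78), e=sq(0.22)),
        "inattention": BiometricParams(a=sq(0.51), e=sq(0.49)),
        "hyperactivity": BiometricParams(a=sq(0.71), e=sq(0.29)),
        "depression": BiometricParams(a=sq(0.61), e=sq(0.39)),
        "gad": BiometricParams(a=sq(0.70), e=sq(0.30)),
    }
    regression = {
        "inattention": np.array([0.24, 0.08, 0.27]),
        "hyperactivity": np.array([0.24, -0.06, 0.48]),
        "cd": np.array([0.28, -0.07, 0.53]),
        "depression": np.array([0.18, 0.35, -0.04]),
        "gad": np.array([0.20, 0.40, -0.13]),
    }
    return GenerativeConfig(biometric=biometric, regression=regression, seed=seed)


def _latent_factors(config: GenerativeConfig, rng: np.random.Generator, n: int, zyg: str) -> np.ndarray:
    """(n, 2, 3) orthogonal latent factor values (general, irritability, defiant)."""
    F = np.empty((n, 2, 3))
    for j, name in enumerate(FACTOR_NAMES):
        pr = config.biometric[name]
        scale = np.sqrt(pr.total_variance)
        F[:, :, j] = _latent_pair(rng, pr, n, zyg) / (scale if scale > 0 else 1.0)
    return F


def _discretize(liab: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    return np.digitize(liab, thresholds).astype(float)


def simulate_symptom_ratings(config: GenerativeConfig, return_latent: bool = False):
    """Item-level twin sample: liabilities Lambda·F + residual, cut to 0-4.

    Latent factors are decomposed per their BiometricParams across the twin
    pair and rescaled to unit variance; item residuals are twin-specific.
    With ``discretize=False`` the continuous liabilities are returned
    (the continuous path used by all recovery analyses).
    """
    rng = np.random.default_rng(config.seed)
    items = list(config.spec.items)
    samples, latents = {}, {}
    for zyg, n in (("MZ", config.n_mz), ("DZ", config.n_dz)):
        F = _latent_factors(config, rng, n, zyg)
        resid = rng.standard_normal((n, 2, len(items))) * np.sqrt(config.residual_variances)
        liab = F @ config.loadings.T + resid
        y = _discretize(liab, config.thresholds) if config.discretize else liab
        sex, age = _pair_covariates(rng, n)
        samples[zyg] = TwinSample(zyg, y, items, sex, age)
        latents[zyg] = F
    study = TwinStudy(mz=samples["MZ"], dz=samples["DZ"])
    if return_latent:
        return study, latents
    return study


def simulate_study(config: GenerativeConfig) -> TwinStudy:
    """Full synthetic study: 8 symptom items plus every configured external
    dimension, per twin.

    Each external dimension is beta'F plus a residual with its own AE twin
    structure (from ``config.biometric[name]``, normalized), scaled so the
    dimension's total variance is 1.
    """
    rng = np.random.default_rng(config.seed)
    items = list(config.spec.items)
    externals = list(config.regression)
    samples = {}
    for zyg, n in (("MZ", config.n_mz), ("DZ", config.n_dz)):
        F = _latent_factors(config, rng, n, zyg)
        resid = rng.standard_normal((n, 2, len(items))) * np.sqrt(config.residual_variances)
        liab = F @ config.loadings.T + resid
        y_items = _discretize(liab, config.thresholds) if config.discretize else liab
        cols = [y_items]
        for name in externals:
            beta = config.regression[name]
            r2 = float(beta @ beta)
            pr = config.biometric.get(name, BiometricParams(e=1.0))
            u = _latent_pair(rng, pr, n, zyg)
            u /= np.sqrt(pr.total_variance)
            ext = F @ beta + np.sqrt(1.0 - r2) * u
            cols.append(ext[:, :, None])
        y = np.concatenate(cols, axis=2)
        sex, age = _pair_covariates(rng, n)
        samples[zyg] = TwinSample(zyg, y, items + externals, sex, age)
    return TwinStudy(mz=samples["MZ"], dz=samples["DZ"])


def simulate_regression_dataset(
    coefs: np.ndarray,
    n: int,
    seed: int,
    outcome: str = "outcome",
    covariates: bool = False,
) -> pd.DataFrame:
    """Flat table for regression recovery: three orthogonal standard-normal
    factor scores and an outcome with unit total variance and population
    R-squared equal to the sum of squared coefficients."""
    beta = np.asarray(coefs, dtype=float)
    if beta.shape != (3,):
        raise ValueError("expected three coefficients (general, irritability, defiant)")
    r2 = float(beta @ beta)
    if r2 > 1.0:
        raise ValueError("sum of squared coefficients exceeds 1; residual variance negative")
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, 3))
    y = F @ beta + np.sqrt(1.0 - r2) * rng.standard_normal(n)
    df = pd.DataFrame(F, columns=FACTOR_NAMES)
    df[outcome] = y
    if covariates:
        df["sex"] = rng.integers(0, 2, size=n).astype(float)
        df["age"] = rng.uniform(6.0, 18.0, size=n)
    return df


def example_cholesky_truth() -> CholeskyParams:
    """A conduct-disorder-like generative truth for multivariate recovery.

    Unit-variance variables (general, defiant, irritability, external) with
    no shared environment; the external variable's additive-genetic variance
    splits into .20 via the general factor, .16 via defiant, .004 via
    irritability and .41 unique, with the remaining .226 nonshared
    environment mostly unique.
    """
    sq = np.sqrt
    L_A = np.array([
        [sq(0.56), 0, 0, 0],
        [0.45, sq(0.68 - 0.45**2), 0, 0],
        [0.40, 0.30, sq(0.64 - 0.16 - 0.09), 0],
        [sq(0.20), sq(0.16), sq(0.004), sq(0.41)],
    ])
    L_E = np.array([
        [sq(0.44), 0, 0, 0],
        [0.10, sq(0.32 - 0.01), 0, 0],
        [0.10, 0.05, sq(0.36 - 0.01 - 0.0025), 0],
        [sq(0.02), sq(0.02), sq(0.01), sq(0.176)],
    ])
    return CholeskyParams(L_A=L_A, L_C=np.zeros((4, 4)), L_E=L_E, s=0.0)
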