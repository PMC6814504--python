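"""Generator correctness: moment convergence, determinism, degenerate cases."""

import numpy as np
import pytest

from twinfactor import (
    BiometricParams,
    GenerativeConfig,
    TwinStudy,
    default_generative_config,
    read_twin_csv,
    simulate_regression_dataset,
    simulate_study,
    simulate_symptom_ratings,
    simulate_univariate_twin_sample,
    write_twin_csv,
)


def _cross_twin_cov(study: TwinStudy, zygosity: str, variable: str = "trait") -> float:
    g = study.mz if zygosity == "MZ" else study.dz
    X = g.pair_array(variable)
    return float(np.cov(X[:, 0], X[:, 1], bias=True)[0, 1])


class TestUnivariateGenerator:
    def test_pure_additive_mz_twins_identical(self):
        study = simulate_univariate_twin_sample(BiometricParams(a=1.0), 200, 200, seed=0)
        X = study.mz.pair_array("trait")
        assert np.allclose(X[:, 0], X[:, 1])

    def test_ae_moments_converge_to_expected(self):
        # moderate additive-genetic trait: MZ covariance a^2, DZ covariance a^2/2
        params = BiometricParams(a=np.sqrt(0.64), e=np.sqrt(0.36))
        study = simulate_univariate_twin_sample(params, 50000, 50000, seed=3)
        assert _cross_twin_cov(study, "MZ") == pytest.approx(0.64, abs=0.02)
        assert _cross_twin_cov(study, "DZ") == pytest.approx(0.32, abs=0.02)

    def test_contrast_population_covariance(self):
        # pure-A with negative contrast: every covariance entry (1-s)^2/(1-s^2)^2
        params = BiometricParams(a=1.0, s=-0.1)
        study = simulate_univariate_twin_sample(params, 50000, 1, seed=5)
        X = study.mz.pair_array("trait")
        S = np.cov(X, rowvar=False, bias=True)
        assert np.allclose(S, 0.8264, atol=0.02)

    def test_shared_environment_only_groups_match(self):
        params = BiometricParams(c=np.sqrt(0.43), e=np.sqrt(0.57))
        study = simulate_univariate_twin_sample(params, 30000, 30000, seed=8)
        assert _cross_twin_cov(study, "MZ") == pytest.approx(
            _cross_twin_cov(study, "DZ"), abs=0.02
        )

    def test_seed_determinism(self):
        params = BiometricParams(a=0.7, e=0.7, s=0.1)
        a = simulate_univariate_twin_sample(params, 50, 60, seed=123)
        b = simulate_univariate_twin_sample(params, 50, 60, seed=123)
        assert np.array_equal(a.mz.phenotypes, b.mz.phenotypes)
        assert np.array_equal(a.dz.phenotypes, b.dz.phenotypes)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(c=0.5, d=0.5, e=0.5), dict(a=0.5, s=1.0), dict(a=0.5, s=-1.2)],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BiometricParams(**kwargs)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            simulate_univariate_twin_sample(BiometricParams(a=1.0), 0, 10, seed=0)


class TestSymptomRatings:
    def test_general_factor_cross_twin_correlation(self):
        # closed form: cross-twin correlation of a unit-variance latent factor
        # is r_A*a^2 + c^2
        cfg = default_generative_config(seed=4)
        cfg.n_mz = cfg.n_dz = 50000
        _, latents = simulate_symptom_ratings(cfg, return_latent=True)
        for zyg, expected in (("MZ", 0.41 + 0.13), ("DZ", 0.5 * 0.41 + 0.13)):
            F = latents[zyg][:, :, 0]  # general factor
            r = np.corrcoef(F[:, 0], F[:, 1])[0, 1]
            assert r == pytest.approx(expected / (0.41 + 0.13 + 0.46), abs=0.015)

    def test_ratings_are_integers_in_range(self):
        cfg = default_generative_config(seed=1)
        cfg.n_mz = cfg.n_dz = 300
        study = simulate_symptom_ratings(cfg)
        y = study.mz.phenotypes
        assert np.array_equal(y, np.round(y))
        assert y.min() >= 0 and y.max() <= 4

    def test_extreme_thresholds_single_category(self):
        cfg = default_generative_config(seed=2)
        cfg.n_mz = cfg.n_dz = 100
        cfg.thresholds = np.array([50.0, 51.0, 52.0, 53.0])
        study = simulate_symptom_ratings(cfg)
        assert (study.mz.phenotypes == 0).all() and (study.dz.phenotypes == 0).all()

    def test_raising_thresholds_never_increases_mean_rating(self):
        base = default_generative_config(seed=6)
        base.n_mz = base.n_dz = 2000
        lower = simulate_symptom_ratings(base)
        raised = default_generative_config(seed=6)
        raised.n_mz = raised.n_dz = 2000
        raised.thresholds = base.thresholds + 0.5
        higher = simulate_symptom_ratings(raised)
        assert higher.mz.phenotypes.mean() <= lower.mz.phenotypes.mean()
        assert higher.dz.phenotypes.mean() <= lower.dz.phenotypes.mean()

    def test_zero_loadings_give_independent_items(self):
        cfg = default_generative_config(seed=9)
        cfg.n_mz = cfg.n_dz = 5000
        cfg.loadings = np.zeros((8, 3))
        cfg.residual_variances = np.ones(8)
        cfg.discretize = False
        study = simulate_symptom_ratings(cfg)
        X = study.children_frame()[list(cfg.spec.items)].to_numpy()
        R = np.corrcoef(X, rowvar=False)
        off = R[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_non_increasing_thresholds_rejected(self):
        cfg = default_generative_config(seed=0)
        with pytest.raises(ValueError):
            GenerativeConfig(
                biometric=cfg.biometric, thresholds=np.array([1.0, 0.5, 2.0, 3.0])
            )


class TestRegressionDataset:
    def test_zero_coefficients_zero_r2(self):
        df = simulate_regression_dataset(np.zeros(3), 20000, seed=0)
        for f in ("general", "irritability", "defiant"):
            assert abs(np.corrcoef(df[f], df["outcome"])[0, 1]) < 0.02

    def test_population_r2_matches_sum_of_squares(self):
        beta = np.array([0.28, -0.07, 0.53])
        df = simulate_regression_dataset(beta, 100000, seed=1)
        assert df["outcome"].var(ddof=0) == pytest.approx(1.0, abs=0.02)
        yhat = df[["general", "irritability", "defiant"]].to_numpy() @ beta
        r2 = np.corrcoef(yhat, df["outcome"])[0, 1] ** 2
        assert r2 == pytest.approx(float(beta @ beta), abs=0.01)

    def test_excess_coefficients_rejected(self):
        with pytest.raises(ValueError):
            simulate_regression_dataset(np.array([0.9, 0.5, 0.5]), 10, seed=0)


class TestStudyAndIO:
    def test_csv_round_trip(self, tmp_path):
        cfg = default_generative_config(seed=11)
        cfg.n_mz, cfg.n_dz = 40, 50
        study = simulate_study(cfg)
        path = tmp_path / "twins.csv"
        write_twin_csv(study, path)
        back = read_twin_csv(path)
        assert back.variables == study.variables
        assert np.allclose(back.mz.phenotypes, study.mz.phenotypes)
        assert np.allclose(back.dz.phenotypes, study.dz.phenotypes)
        assert np.allclose(back.dz.age, study.dz.age)

    def test_same_sex_pairs_and_age_range(self):
        study = simulate_univariate_twin_sample(BiometricParams(a=1.0), 100, 100, seed=2)
        for g in study.groups:
            assert set(np.unique(g.sex)) <= {0.0, 1.0}
            assert g.age.min() >= 6.0 and g.age.max() <= 18.0

    def test_missing_values_rejected(self):
        from twinfactor import TwinSample

        phen = np.ones((5, 2, 1))
        phen[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            TwinSample("MZ", phen, ["x"])
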