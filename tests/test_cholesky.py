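"""Multivariate Cholesky: covariance algebra, recovery, order swap, ladder."""

import dataclasses

import numpy as np
import pytest

from twinfactor import (
    CholeskyParams,
    CholeskySpec,
    compare_cholesky_models,
    example_cholesky_truth,
    expected_covariance_mv,
    fit_cholesky,
    reorder_and_refit,
    simulate_multivariate_twin_sample,
)
from twinfactor.cholesky import ZYGOSITY_RA, _hessian_identified

VARS = ("general", "defiant", "irritability", "external")


def naive_expected_covariance_mv(params: CholeskyParams, zygosity: str) -> np.ndarray:
    """Outer-product oracle: expand every latent factor into an explicit
    2p-dimensional loading column and sum the outer products."""
    r_a = ZYGOSITY_RA[zygosity]
    p = params.p
    cols = []
    for k in range(p):
        la = params.L_A[:, k]
        shared = np.concatenate([la, la]) * np.sqrt(r_a)
        u1 = np.concatenate([la, np.zeros(p)]) * np.sqrt(1 - r_a)
        u2 = np.concatenate([np.zeros(p), la]) * np.sqrt(1 - r_a)
        cols += [shared, u1, u2]
        lc = params.L_C[:, k]
        cols.append(np.concatenate([lc, lc]))
        le = params.L_E[:, k]
        cols.append(np.concatenate([le, np.zeros(p)]))
        cols.append(np.concatenate([np.zeros(p), le]))
    Sigma = sum(np.outer(v, v) for v in cols)
    if params.s:
        B = np.zeros((2 * p, 2 * p))
        B[p - 1, 2 * p - 1] = B[2 * p - 1, p - 1] = params.s
        M = np.linalg.inv(np.eye(2 * p) - B)
        Sigma = M @ Sigma @ M.T
    return Sigma


class TestExpectedCovariance:
    def test_identity_genetic_loadings(self):
        params = CholeskyParams(L_A=np.eye(4), L_C=np.zeros((4, 4)), L_E=np.zeros((4, 4)))
        mz = expected_covariance_mv(params, "MZ")
        assert np.allclose(mz, np.block([[np.eye(4), np.eye(4)], [np.eye(4), np.eye(4)]]))
        dz = expected_covariance_mv(params, "DZ")
        assert np.allclose(dz[:4, 4:], 0.5 * np.eye(4))

    def test_single_column_gives_unit_genetic_correlations(self):
        L_A = np.zeros((4, 4))
        L_A[:, 0] = [0.5, 0.6, 0.7, 0.8]
        params = CholeskyParams(L_A=L_A, L_C=np.zeros((4, 4)), L_E=np.zeros((4, 4)))
        SigA = params.component_covariances()["A"]
        d = np.sqrt(np.diag(SigA))
        corr = SigA / np.outer(d, d)
        assert np.allclose(corr, 1.0)

    @pytest.mark.parametrize("zyg", ["MZ", "DZ"])
    @pytest.mark.parametrize("p,s", [(3, 0.0), (4, 0.0), (4, -0.12), (3, 0.3)])
    def test_matches_outer_product_oracle(self, zyg, p, s):
        rng = np.random.default_rng(p * 10 + int(s * 100) + (zyg == "DZ"))
        mk = lambda: np.tril(rng.normal(0, 0.5, (p, p)))
        params = CholeskyParams(L_A=mk(), L_C=mk(), L_E=mk(), s=s)
        got = expected_covariance_mv(params, zyg)
        want = naive_expected_covariance_mv(params, zyg)
        assert np.allclose(got, want, atol=1e-12)
        assert np.allclose(got, got.T, atol=1e-12)
        assert np.linalg.eigvalsh(got).min() >= -1e-12

    def test_non_lower_triangular_rejected(self):
        with pytest.raises(ValueError):
            CholeskyParams(L_A=np.ones((4, 4)), L_C=np.zeros((4, 4)), L_E=np.zeros((4, 4)))


class TestFit:
    def test_recovery_of_known_shares(self):
        truth = example_cholesky_truth()
        study = simulate_multivariate_twin_sample(truth, 8000, 8000, seed=20, variables=VARS)
        fit = fit_cholesky(study, CholeskySpec(variables=VARS, c_pattern="none"))
        assert fit.status == "ok"
        a = fit.decomposition.shares.loc["A"]
        assert a["via_general"] == pytest.approx(0.20, abs=0.05)
        assert a["via_defiant"] == pytest.approx(0.16, abs=0.05)
        assert a["residual"] == pytest.approx(0.41, abs=0.05)
        # all-component shares account for the full variance
        assert fit.decomposition.shares.to_numpy().sum() == pytest.approx(1.0, abs=1e-6)
        assert fit.fitstats.df == 68  # 88 observed statistics - 20 loadings

    def test_independent_external_has_no_common_shares(self):
        L_A = np.diag([0.7, 0.7, 0.7, 0.7])
        L_E = np.diag([np.sqrt(1 - 0.49)] * 4)
        truth = CholeskyParams(L_A=L_A, L_C=np.zeros((4, 4)), L_E=L_E)
        study = simulate_multivariate_twin_sample(truth, 5000, 5000, seed=21, variables=VARS)
        fit = fit_cholesky(study, CholeskySpec(variables=VARS, c_pattern="none"))
        shares = fit.decomposition.shares
        common = shares[["via_general", "via_defiant", "via_irritability"]].to_numpy()
        assert np.abs(common).max() < 0.02

    def test_order_swap_preserves_totals(self):
        truth = example_cholesky_truth()
        study = simulate_multivariate_twin_sample(truth, 5000, 5000, seed=22, variables=VARS)
        rep = reorder_and_refit(study, CholeskySpec(variables=VARS, c_pattern="none"))
        assert rep.fit.status == "ok" and rep.fit_swapped.status == "ok"
        assert rep.max_total_discrepancy() < 1e-6
        # defiant (not irritability) carries the unique genetic overlap
        assert rep.unique_shares.loc["A", "defiant third"] > 0.08
        assert rep.unique_shares.loc["A", "irritability third"] < 0.03


class TestIdentification:
    def test_flat_direction_detected(self):
        flat = lambda x: (x[0] - 1.0) ** 2  # x[1] unidentified
        assert not _hessian_identified(flat, np.array([1.0, 0.5]))

    def test_curved_objective_identified(self):
        bowl = lambda x: (x[0] - 1.0) ** 2 + 2.0 * (x[1] + 0.5) ** 2
        assert _hessian_identified(bowl, np.array([1.0, -0.5]))


@pytest.fixture(scope="module")
def ladder_table():
    # strong general-factor structure, no shared environment
    truth = example_cholesky_truth()
    study = simulate_multivariate_twin_sample(truth, 4000, 4000, seed=23, variables=VARS)
    return compare_cholesky_models(study, VARS)


class TestLadder:
    def test_no_general_restriction_fits_dramatically_worse(self, ladder_table):
        table = ladder_table
        ok = table[table["status"] == "ok"]
        worst = table.loc["no_general_on_specifics"]
        rest = ok.drop("no_general_on_specifics", errors="ignore")
        assert worst["chi2"] > rest["chi2"].max() + 100

    def test_c_free_models_equivalent_without_c(self, ladder_table):
        table = ladder_table
        d_chi2 = table.loc["c_general_only", "chi2"] - table.loc["no_c", "chi2"]
        assert abs(d_chi2) < 5.0
        assert table.loc["no_c", "best_bic"]

    def test_df_ladder_matches_parameter_counts(self, ladder_table):
        table = ladder_table
        assert table.loc["full", "df"] == 58
        assert table.loc["c_general_only", "df"] == 67
        assert table.loc["no_c", "df"] == 68
        assert table.loc["no_general_on_specifics", "df"] == 72
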