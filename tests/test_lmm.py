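"""REML engine: closed-form oracles, grid-search agreement, BLUP prediction."""

import numpy as np
import pandas as pd
import pytest

from hybridgp.lmm import (ar1_matrix, ScaledKernel, IIDResidual,
                          KnownDiagonalResidual, GridAR1Residual, RandomTerm,
                          MixedModel, compare_aic, predict_random)


def reml_loglik_direct(y, X, V):
    """Independent textbook REML log-likelihood (dense, no factor reuse)."""
    n, p = len(y), X.shape[1]
    Vi = np.linalg.inv(V)
    W = X.T @ Vi @ X
    beta = np.linalg.solve(W, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * ((n - p) * np.log(2 * np.pi) + np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(W)[1] + r @ Vi @ r)


class TestAr1Matrix:
    def test_zero_rho_is_identity(self):
        assert np.allclose(ar1_matrix(4, 0.0), np.eye(4))

    def test_direct_formula(self):
        want = [[1, .5, .25], [.5, 1, .5], [.25, .5, 1]]
        assert np.allclose(ar1_matrix(3, 0.5), want)

    def test_inverse_is_tridiagonal(self):
        Si = np.linalg.inv(ar1_matrix(8, 0.7))
        off = np.triu(np.abs(Si), k=2)
        assert np.all(off < 1e-10)

    def test_positive_definite(self):
        for rho in (-0.9, -0.3, 0.6, 0.95):
            assert np.linalg.eigvalsh(ar1_matrix(6, rho)).min() > 0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            ar1_matrix(3, 1.0)


def _oneway(y_groups):
    y = np.concatenate(y_groups)
    n_g = len(y_groups)
    X = np.ones((len(y), 1))
    Z = np.zeros((len(y), n_g))
    k = 0
    for g, grp in enumerate(y_groups):
        Z[k:k + len(grp), g] = 1.0
        k += len(grp)
    term = RandomTerm("grp", Z, ScaledKernel(np.eye(n_g)))
    return MixedModel(y, X, ["mu"], [term], IIDResidual(len(y)))


class TestFit:
    def test_balanced_oneway_matches_anova(self):
        # groups A:(1,2) B:(3,5) C:(9,11); MSW = 1.5, MSB = 2*var(group means)
        fit = _oneway([[1, 2], [3, 5], [9, 11]]).fit()
        msb = 2 * np.var([1.5, 4.0, 10.0], ddof=1)
        assert fit.varcomps["resid:var_e"] == pytest.approx(1.5, abs=1e-5)
        assert fit.varcomps["grp:var"] == pytest.approx((msb - 1.5) / 2, abs=1e-4)
        assert fit.converged

    def test_no_random_terms_gives_ols(self, rng):
        X = np.column_stack([np.ones(25), rng.standard_normal(25)])
        y = X @ [2.0, -1.0] + rng.standard_normal(25)
        fit = MixedModel(y, X, ["b0", "b1"], [], IIDResidual(25)).fit()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta.to_numpy(), ols, atol=1e-8)

    def test_known_diagonal_weights_give_gls(self, rng):
        # heteroscedastic toy; oracle: closed-form generalized least squares
        w = rng.uniform(0.5, 4.0, 20)
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = X @ [1.0, 0.5] + rng.standard_normal(20) * np.sqrt(w)
        fit = MixedModel(y, X, ["b0", "b1"], [],
                         KnownDiagonalResidual(w)).fit()
        Wi = np.diag(1.0 / w)
        gls = np.linalg.solve(X.T @ Wi @ X, X.T @ Wi @ y)
        assert np.allclose(fit.beta.to_numpy(), gls, atol=1e-10)
        cov = np.linalg.inv(X.T @ Wi @ X)
        assert np.allclose(fit.beta_se.to_numpy(), np.sqrt(np.diag(cov)),
                           atol=1e-10)

    def test_loglik_matches_grid_search(self):
        fit_model = _oneway([[1.2, 2.1, 0.8], [3.3, 4.0, 5.1],
                             [9.2, 10.5, 11.0], [4.4, 3.9, 5.0]])
        fit = fit_model.fit()
        y = fit_model.y
        X = fit_model.X
        Z = fit_model.terms[0].Z
        best = -np.inf
        lv_b = np.log(np.var(y))
        grid_b = np.linspace(lv_b - 8, lv_b + 4, 33)
        grid_e = np.linspace(lv_b - 8, lv_b + 4, 33)
        for _ in range(4):
            lls = np.array([[reml_loglik_direct(
                y, X, np.exp(b) * (Z @ Z.T) + np.exp(e) * np.eye(len(y)))
                for e in grid_e] for b in grid_b])
            i, j = np.unravel_index(np.argmax(lls), lls.shape)
            best = lls[i, j]
            db, de = grid_b[1] - grid_b[0], grid_e[1] - grid_e[0]
            grid_b = np.linspace(grid_b[i] - db, grid_b[i] + db, 33)
            grid_e = np.linspace(grid_e[j] - de, grid_e[j] + de, 33)
        assert fit.loglik == pytest.approx(best, abs=1e-4)

    def test_loglik_trace_monotone_and_deterministic(self):
        m1 = _oneway([[1, 2], [3, 5], [9, 11], [0, 1]])
        f1, f2 = m1.fit(), _oneway([[1, 2], [3, 5], [9, 11], [0, 1]]).fit()
        assert np.all(np.diff(f1.trace) >= -1e-10)
        assert f1.loglik == f2.loglik
        assert f1.varcomps == f2.varcomps

    def test_implied_covariance_psd_at_optimum(self, rng):
        cells = np.arange(24)
        resid = GridAR1Residual(4, 6, cells, row_ar1=True, nugget=True)
        y = rng.standard_normal(24)
        m = MixedModel(y, np.ones((24, 1)), ["mu"], [], resid)
        fit = m.fit()
        V = m._V(fit.theta)
        assert np.allclose(V, V.T, atol=1e-10)
        assert np.linalg.eigvalsh(V).min() > -1e-8

    def test_matches_henderson_mme_oracle(self, rng):
        # small two-term model; oracle: explicit mixed-model equations at
        # the fitted variance components
        n, q1, q2 = 18, 5, 6
        K1 = ar1_matrix(q1, 0.4) * 1.3
        K2 = np.eye(q2)
        Z1 = rng.integers(0, 2, (n, q1)).astype(float)
        Z2 = np.zeros((n, q2))
        Z2[np.arange(n), rng.integers(0, q2, n)] = 1.0
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n) * 2 + Z1 @ rng.standard_normal(q1)
        terms = [RandomTerm("a", Z1, ScaledKernel(K1)),
                 RandomTerm("b", Z2, ScaledKernel(K2))]
        fit = MixedModel(y, X, ["b0", "b1"], terms, IIDResidual(n)).fit()
        s2a, s2b = fit.varcomps["a:var"], fit.varcomps["b:var"]
        s2e = fit.varcomps["resid:var_e"]
        Z = np.column_stack([Z1, Z2])
        from scipy.linalg import block_diag
        G = block_diag(s2a * K1 + 1e-12 * np.eye(q1), s2b * K2 + 1e-12 * np.eye(q2))
        Ri = np.eye(n) / s2e
        C = np.block([[X.T @ Ri @ X, X.T @ Ri @ Z],
                      [Z.T @ Ri @ X, Z.T @ Ri @ Z + np.linalg.inv(G)]])
        rhs = np.concatenate([X.T @ Ri @ y, Z.T @ Ri @ y])
        sol = np.linalg.solve(C, rhs)
        assert np.allclose(fit.beta.to_numpy(), sol[:2], atol=1e-6)
        u = np.concatenate([fit.blups["a"].to_numpy(),
                            fit.blups["b"].to_numpy()])
        assert np.allclose(u, sol[2:], atol=1e-6)


class TestCompareAic:
    def _dummy(self, ll, k, names=("mu",)):
        from hybridgp.lmm.model import ModelFit
        return ModelFit(varcomps={}, fixed_varcomps=set(), loglik=ll,
                        aic=-2 * ll + 2 * k, n_vparams=k,
                        beta=pd.Series(dtype=float),
                        beta_se=pd.Series(dtype=float),
                        beta_cov=np.zeros((0, 0)), blups={}, pev={},
                        converged=True, n_iter=1, fixed_names=tuple(names))

    def test_aic_arithmetic(self):
        assert self._dummy(-10.0, 2).aic == pytest.approx(24.0)

    def test_tie_prefers_fewer_parameters(self):
        f2, f3 = self._dummy(-10, 2), self._dummy(-10, 3)
        best, order = compare_aic([f3, f2])
        assert best is f2

    def test_mixed_fixed_specs_refused(self):
        with pytest.raises(ValueError, match="not comparable"):
            compare_aic([self._dummy(-10, 2, ("mu",)),
                         self._dummy(-9, 2, ("mu", "x"))])

    def test_ar1_beats_iid_on_ar1_data(self, rng):
        # small simulation study of the AIC selection behavior
        wins = 0
        n_rows, n_cols = 5, 12
        S = np.kron(np.eye(n_rows), ar1_matrix(n_cols, 0.8))
        L = np.linalg.cholesky(S + 1e-10 * np.eye(60))
        cells = np.arange(60)
        for _ in range(20):
            y = L @ rng.standard_normal(60)
            X = np.ones((60, 1))
            f_iid = MixedModel(y, X, ["mu"], [], IIDResidual(60)).fit()
            f_ar1 = MixedModel(y, X, ["mu"], [], GridAR1Residual(
                n_rows, n_cols, cells)).fit()
            best, _ = compare_aic([f_iid, f_ar1])
            wins += best is f_ar1
        assert wins >= 16


class TestPredictRandom:
    def test_identity_kernel_predicts_zero_for_unobserved(self):
        y = np.array([1.0, 2.0, 3.0])
        Z = np.zeros((3, 5))
        Z[np.arange(3), np.arange(3)] = 1.0   # levels 3,4 unobserved
        term = RandomTerm("g", Z, ScaledKernel(np.eye(5)),
                          levels=list("abcde"))
        fit = MixedModel(y, np.ones((3, 1)), ["mu"], [term],
                         IIDResidual(3)).fit()
        pred = predict_random(fit, "g", ["d", "e"])
        assert np.allclose(pred.to_numpy(), 0.0, atol=1e-10)

    def test_duplicated_level_gets_identical_blup(self):
        y = np.array([1.0, 2.0, 5.0, 6.0])
        K = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        Z = np.array([[1, 0, 0], [1, 0, 0], [0, 0, 1], [0, 0, 1.]])
        term = RandomTerm("g", Z, ScaledKernel(K + 1e-8 * np.eye(3)),
                          levels=["a", "a_copy", "b"])
        fit = MixedModel(y, np.ones((4, 1)), ["mu"], [term],
                         IIDResidual(4)).fit()
        u = fit.blups["g"]
        assert u["a"] == pytest.approx(u["a_copy"], abs=1e-6)

    def test_conditional_expectation_oracle(self, rng):
        # 5-level kernel, 3 observed; unobserved BLUPs must equal
        # K_new,obs @ inv(K_obs,obs) @ u_obs
        A = rng.standard_normal((5, 5))
        K = A @ A.T + 5 * np.eye(5)
        Z = np.zeros((12, 5))
        Z[np.arange(12), rng.integers(0, 3, 12)] = 1.0
        y = rng.standard_normal(12) + Z[:, :3] @ rng.standard_normal(3)
        term = RandomTerm("g", Z, ScaledKernel(K), levels=list("abcde"))
        fit = MixedModel(y, np.ones((12, 1)), ["mu"], [term],
                         IIDResidual(12)).fit()
        u = fit.blups["g"]
        want = K[3:, :3] @ np.linalg.solve(K[:3, :3], u.to_numpy()[:3])
        assert np.allclose(u.to_numpy()[3:], want, atol=1e-8)

    def test_absent_level_raises(self):
        y = np.array([1.0, 2.0, 3.0])
        term = RandomTerm("g", np.eye(3), ScaledKernel(np.eye(3)),
                          levels=list("abc"))
        fit = MixedModel(y, np.ones((3, 1)), ["mu"], [term],
                         IIDResidual(3)).fit()
        with pytest.raises(KeyError):
            predict_random(fit, "g", ["z"])
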