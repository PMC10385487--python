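"""Combining-ability models: weights, variance partition, prediction."""

import numpy as np
import pandas as pd
import pytest

from hybridgp.lmm import KnownDiagonalResidual
from hybridgp.markers import grm_vanraden, dominance_matrix
from hybridgp.simulate import simulate_stage2_response
from hybridgp.stage2 import (build_weights, fit_gca, fit_gca_sca,
                             partition_variance, predict_hybrids)


class TestBuildWeights:
    def test_unit_ses_give_identity(self):
        blues = pd.DataFrame({"se": np.ones(4)})
        R = build_weights(blues)
        assert np.allclose(R.matrix(None), np.eye(4))

    def test_doubling_se_quadruples_weight(self):
        blues = pd.DataFrame({"se": [1.0, 2.0]})
        w = build_weights(blues).weights
        assert w[1] == pytest.approx(4.0 * w[0])

    def test_missing_or_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            build_weights(pd.DataFrame({"se": [1.0, np.nan]}))
        with pytest.raises(ValueError):
            build_weights(pd.DataFrame({"se": [1.0, 0.0]}))


class TestPartitionVariance:
    def test_tuber_number_gca_row(self):
        part = partition_variance({"var_gca": 368.9, "var_delta": 341.0})
        assert part.rounded() == (0.68, None, 0.32)

    def test_total_yield_gca_sca_row(self):
        part = partition_variance({"var_gca": 7.4, "var_sca": 3.0,
                                   "var_delta": 3.6})
        a, s, d = part.rounded()
        assert (a, s, d) == (0.69, 0.14, 0.17)

    def test_pure_additive_limit(self):
        part = partition_variance({"var_gca": 5.0, "var_sca": 0.0,
                                   "var_delta": 0.0})
        assert part.rounded() == (1.0, 0.0, 0.0)

    def test_proportions_sum_to_one(self):
        part = partition_variance({"var_gca": 1.7, "var_sca": 0.9,
                                   "var_delta": 2.2})
        assert part.prop_additive + part.prop_sca + part.prop_delta \
            == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ZeroDivisionError):
            partition_variance({"var_gca": 0.0, "var_delta": 0.0})


@pytest.fixture(scope="module")
def stage2_sim(tiny_ds, tiny_kernels):
    """Responses drawn straight from the combining model (no SCA, no GxT)."""
    blues = simulate_stage2_response(
        tiny_ds["crossplan"], tiny_kernels["Gp"], tiny_kernels["Gh"], None,
        trials=["Est19", "Hee19", "Est20", "Hee20"],
        varcomps={"var_gca": 3.0, "var_gxt": 0.0, "var_delta": 0.5},
        se=0.7, seed=99)
    return blues


class TestFitGca:
    def test_zero_gxt_estimated_at_boundary(self, tiny_ds, tiny_kernels,
                                            stage2_sim):
        fit = fit_gca(stage2_sim, tiny_ds["crossplan"], tiny_kernels["Gp"],
                      tiny_kernels["Gh"])
        assert fit.var_gxt < 0.25
        assert fit.fit.converged

    def test_shared_parent_predictions_positively_correlated(self, tiny_ds,
                                                             tiny_gca):
        cp = tiny_ds["crossplan"]
        pred = predict_hybrids(tiny_gca, cp, "AVG")
        pred = pred - pred.mean()
        share, noshare = [], []
        hybrids = list(cp.index)
        parents = {h: {cp.loc[h, "parent1"], cp.loc[h, "parent2"]}
                   for h in hybrids}
        for i, hi in enumerate(hybrids):
            for hj in hybrids[i + 1:]:
                (share if parents[hi] & parents[hj] else noshare).append(
                    pred[hi] * pred[hj])
        assert np.mean(share) > np.mean(noshare)
        assert np.mean(share) > 0

    def test_ungenotyped_parent_excluded_with_warning(self, tiny_ds,
                                                      tiny_kernels,
                                                      tiny_blues):
        Gp = tiny_kernels["Gp"]
        dropped = Gp.iloc[1:, 1:]
        with pytest.warns(UserWarning, match="ungenotyped"):
            fit = fit_gca(tiny_blues.table, tiny_ds["crossplan"], dropped,
                          tiny_kernels["Gh"])
        assert fit.fit.converged


class TestFitGcaSca:
    def test_fixed_components_exact(self, tiny_ds, tiny_kernels, tiny_blues,
                                    tiny_gca):
        sf = fit_gca_sca(tiny_blues.table, tiny_ds["crossplan"],
                         tiny_kernels["Gp"], tiny_kernels["Gh"],
                         tiny_kernels["D"], tiny_gca)
        assert sf.var_gca == tiny_gca.var_gca       # machine-precision equal
        assert sf.var_gxt == tiny_gca.var_gxt
        assert sf.fixed_components == {"gca:var", "hxt:var"}

    def test_no_sca_simulated_collapses_to_gca(self, tiny_ds, tiny_kernels,
                                               stage2_sim):
        gf = fit_gca(stage2_sim, tiny_ds["crossplan"], tiny_kernels["Gp"],
                     tiny_kernels["Gh"])
        sf = fit_gca_sca(stage2_sim, tiny_ds["crossplan"], tiny_kernels["Gp"],
                         tiny_kernels["Gh"], tiny_kernels["D"], gf)
        assert sf.var_sca < 0.3
        p_g = predict_hybrids(gf, tiny_ds["crossplan"], "AVG")
        p_s = predict_hybrids(sf, tiny_ds["crossplan"], "AVG")
        assert np.corrcoef(p_g, p_s)[0, 1] > 0.98

    def test_sca_fixed_to_zero_reproduces_gca_exactly(self, tiny_ds,
                                                      tiny_kernels,
                                                      tiny_blues, tiny_gca):
        sf = fit_gca_sca(tiny_blues.table, tiny_ds["crossplan"],
                         tiny_kernels["Gp"], tiny_kernels["Gh"],
                         tiny_kernels["D"], tiny_gca, fix_sca=0.0)
        p_g = predict_hybrids(tiny_gca, tiny_ds["crossplan"], "AVG")
        p_s = predict_hybrids(sf, tiny_ds["crossplan"], "AVG")
        assert np.allclose(p_g, p_s, atol=1e-4)


class TestPredictHybrids:
    def _toy(self):
        rng = np.random.default_rng(4)
        parents = ["P1", "P2", "P3", "P4"]
        g = pd.DataFrame(rng.integers(0, 2, (4, 12)) * 2.0, index=parents,
                         columns=[f"s{j}" for j in range(12)])
        cp = pd.DataFrame({
            "hybrid_id": ["HA", "HB", "HC"],
            "parent1": ["P1", "P2", "P3"],
            "parent2": ["P2", "P3", "P4"]}).set_index("hybrid_id", drop=False)
        from hybridgp.simulate import hybrid_dosages
        Xh = hybrid_dosages(g, cp)
        Gp = grm_vanraden(g) + np.eye(4) * 0.01
        Gh = grm_vanraden(Xh) + np.eye(3) * 0.01
        blues = pd.DataFrame({
            "trial": ["T1"] * 3 + ["T2"] * 3,
            "hybrid_id": ["HA", "HB", "HC"] * 2,
            "blue": [10.0, 12.0, 9.0, 11.0, 13.5, 8.5],
            "se": [1.0, 1.2, 0.8, 1.1, 0.9, 1.0]})
        return g, cp, Gp, Gh, blues

    def test_matches_henderson_oracle(self):
        g, cp, Gp, Gh, blues = self._toy()
        fit = fit_gca(blues, cp, Gp, Gh)
        # hand-built mixed-model equations at the fitted variances
        from scipy.linalg import block_diag
        X = np.kron(np.eye(2), np.ones((3, 1)))
        Zg = np.zeros((6, 4))
        for r, h in enumerate(blues["hybrid_id"]):
            for p in (cp.loc[h, "parent1"], cp.loc[h, "parent2"]):
                Zg[r, ["P1", "P2", "P3", "P4"].index(p)] += 1
        Zt = np.kron(np.eye(2), np.eye(3))
        Zd = np.tile(np.eye(3), (2, 1))
        Z = np.column_stack([Zg, Zt, Zd])
        G = block_diag(fit.var_gca * Gp.to_numpy(),
                       fit.var_gxt * np.kron(np.eye(2), Gh.to_numpy()),
                       fit.var_delta * np.eye(3))
        G = G + 1e-10 * np.eye(G.shape[0])
        Ri = np.diag(1.0 / blues["se"].to_numpy() ** 2)
        y = blues["blue"].to_numpy()
        C = np.block([[X.T @ Ri @ X, X.T @ Ri @ Z],
                      [Z.T @ Ri @ X, Z.T @ Ri @ Z + np.linalg.inv(G)]])
        sol = np.linalg.solve(C, np.concatenate([X.T @ Ri @ y, Z.T @ Ri @ y]))
        beta, u = sol[:2], sol[2:]
        # prediction excludes the genetic residual (zero for new hybrids)
        want_T1 = beta[0] + Zg[0] @ u[:4] + u[4:10][0]
        got = predict_hybrids(fit, cp, "T1")
        assert got["HA"] == pytest.approx(want_T1, abs=1e-5)
        got_avg = predict_hybrids(fit, cp, "AVG")
        assert got_avg["HB"] == pytest.approx(Zg[1] @ u[:4], abs=1e-5)

    def test_parent_order_symmetry(self, tiny_ds, tiny_gca):
        cp = tiny_ds["crossplan"]
        swapped = cp.copy()
        swapped["parent1"], swapped["parent2"] = cp["parent2"], cp["parent1"]
        p1 = predict_hybrids(tiny_gca, cp, "AVG")
        p2 = predict_hybrids(tiny_gca, swapped, "AVG")
        assert np.allclose(p1, p2, atol=1e-12)

    def test_unknown_parent_raises(self, tiny_ds, tiny_gca):
        cp = tiny_ds["crossplan"].copy()
        cp.loc[cp.index[0], "parent1"] = "NOT_A_PARENT"
        with pytest.raises(KeyError, match="NOT_A_PARENT"):
            predict_hybrids(tiny_gca, cp, "AVG")

    def test_unknown_target_raises(self, tiny_ds, tiny_gca):
        with pytest.raises(KeyError, match="unknown prediction target"):
            predict_hybrids(tiny_gca, tiny_ds["crossplan"], "Mars2031")
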