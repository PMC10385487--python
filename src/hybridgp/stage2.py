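"""Weighted second-stage combining-ability models on first-stage BLUEs.

The GCA model regresses hybrid BLUEs on fixed trial intercepts, a single
parental GCA effect vector entering additively (g_i + g_j), an IID genetic
residual per hybrid, and a hybrid-by-trial interaction structured by
I_t (x) G_h.  The GCA+SCA model adds a specific-combining-ability term with
the dominance kernel, holding the GCA and hybrid-by-trial variances fixed
at the GCA model's estimates (a constrained two-step estimation that makes
the additive/dominance partition identifiable).  Each observation's
residual variance is fixed at its first-stage squared standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import (MixedModel, RandomTerm, ScaledKernel, KnownDiagonalResidual,
                  design_columns, ModelFit)

__all__ = ["CombiningFit", "VariancePartition", "build_weights", "fit_gca",
           "fit_gca_sca", "partition_variance", "predict_hybrids"]


def build_weights(blues: pd.DataFrame) -> KnownDiagonalResidual:
    """Known-diagonal residual: each observation fixed at its squared SE."""
    if "se" not in blues.columns or blues["se"].isna().any():
        raise ValueError("every BLUE needs a standard error")
    se = blues["se"].to_numpy(dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    return KnownDiagonalResidual(se ** 2)


@dataclass
class CombiningFit:
    """A fitted GCA or GCA+SCA model with its variance components and BLUPs."""
    model: str                      # "GCA" or "GCA+SCA"
    fit: ModelFit
    var_gca: float
    var_gxt: float
    var_sca: float | None
    var_delta: float
    trial_beta: pd.Series           # fixed trial intercepts
    gca: pd.Series                  # parental GCA BLUPs (all parents in Gp)
    sca: pd.Series | None           # hybrid SCA BLUPs (all hybrids in D)
    delta: pd.Series
    hxt: pd.Series                  # (trial, hybrid) -> BLUP
    parents: list[str]
    hybrids: list[str]
    trials: list[str]
    fixed_components: set[str]

    @property
    def mean_intercept(self) -> float:
        return float(self.trial_beta.mean())


def _prepare(blues: pd.DataFrame, crossplan: pd.DataFrame, Gp: pd.DataFrame,
             Gh: pd.DataFrame):
    cp = crossplan[["hybrid_id", "parent1", "parent2"]].reset_index(drop=True)
    data = blues.merge(cp, on="hybrid_id", how="left")
    unknown = data["parent1"].isna()
    if unknown.any():
        raise KeyError("BLUEs reference hybrids absent from the cross plan: "
                       f"{sorted(data.loc[unknown, 'hybrid_id'].unique())[:5]}")
    genotyped = set(Gp.index)
    bad = ~(data["parent1"].isin(genotyped) & data["parent2"].isin(genotyped))
    if bad.any():
        warnings.warn(f"excluding {data.loc[bad, 'hybrid_id'].nunique()} hybrids "
                      "with ungenotyped parents from the combining-ability fit")
        data = data.loc[~bad]
    missing_h = set(data["hybrid_id"]) - set(Gh.index)
    if missing_h:
        raise KeyError(f"hybrids absent from the hybrid kernel: "
                       f"{sorted(missing_h)[:5]}")
    return data.reset_index(drop=True)


def _terms(data: pd.DataFrame, Gp: pd.DataFrame, Gh: pd.DataFrame,
           fix_gca: float | None, fix_gxt: float | None):
    parents = list(Gp.index)
    hybrids = list(Gh.index)
    ppos = {p: i for i, p in enumerate(parents)}
    hpos = {h: i for i, h in enumerate(hybrids)}
    trials = sorted(data["trial"].unique())
    n = len(data)
    Zg = np.zeros((n, len(parents)))
    for r, (p1, p2) in enumerate(zip(data["parent1"], data["parent2"])):
        Zg[r, ppos[p1]] += 1.0
        Zg[r, ppos[p2]] += 1.0
    Zd = np.zeros((n, len(hybrids)))
    Zt = np.zeros((n, len(trials) * len(hybrids)))
    for r, (h, t) in enumerate(zip(data["hybrid_id"], data["trial"])):
        Zd[r, hpos[h]] = 1.0
        Zt[r, trials.index(t) * len(hybrids) + hpos[h]] = 1.0
    K_t = np.kron(np.eye(len(trials)), Gh.to_numpy())
    terms = [
        RandomTerm("gca", Zg, ScaledKernel(Gp.to_numpy(), fixed_value=fix_gca),
                   levels=parents),
        RandomTerm("hxt", Zt, ScaledKernel(K_t, fixed_value=fix_gxt),
                   levels=[(t, h) for t in trials for h in hybrids]),
        RandomTerm("delta", Zd, ScaledKernel(np.eye(len(hybrids))),
                   levels=hybrids),
    ]
    return terms, parents, hybrids, trials


def _extract(model_name, fit, parents, hybrids, trials, var_sca,
             fixed: set[str]) -> CombiningFit:
    vc = fit.varcomps
    beta = fit.beta
    tb = pd.Series({n[len("trial["):-1]: float(v)
                    for n, v in beta.items() if n.startswith("trial[")})
    return CombiningFit(
        model=model_name, fit=fit,
        var_gca=vc["gca:var"], var_gxt=vc["hxt:var"],
        var_sca=vc.get("sca:var") if var_sca else None,
        var_delta=vc["delta:var"],
        trial_beta=tb, gca=fit.blups["gca"],
        sca=fit.blups.get("sca"), delta=fit.blups["delta"],
        hxt=fit.blups["hxt"], parents=parents, hybrids=hybrids, trials=trials,
        fixed_components=fixed)


def fit_gca(blues: pd.DataFrame, crossplan: pd.DataFrame, Gp: pd.DataFrame,
            Gh: pd.DataFrame, K_hxt: np.ndarray | None = None) -> CombiningFit:
    """Fit the GCA model on stage-1 BLUEs with known residual weights."""
    data = _prepare(blues, crossplan, Gp, Gh)
    terms, parents, hybrids, trials = _terms(data, Gp, Gh, None, None)
    if K_hxt is not None:
        terms[1] = RandomTerm("hxt", terms[1].Z, ScaledKernel(K_hxt),
                              levels=terms[1].levels)
    Xt, nt = design_columns(data, "trial", coding="onehot")
    model = MixedModel(data["blue"].to_numpy(dtype=float), Xt, nt, terms,
                       build_weights(data))
    fit = model.fit()
    return _extract("GCA", fit, parents, hybrids, trials, var_sca=False,
                    fixed=set())


def fit_gca_sca(blues: pd.DataFrame, crossplan: pd.DataFrame,
                Gp: pd.DataFrame, Gh: pd.DataFrame, D: pd.DataFrame,
                gca_fit: CombiningFit,
                fix_sca: float | None = None) -> CombiningFit:
    """Fit the GCA+SCA model with GCA and G-by-T variances held fixed.

    sigma2_gca and sigma2_gxt are pinned exactly to the GCA fit's
    estimates; only the SCA and genetic-residual variances are estimated.
    """
    if not gca_fit.fit.converged:
        raise RuntimeError("GCA fit did not converge; refusing the second step")
    data = _prepare(blues, crossplan, Gp, Gh)
    missing = set(data["hybrid_id"]) - set(D.index)
    if missing:
        raise KeyError(f"dominance kernel lacks hybrids: {sorted(missing)[:5]}")
    terms, parents, hybrids, trials = _terms(
        data, Gp, Gh, fix_gca=gca_fit.var_gca, fix_gxt=gca_fit.var_gxt)
    D_al = D.loc[hybrids, hybrids] if list(D.index) != hybrids else D
    Zs = terms[2].Z.copy()  # same hybrid incidence as delta
    terms.insert(2, RandomTerm("sca", Zs,
                               ScaledKernel(D_al.to_numpy(), fixed_value=fix_sca),
                               levels=hybrids))
    Xt, nt = design_columns(data, "trial", coding="onehot")
    model = MixedModel(data["blue"].to_numpy(dtype=float), Xt, nt, terms,
                       build_weights(data))
    fit = model.fit()
    return _extract("GCA+SCA", fit, parents, hybrids, trials, var_sca=True,
                    fixed={"gca:var", "hxt:var"})


@dataclass
class VariancePartition:
    """Shares of total genetic variance sigma2_G = 2*Vgca + Vsca + Vdelta."""
    model: str
    prop_additive: float
    prop_sca: float | None
    prop_delta: float

    def rounded(self, ndigits: int = 2) -> tuple:
        r = lambda v: None if v is None else round(v, ndigits)
        return (r(self.prop_additive), r(self.prop_sca), r(self.prop_delta))


def partition_variance(fit) -> VariancePartition:
    """Genetic-variance partition with the scalar 2*Vgca bookkeeping.

    ``fit`` may be a :class:`CombiningFit` or any mapping with keys
    ``var_gca``, ``var_delta`` and optionally ``var_sca`` (absent or None
    for a GCA-only model).
    """
    if isinstance(fit, CombiningFit):
        vg, vs, vd = fit.var_gca, fit.var_sca, fit.var_delta
        model = fit.model
    else:
        vg = float(fit["var_gca"])
        vd = float(fit["var_delta"])
        vs = fit.get("var_sca")
        vs = None if vs is None else float(vs)
        model = "GCA" if vs is None else "GCA+SCA"
    total = 2.0 * vg + (vs or 0.0) + vd
    if total <= 0:
        raise ZeroDivisionError("total genetic variance is zero; "
                                "partition undefined")
    return VariancePartition(
        model=model,
        prop_additive=2.0 * vg / total,
        prop_sca=None if vs is None else vs / total,
        prop_delta=vd / total)


def predict_hybrids(fit: CombiningFit, crossplan: pd.DataFrame,
                    target: str) -> pd.Series:
    """Predicted hybrid values for the AVG or a per-trial target.

    AVG: g_i + g_j (+ s_ij).  Trial f: beta_f + g_i + g_j (+ s_ij) + t_f,ij.
    Parents or hybrids never seen in training are predicted through the
    genomic kernels (kernel-conditional BLUPs).
    """
    cp = crossplan.set_index("hybrid_id") if crossplan.index.name != "hybrid_id" \
        else crossplan
    unknown = sorted((set(cp["parent1"]) | set(cp["parent2"])) - set(fit.parents))
    if unknown:
        raise KeyError(f"parents absent from the GCA kernel: {unknown[:5]}")
    g = fit.gca
    pred = (g.loc[cp["parent1"]].to_numpy() + g.loc[cp["parent2"]].to_numpy())
    out = pd.Series(pred, index=cp.index.copy())
    if fit.sca is not None:
        missing = sorted(set(cp.index) - set(fit.sca.index))
        if missing:
            raise KeyError(f"hybrids absent from the SCA kernel: {missing[:5]}")
        out = out + fit.sca.loc[cp.index].to_numpy()
    if target == "AVG":
        return out
    if target not in fit.trials:
        raise KeyError(f"unknown prediction target {target!r}; "
                       f"expected 'AVG' or one of {fit.trials}")
    missing = sorted(set(cp.index) - set(fit.hybrids))
    if missing:
        raise KeyError(f"hybrids absent from the G-by-T kernel: {missing[:5]}")
    t = fit.hxt.loc[[(target, h) for h in cp.index]].to_numpy()
    return out + float(fit.trial_beta[target]) + t
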