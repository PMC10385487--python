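"""Raw-data multi-trial model: unstructured hybrid-by-location covariance.

Plot phenotypes from all trials are modeled jointly with fixed trial
intercepts, fixed blocks nested in trials, a random hybrid-by-location
term whose covariance across the two locations is unstructured (separate
genetic variance per location plus their covariance), and an IID residual.
The across-trial hybrid BLUPs from this fit define the average-performance
(AVG) prediction target, and the variance components yield per-location
broad-sense heritabilities and coefficients of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import (MixedModel, RandomTerm, UnstructuredKron, IIDResidual,
                  design_columns, ModelFit)

__all__ = ["MultiTrialFit", "fit_multitrial", "heritability",
           "coefficients_of_variation", "avg_targets"]


@dataclass
class MultiTrialFit:
    """Variance components, means and hybrid BLUPs of the multi-trial model."""
    fit: ModelFit
    locations: list[str]
    hybrids: list[str]
    sigma_a: pd.DataFrame         # unstructured location covariance
    sigma_e2: float
    loc_means: pd.Series          # observed plot mean per location
    grand_mean: float
    blups: pd.DataFrame           # hybrid x location BLUPs
    avg_blup: pd.Series           # per-hybrid mean across locations
    intercept: float              # mean fixed trial intercept


def fit_multitrial(plots: pd.DataFrame, trait: str) -> MultiTrialFit:
    """Fit the multi-trial model on raw plot data (requires >= 2 locations)."""
    locs = sorted(plots["location"].unique())
    if len(locs) < 2:
        raise ValueError("multi-trial model needs >= 2 locations; "
                         "use the single-trial path instead")
    data = plots.reset_index(drop=True)
    y = data[trait].to_numpy(dtype=float)
    Xt, nt = design_columns(data, "trial", coding="onehot")
    Xb, nb = design_columns(data, "block", coding="sum", nested_in="trial")
    X = np.column_stack([Xt, Xb])
    hybrids = sorted(data["hybrid_id"].unique())
    n_h = len(hybrids)
    hpos = {h: i for i, h in enumerate(hybrids)}
    lpos = {l: i for i, l in enumerate(locs)}
    # levels ordered location-major to match UnstructuredKron
    Z = np.zeros((len(data), len(locs) * n_h))
    for r, (h, l) in enumerate(zip(data["hybrid_id"], data["location"])):
        Z[r, lpos[l] * n_h + hpos[h]] = 1.0
    levels = [(l, h) for l in locs for h in hybrids]
    term = RandomTerm("hybrid_loc", Z,
                      UnstructuredKron(len(locs), n_h, group_names=locs),
                      levels=levels)
    fit = MixedModel(y, X, nt + nb, [term], IIDResidual(len(data))).fit()
    vc = fit.varcomps
    S = pd.DataFrame(np.zeros((len(locs), len(locs))), index=locs, columns=locs)
    for i, li in enumerate(locs):
        S.loc[li, li] = vc[f"hybrid_loc:var_{li}"]
        for lj in locs[i + 1:]:
            S.loc[li, lj] = S.loc[lj, li] = vc[f"hybrid_loc:cov_{li}_{lj}"]
    u = fit.blups["hybrid_loc"]
    blups = pd.DataFrame({l: [u[(l, h)] for h in hybrids] for l in locs},
                         index=pd.Index(hybrids, name="hybrid_id"))
    trial_beta = fit.beta[[n for n in fit.beta.index
                           if n.startswith("trial[") and ":" not in n]]
    return MultiTrialFit(
        fit=fit, locations=locs, hybrids=hybrids, sigma_a=S,
        sigma_e2=vc["resid:var_e"],
        loc_means=data.groupby("location")[trait].mean(),
        grand_mean=float(data[trait].mean()),
        blups=blups, avg_blup=blups.mean(axis=1),
        intercept=float(trial_beta.mean()))


def heritability(mfit: MultiTrialFit, location: str) -> float:
    """Broad-sense heritability H2 = var_a(loc) / (var_a(loc) + var_e)."""
    if location not in mfit.locations:
        raise KeyError(f"unknown location {location!r}")
    va = float(mfit.sigma_a.loc[location, location])
    tot = va + mfit.sigma_e2
    if tot <= 0:
        raise ZeroDivisionError("total variance is zero; H2 undefined")
    return va / tot


def coefficients_of_variation(mfit: MultiTrialFit) -> tuple[pd.Series, float]:
    """(CVG per location, CVe), both in percent.

    CVG(loc) = 100 * sd_a(loc) / location mean; CVe = 100 * sd_e / grand mean.
    """
    if (mfit.loc_means <= 0).any() or mfit.grand_mean <= 0:
        raise ValueError("coefficients of variation need positive means")
    cvg = pd.Series({l: 100.0 * np.sqrt(mfit.sigma_a.loc[l, l]) / mfit.loc_means[l]
                     for l in mfit.locations})
    cve = 100.0 * np.sqrt(mfit.sigma_e2) / mfit.grand_mean
    return cvg, float(cve)


def avg_targets(mfit: MultiTrialFit) -> pd.Series:
    """AVG prediction target: mean trial intercept + across-location BLUP."""
    return mfit.intercept + mfit.avg_blup
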