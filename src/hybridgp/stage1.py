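"""Per-trial spatial analysis: model ladder, AIC selection, hybrid BLUEs.

Each trial/trait combination is fit with eight candidate models: two base
mean structures (fixed hybrid + fixed block, optionally plus a random
column effect) crossed with four residual structures (IID; AR1 along
columns; AR1 columns + nugget; AR1 rows x AR1 columns + nugget).  The
minimum-AIC converged model supplies the hybrid BLUEs and standard errors
that the second-stage genomic models consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import (MixedModel, RandomTerm, ScaledKernel, IIDResidual,
                  GridAR1Residual, compare_aic, design_columns, ModelFit)

__all__ = ["LADDER", "ladder_label", "fit_ladder", "select_and_extract",
           "trial_residuals", "semivariogram", "run_stage1"]

# (base, residual) codes: base 1 = fixed hybrid+block, base 2 = + random column;
# residual 3 = IID, 4 = AR1 cols, 5 = AR1 cols + nugget, 6 = AR1 rows x cols + nugget
LADDER: tuple[tuple[int, int], ...] = tuple(
    (b, r) for b in (1, 2) for r in (3, 4, 5, 6))


def ladder_label(entry: tuple[int, int]) -> str:
    return f"({entry[0]}) + ({entry[1]})"


def _build(sub: pd.DataFrame, trait: str, base: int, resid: int):
    y = sub[trait].to_numpy(dtype=float)
    Xh, nh = design_columns(sub, "hybrid_id", coding="onehot")
    Xb, nb = design_columns(sub, "block", coding="sum")
    X = np.column_stack([Xh, Xb])
    names = nh + nb
    terms = []
    n_rows = int(sub["row"].max())
    n_cols = int(sub["col"].max())
    if base == 2:
        cols = sorted(sub["col"].unique())
        Z = (sub["col"].to_numpy()[:, None] == np.array(cols)[None, :]).astype(float)
        terms.append(RandomTerm("column", Z, ScaledKernel(np.eye(len(cols))),
                                levels=cols))
    cells = ((sub["row"].to_numpy() - 1) * n_cols + (sub["col"].to_numpy() - 1))
    if resid == 3:
        residual = IIDResidual(len(sub))
    elif resid == 4:
        residual = GridAR1Residual(n_rows, n_cols, cells, row_ar1=False, nugget=False)
    elif resid == 5:
        residual = GridAR1Residual(n_rows, n_cols, cells, row_ar1=False, nugget=True)
    elif resid == 6:
        residual = GridAR1Residual(n_rows, n_cols, cells, row_ar1=True, nugget=True)
    else:
        raise ValueError(f"unknown residual code {resid}")
    return MixedModel(y, X, names, terms, residual)


def fit_ladder(plots: pd.DataFrame, trial: str, trait: str,
               entries: tuple[tuple[int, int], ...] = LADDER,
               ) -> dict[tuple[int, int], ModelFit]:
    """Fit every ladder entry for one trial/trait; failures are recorded as None."""
    sub = plots.loc[plots["trial"] == trial].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no plots for trial {trial!r}")
    for col in ("row", "col", "block", "hybrid_id"):
        if col not in sub.columns:
            raise ValueError(f"plot table lacks required column {col!r}")
    fits: dict[tuple[int, int], ModelFit | None] = {}
    for entry in entries:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits[entry] = _build(sub, trait, *entry).fit()
        except Exception as e:  # noqa: BLE001 - a failed entry must not kill the ladder
            warnings.warn(f"ladder entry {ladder_label(entry)} failed for "
                          f"{trial}/{trait}: {e}")
            fits[entry] = None
    if all(f is None for f in fits.values()):
        raise RuntimeError(f"all spatial models failed for {trial}/{trait}")
    return fits


@dataclass
class BlueTable:
    """Hybrid BLUEs with standard errors from the selected spatial model."""
    table: pd.DataFrame           # columns: trial, hybrid_id, blue, se, model
    selected: dict[str, str]      # trial -> model label


def select_and_extract(fits: dict[tuple[int, int], ModelFit], trial: str,
                       ) -> pd.DataFrame:
    """AIC-select among converged ladder fits and extract hybrid BLUEs/SEs."""
    usable = {e: f for e, f in fits.items() if f is not None and f.converged}
    if not usable:
        raise RuntimeError(f"no converged spatial model for trial {trial!r}")
    best, _ = compare_aic(list(usable.values()))
    entry = next(e for e, f in usable.items() if f is best)
    rows = []
    for name, est in best.beta.items():
        if name.startswith("hybrid_id["):
            hybrid = name[len("hybrid_id["):-1]
            rows.append({"trial": trial, "hybrid_id": hybrid,
                         "blue": float(est), "se": float(best.beta_se[name]),
                         "model": ladder_label(entry)})
    out = pd.DataFrame(rows)
    if (out["se"] <= 0).any():
        raise RuntimeError(f"non-positive BLUE standard error in trial {trial!r}")
    return out


def trial_residuals(plots: pd.DataFrame, trial: str, trait: str,
                    entry: tuple[int, int], fit: ModelFit) -> pd.DataFrame:
    """Conditional residuals y - X b - Z u of a ladder fit, with coordinates."""
    sub = plots.loc[plots["trial"] == trial].reset_index(drop=True)
    model = _build(sub, trait, *entry)
    yhat = model.X @ fit.beta.to_numpy()
    for term in model.terms:
        yhat = yhat + term.Z @ fit.blups[term.name].to_numpy()
    return pd.DataFrame({"row": sub["row"], "col": sub["col"],
                         "resid": model.y - yhat})


def semivariogram(residuals: np.ndarray, coords: np.ndarray,
                  max_lag: int = 10) -> pd.DataFrame:
    """Empirical semivariogram gamma(h) = mean[(r_i - r_j)^2] / 2 by lag bin.

    Pairs are binned by Euclidean plot distance rounded to the nearest
    integer lag; empty bins are reported with count 0.
    """
    r = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    sq = 0.5 * (r[:, None] - r[None, :]) ** 2
    iu = np.triu_indices(len(r), k=1)
    d, sq = d[iu], sq[iu]
    lag_bin = np.rint(d).astype(int)
    rows = []
    for h in range(1, max_lag + 1):
        m = lag_bin == h
        n_pairs = int(m.sum())
        rows.append({"lag": h, "semivariance":
                     float(sq[m].mean()) if n_pairs else np.nan,
                     "n_pairs": n_pairs})
    return pd.DataFrame(rows)


def run_stage1(plots: pd.DataFrame, traits: list[str]) -> dict[str, BlueTable]:
    """Ladder + selection for every trial and trait; one BlueTable per trait."""
    out: dict[str, BlueTable] = {}
    for trait in traits:
        pieces, selected = [], {}
        for trial in sorted(plots["trial"].unique()):
            fits = fit_ladder(plots, trial, trait)
            tab = select_and_extract(fits, trial)
            selected[trial] = tab["model"].iloc[0]
            pieces.append(tab)
        out[trait] = BlueTable(table=pd.concat(pieces, ignore_index=True),
                               selected=selected)
    return out
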