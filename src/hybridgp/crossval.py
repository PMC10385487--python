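"""Evaluated-parent cross-validation of the combining-ability models.

Parents are randomly split into an evaluated and an unevaluated set; each
hybrid then lands in the training set (both parents evaluated), the 1EP
test set (one parent evaluated) or the 0EP test set (no parent evaluated).
Second-stage models are refit on training hybrids only and scored on both
test sets against per-trial BLUEs and the across-trial AVG target, with
Pearson accuracy and trait-mean-scaled RMSE; repetitions are summarized by
medians.  Both genetic models are scored on identical splits within a
repetition, so their comparison is paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stage2 import fit_gca, fit_gca_sca, predict_hybrids, CombiningFit

__all__ = ["ParentSplit", "split_hybrids", "accuracy", "scaled_rmse",
           "CVBundle", "run_crossval"]


@dataclass
class ParentSplit:
    """One random assignment of parents to evaluated/unevaluated sets."""
    evaluated: set[str]
    unevaluated: set[str]
    train: list[str]     # hybrids with two evaluated parents
    one_ep: list[str]
    zero_ep: list[str]
    seed: int


def split_hybrids(crossplan: pd.DataFrame, seed: int,
                  evaluated_fraction: float = 0.5) -> ParentSplit:
    """Assign parents Bernoulli(evaluated_fraction); classify hybrids by the
    number of evaluated parents (2 -> training, 1 -> 1EP, 0 -> 0EP)."""
    if crossplan.empty:
        raise ValueError("empty cross plan")
    parents = sorted(set(crossplan["parent1"]) | set(crossplan["parent2"]))
    rng = np.random.default_rng(seed)
    mask = rng.random(len(parents)) < evaluated_fraction
    evaluated = {p for p, m in zip(parents, mask) if m}
    train, one_ep, zero_ep = [], [], []
    for h, p1, p2 in zip(crossplan["hybrid_id"], crossplan["parent1"],
                         crossplan["parent2"]):
        k = (p1 in evaluated) + (p2 in evaluated)
        (zero_ep, one_ep, train)[k].append(h)
    return ParentSplit(evaluated=evaluated,
                       unevaluated=set(parents) - evaluated,
                       train=train, one_ep=one_ep, zero_ep=zero_ep, seed=seed)


def accuracy(truth, pred) -> float:
    """Pearson correlation between true and predicted values."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.size != p.size or t.size < 3:
        raise ValueError("accuracy needs >= 3 paired values")
    if np.std(t) == 0 or np.std(p) == 0:
        raise ValueError("accuracy undefined: a vector has zero variance")
    return float(np.corrcoef(t, p)[0, 1])


def scaled_rmse(truth, pred, mu: float) -> float:
    """Root mean square error scaled by the trait mean, in percent."""
    if mu <= 0:
        raise ValueError("scaled RMSE needs a positive trait mean")
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    return float(100.0 * np.sqrt(np.mean((t - p) ** 2)) / mu)


@dataclass
class CVBundle:
    """Everything one repetition needs: BLUEs, targets, kernels, cross plan."""
    blues: pd.DataFrame            # trial, hybrid_id, blue, se
    avg_target: pd.Series          # per-hybrid AVG truth (intercept included)
    crossplan: pd.DataFrame
    Gp: pd.DataFrame
    Gh: pd.DataFrame
    D: pd.DataFrame | None = None
    trait: str = "trait"
    K_hxt: np.ndarray | None = field(default=None, repr=False)


def _truth_for(bundle: CVBundle, target: str, hybrids: list[str]) -> pd.Series:
    if target == "AVG":
        t = bundle.avg_target
    else:
        sub = bundle.blues.loc[bundle.blues["trial"] == target]
        t = sub.set_index("hybrid_id")["blue"]
    return t.reindex(hybrids).dropna()


def _score_one(bundle: CVBundle, fit: CombiningFit, cp_test: pd.DataFrame,
               target: str, mu: float) -> tuple[float, float, int]:
    pred = predict_hybrids(fit, cp_test, target)
    if target == "AVG":
        pred = pred + fit.mean_intercept
    truth = _truth_for(bundle, target, list(cp_test["hybrid_id"]))
    pred = pred.reindex(truth.index)
    return (accuracy(truth, pred), scaled_rmse(truth, pred, mu), len(truth))


def run_crossval(bundle: CVBundle, n_reps: int = 100,
                 models: tuple[str, ...] = ("GCA", "GCA+SCA"),
                 targets: tuple[str, ...] = ("AVG",),
                 seed: int = 0, evaluated_fraction: float = 0.5,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat the evaluated-parent scheme; return (long results, medians).

    Degenerate repetitions (an empty training set, or a test cell too small
    to score) are resampled with a logged note; more than 10% failed
    repetitions aborts.
    """
    if "GCA+SCA" in models and bundle.D is None:
        raise ValueError("GCA+SCA requested but no dominance kernel supplied")
    ss = np.random.SeedSequence(seed)
    mus = {t: float(_truth_for(bundle, t,
                               list(bundle.crossplan["hybrid_id"])).mean())
           for t in targets}
    cp = bundle.crossplan.set_index("hybrid_id", drop=False) \
        if bundle.crossplan.index.name != "hybrid_id" else bundle.crossplan
    rows = []
    failures = 0
    rep = 0
    attempt = 0
    max_failures = max(1, int(0.1 * n_reps))
    while rep < n_reps:
        child = np.random.default_rng(ss.spawn(1)[0])
        split_seed = int(child.integers(2 ** 31))
        attempt += 1
        split = split_hybrids(cp, split_seed, evaluated_fraction)
        train_blues = bundle.blues.loc[
            bundle.blues["hybrid_id"].isin(split.train)]
        test_sets = {"1EP": split.one_ep, "0EP": split.zero_ep}
        if train_blues.empty or any(len(h) < 3 for h in test_sets.values()):
            failures += 1
            warnings.warn(f"degenerate split (seed {split_seed}); resampling")
            if failures > max_failures:
                raise RuntimeError(
                    f"more than 10% of repetitions degenerate ({failures})")
            continue
        # audit: no test hybrid's BLUE enters the training fit
        assert not (set(train_blues["hybrid_id"]) &
                    (set(split.one_ep) | set(split.zero_ep)))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits: dict[str, CombiningFit] = {}
                if "GCA" in models or "GCA+SCA" in models:
                    fits["GCA"] = fit_gca(train_blues, cp, bundle.Gp,
                                          bundle.Gh, K_hxt=bundle.K_hxt)
                if "GCA+SCA" in models:
                    fits["GCA+SCA"] = fit_gca_sca(train_blues, cp, bundle.Gp,
                                                  bundle.Gh, bundle.D,
                                                  fits["GCA"])
            for scenario, hybrids in test_sets.items():
                cp_test = cp.loc[cp["hybrid_id"].isin(hybrids)]
                for model in models:
                    for target in targets:
                        rho, rmse, n = _score_one(bundle, fits[model],
                                                  cp_test, target, mus[target])
                        rows.append({
                            "rep": rep, "scenario": scenario, "model": model,
                            "trait": bundle.trait, "target": target,
                            "accuracy": rho, "scaled_rmse": rmse, "n_test": n})
        except (ValueError, RuntimeError) as e:
            failures += 1
            warnings.warn(f"repetition failed ({e}); resampling")
            if failures > max_failures:
                raise RuntimeError(
                    f"more than 10% of repetitions failed ({failures})")
            continue
        rep += 1
    results = pd.DataFrame(rows)
    medians = (results
               .groupby(["scenario", "model", "trait", "target"])
               [["accuracy", "scaled_rmse"]].median().reset_index())
    return results, medians
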