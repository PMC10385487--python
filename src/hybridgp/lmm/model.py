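"""REML fitting of linear mixed models with structured (co)variances.

The solver maximizes the restricted likelihood with average-information (AI)
updates, step-halving, and a guaranteed-uphill gradient fallback, so the
log-likelihood is non-decreasing over iterations.  Variances are optimized on
the log scale and autocorrelations through atanh, which keeps every iterate
feasible.  Fixed-effect BLUEs and random-effect BLUPs come from the
mixed-model equations evaluated at the REML optimum; random terms may carry
kernel levels with no data (e.g. untested hybrids), whose BLUPs are then the
kernel-conditional expectations given the observed levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .structures import KernelStructure, ResidualStructure

__all__ = ["RandomTerm", "ModelFit", "MixedModel", "compare_aic",
           "predict_random", "design_columns", "NotConvergedWarning"]

_LOG2PI = np.log(2.0 * np.pi)


class NotConvergedWarning(UserWarning):
    pass


@dataclass
class RandomTerm:
    """A random-effect term: incidence onto kernel levels plus a structure.

    ``levels`` may include entries that never occur in the data; those
    columns of Z are zero and the corresponding BLUPs are predicted through
    the covariance structure.
    """

    name: str
    Z: np.ndarray              # n_obs x n_levels incidence
    structure: KernelStructure
    levels: list = field(default_factory=list)

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if not self.levels:
            self.levels = list(range(self.Z.shape[1]))
        if len(self.levels) != self.Z.shape[1]:
            raise ValueError(f"term {self.name}: levels/Z shape mismatch")


@dataclass
class ModelFit:
    """Result of a REML fit: variance components, BLUEs, BLUPs, fit indices."""

    varcomps: dict[str, float]
    fixed_varcomps: set[str]
    loglik: float
    aic: float
    n_vparams: int
    beta: pd.Series
    beta_se: pd.Series
    beta_cov: np.ndarray
    blups: dict[str, pd.Series]
    pev: dict[str, pd.Series]
    converged: bool
    n_iter: int
    fixed_names: tuple[str, ...]
    theta: np.ndarray = field(default=None, repr=False)
    trace: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        return {
            "varcomps": self.varcomps,
            "fixed_varcomps": sorted(self.fixed_varcomps),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_vparams": self.n_vparams,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "beta": {k: float(v) for k, v in self.beta.items()},
            "beta_se": {k: float(v) for k, v in self.beta_se.items()},
            "trace": [float(x) for x in self.trace],
        }


def design_columns(data: pd.DataFrame, factor: str, coding: str = "onehot",
                   nested_in: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Build design-matrix columns for a categorical factor.

    coding="onehot": one indicator column per level (no reference level).
    coding="sum":    sum-to-zero contrasts; the last level (sorted order) is
                     the implicit reference, so effects average to zero across
                     levels and one-hot effect columns of other factors read
                     directly as level means at the average of this factor.
    ``nested_in`` builds the contrasts separately within each level of an
    outer factor (e.g. blocks within trials).
    """
    if nested_in is None:
        groups = [(None, data.index)]
    else:
        groups = [(g, idx) for g, idx in data.groupby(nested_in, sort=True).groups.items()]
    n = len(data)
    cols, names = [], []
    pos = {label: i for i, label in enumerate(data.index)}
    for g, idx in groups:
        sub = data.loc[idx, factor]
        levels = sorted(sub.unique())
        prefix = f"{nested_in}[{g}]:" if nested_in is not None else ""
        if coding == "onehot":
            use = levels
        elif coding == "sum":
            use = levels[:-1]
        else:
            raise ValueError(f"unknown coding {coding!r}")
        for lev in use:
            col = np.zeros(n)
            rows = [pos[i] for i in idx]
            vals = (sub == lev).astype(float).to_numpy()
            if coding == "sum":
                vals = vals - (sub == levels[-1]).astype(float).to_numpy()
            col[rows] = vals
            cols.append(col)
            names.append(f"{prefix}{factor}[{lev}]")
    X = np.column_stack(cols) if cols else np.zeros((n, 0))
    return X, names


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop linearly dependent columns left-to-right (first occurrence wins)."""
    keep: list[int] = []
    Q: list[np.ndarray] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float).copy()
        for q in Q:
            v -= (q @ X[:, j]) * q
        nv = np.linalg.norm(v)
        if nv > 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            Q.append(v / nv)
            keep.append(j)
        else:
            warnings.warn(f"dropping aliased fixed-effect column {names[j]!r}")
    return X[:, keep], [names[j] for j in keep]


class MixedModel:
    """y = X b + sum_k Z_k u_k + e, with structured u_k and e covariances."""

    def __init__(self, y: np.ndarray, X: np.ndarray, fixed_names: list[str],
                 terms: list[RandomTerm], residual: ResidualStructure):
        self.y = np.asarray(y, dtype=float).ravel()
        n = self.y.size
        if n == 0:
            raise ValueError("empty data")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != n:
            raise ValueError("X shape incompatible with y")
        self.X, self.fixed_names = _drop_aliased(X, list(fixed_names))
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design not full rank after aliasing removal")
        self.terms = terms
        self.residual = residual
        # pre-compute Z B_j Z' for every basis matrix of every term
        self._C: list[list[np.ndarray]] = []
        for t in self.terms:
            if t.Z.shape[0] != n:
                raise ValueError(f"term {t.name}: Z row count != n_obs")
            mats = []
            for B in t.structure.bases():
                if B.shape[0] != t.Z.shape[1]:
                    raise ValueError(f"term {t.name}: kernel/Z shape mismatch")
                mats.append(t.Z @ B @ t.Z.T)
            self._C.append(mats)
        # parameter layout: [term_1 params, ..., term_K params, residual params]
        self._slices = []
        k = 0
        for t in self.terms:
            self._slices.append(slice(k, k + t.structure.n_params))
            k += t.structure.n_params
        self._res_slice = slice(k, k + residual.n_params)
        self.n_vparams = k + residual.n_params

    # -- likelihood machinery -------------------------------------------------

    def _V(self, theta):
        V = self.residual.matrix(theta[self._res_slice]).copy()
        for t, sl, Cs in zip(self.terms, self._slices, self._C):
            for cj, Cj in zip(t.structure.coefs(theta[sl]), Cs):
                if cj != 0.0:
                    V += cj * Cj
        return V

    def _dV(self, theta):
        out = []
        for t, sl, Cs in zip(self.terms, self._slices, self._C):
            dc = t.structure.dcoefs(theta[sl])
            for p in range(t.structure.n_params):
                D = np.zeros_like(Cs[0])
                for j, Cj in enumerate(Cs):
                    if dc[p, j] != 0.0:
                        D += dc[p, j] * Cj
                out.append(D)
        out.extend(self.residual.dmatrices(theta[self._res_slice]))
        return out

    def _loglik(self, theta):
        """REML log-likelihood and solve cache; -inf if V not PD."""
        V = self._V(theta)
        try:
            cV = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf, None
        except ValueError:
            return -np.inf, None
        n, p = self.y.size, self.X.shape[1]
        Vi_y = cho_solve(cV, self.y, check_finite=False)
        Vi_X = cho_solve(cV, self.X, check_finite=False)
        W = self.X.T @ Vi_X
        try:
            cW = cho_factor(W, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf, None
        Xt_Vi_y = self.X.T @ Vi_y
        beta = cho_solve(cW, Xt_Vi_y, check_finite=False)
        Py = Vi_y - Vi_X @ beta
        ldV = 2.0 * np.sum(np.log(np.diag(cV[0])))
        ldW = 2.0 * np.sum(np.log(np.diag(cW[0])))
        quad = float(self.y @ Py)
        ll = -0.5 * ((n - p) * _LOG2PI + ldV + ldW + quad)
        if not np.isfinite(ll):
            return -np.inf, None
        cache = {"cV": cV, "cW": cW, "Vi_X": Vi_X, "Py": Py, "beta": beta}
        return ll, cache

    def _score_ai(self, theta, cache):
        """REML score vector and average-information matrix."""
        dVs = self._dV(theta)
        q = len(dVs)
        cV, cW, Vi_X, Py = cache["cV"], cache["cW"], cache["Vi_X"], cache["Py"]
        Vi = cho_solve(cV, np.eye(self.y.size), check_finite=False)
        score = np.zeros(q)
        f = []
        for i, D in enumerate(dVs):
            DVi_X = D @ Vi_X
            trPD = float(np.sum(Vi * D)) - float(
                np.sum(cho_solve(cW, Vi_X.T @ DVi_X, check_finite=False).diagonal()))
            fi = D @ Py
            f.append(fi)
            score[i] = -0.5 * (trPD - float(Py @ fi))
        AI = np.zeros((q, q))
        for j in range(q):
            Vi_fj = cho_solve(cV, f[j], check_finite=False)
            Pfj = Vi_fj - Vi_X @ cho_solve(cW, Vi_X.T @ f[j], check_finite=False)
            for i in range(j + 1):
                AI[i, j] = AI[j, i] = 0.5 * float(f[i] @ Pfj)
        return score, AI

    # -- optimizer ------------------------------------------------------------

    def _init_theta(self):
        p = self.X.shape[1]
        if p and p < self.y.size:
            beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
            resid = self.y - self.X @ beta
            dof = max(self.y.size - p, 1)
            var0 = float(resid @ resid) / dof
        else:
            var0 = float(np.var(self.y))
        var0 = max(var0, 1e-8)
        slots = self.residual.n_variance_slots()
        for t in self.terms:
            slots += t.structure.n_variance_slots()
        share = var0 / max(slots, 1)
        theta = np.zeros(self.n_vparams)
        for t, sl in zip(self.terms, self._slices):
            theta[sl] = t.structure.init_params(share)
        theta[self._res_slice] = self.residual.init_params(share)
        return theta

    def fit(self, max_iter: int = 100, tol: float = 1e-8,
            pev_terms: list[str] | None = None) -> ModelFit:
        theta = self._init_theta()
        ll, cache = self._loglik(theta)
        if not np.isfinite(ll):
            raise RuntimeError("likelihood not finite at the initial point")
        trace = [ll]
        converged = self.n_vparams == 0
        it = 0
        while not converged and it < max_iter:
            it += 1
            score, AI = self._score_ai(theta, cache)
            gnorm = float(np.max(np.abs(score)))
            if gnorm < 1e-6 * (1.0 + abs(ll)):
                converged = True
                break
            # AI step, ridged for safety, with step-halving
            ridge = 1e-8 * max(1.0, float(np.trace(AI)) / max(AI.shape[0], 1))
            accepted = False
            for _ in range(3):
                try:
                    delta = np.linalg.solve(AI + ridge * np.eye(AI.shape[0]), score)
                    break
                except np.linalg.LinAlgError:
                    ridge *= 1e4
            else:
                delta = score
            dmax = float(np.max(np.abs(delta)))
            if dmax > 5.0:
                delta *= 5.0 / dmax
            step = 1.0
            for _ in range(25):
                th_new = theta + step * delta
                ll_new, cache_new = self._loglik(th_new)
                if ll_new > ll:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                # uphill gradient fallback (EM-style safeguard): scaled ascent
                g = score / max(float(np.max(np.abs(score))), 1e-12)
                step = 1.0
                for _ in range(30):
                    th_new = theta + step * g
                    ll_new, cache_new = self._loglik(th_new)
                    if ll_new > ll:
                        accepted = True
                        break
                    step *= 0.5
            if not accepted:
                # cannot improve in either direction: treat as converged
                converged = True
                break
            rel = abs(ll_new - ll) / (1.0 + abs(ll))
            theta, ll, cache = th_new, ll_new, cache_new
            trace.append(ll)
            if rel < tol:
                converged = True
        if not converged:
            warnings.warn(
                f"REML did not converge in {max_iter} iterations "
                f"(last logLik {ll:.6f})", NotConvergedWarning)
        return self._extract(theta, ll, cache, converged, it, trace, pev_terms)

    # -- extraction -----------------------------------------------------------

    def _extract(self, theta, ll, cache, converged, n_iter, trace, pev_terms):
        varcomps: dict[str, float] = {}
        fixed: set[str] = set()
        for t, sl in zip(self.terms, self._slices):
            for k, v in t.structure.param_dict(theta[sl]).items():
                key = f"{t.name}:{k}"
                varcomps[key] = v
                if t.structure.n_params == 0:
                    fixed.add(key)
        for k, v in self.residual.param_dict(theta[self._res_slice]).items():
            varcomps[f"resid:{k}"] = v
        beta = cache["beta"]
        bcov = cho_solve(cache["cW"], np.eye(self.X.shape[1]), check_finite=False)
        Py = cache["Py"]
        blups: dict[str, pd.Series] = {}
        pevs: dict[str, pd.Series] = {}
        for t, sl in zip(self.terms, self._slices):
            K = t.structure.matrix(theta[sl])
            u = K @ (t.Z.T @ Py)
            idx = pd.Index(t.levels, tupleize_cols=False)
            blups[t.name] = pd.Series(u, index=idx)
            if pev_terms and t.name in pev_terms:
                PZ = cho_solve(cache["cV"], t.Z, check_finite=False) - cache["Vi_X"] @ cho_solve(
                    cache["cW"], cache["Vi_X"].T @ t.Z, check_finite=False)
                M = t.Z.T @ PZ
                KM = K @ M
                pev = np.diag(K) - np.sum(KM * K.T, axis=1)
                pevs[t.name] = pd.Series(np.maximum(pev, 0.0), index=idx)
        aic = -2.0 * ll + 2.0 * self.n_vparams
        names = pd.Index(self.fixed_names)
        return ModelFit(
            varcomps=varcomps, fixed_varcomps=fixed, loglik=float(ll), aic=float(aic),
            n_vparams=self.n_vparams,
            beta=pd.Series(beta, index=names),
            beta_se=pd.Series(np.sqrt(np.maximum(np.diag(bcov), 0.0)), index=names),
            beta_cov=bcov, blups=blups, pev=pevs, converged=converged,
            n_iter=n_iter, fixed_names=tuple(self.fixed_names), theta=theta,
            trace=trace)

    def loglik_at(self, theta: np.ndarray) -> float:
        """REML log-likelihood at an arbitrary transformed-parameter point."""
        ll, _ = self._loglik(np.asarray(theta, dtype=float))
        return ll


def compare_aic(fits: list[ModelFit]) -> tuple[ModelFit, list[int]]:
    """Select the minimum-AIC fit; ties go to the fewer-parameter model.

    All fits must share the same fixed-effect specification (REML
    log-likelihoods are only comparable under a common fixed part).
    Returns (best fit, ranking of indices from best to worst).
    """
    if not fits:
        raise ValueError("no fits to compare")
    names0 = fits[0].fixed_names
    for f in fits[1:]:
        if f.fixed_names != names0:
            raise ValueError(
                "AIC comparison refused: fits have different fixed-effect "
                f"specifications ({f.fixed_names} vs {names0}); REML "
                "likelihoods are not comparable across fixed parts")
    order = sorted(range(len(fits)),
                   key=lambda i: (fits[i].aic, fits[i].n_vparams, i))
    return fits[order[0]], order


def predict_random(fit: ModelFit, term: str, levels) -> pd.Series:
    """BLUPs of the requested levels of a random term.

    Levels with no data carry the kernel-conditional expectation given the
    observed levels (the incidence used at fit time spans the full kernel, so
    the stored BLUP vector already realizes K_new,obs K_obs,obs^-1 u_obs).
    """
    if term not in fit.blups:
        raise KeyError(f"no random term named {term!r} in this fit")
    u = fit.blups[term]
    missing = [lv for lv in levels if lv not in u.index]
    if missing:
        raise KeyError(f"levels absent from the {term!r} kernel: {missing[:5]}")
    return u.loc[list(levels)]
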