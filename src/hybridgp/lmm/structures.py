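"""Covariance structures for the mixed-model engine.

Two families of structure are distinguished:

* :class:`KernelStructure` — covariance of a vector of random effects,
  expressed as a linear combination of fixed basis matrices,
  ``K(theta) = sum_j c_j(theta) * B_j``.  Linearity in the coefficients lets
  the solver pre-compute ``Z B_j Z'`` once per fit, which is what makes
  repeated likelihood evaluations cheap.
* :class:`ResidualStructure` — covariance of the observation-level error,
  built directly on the observed plots/records (IID, AR1 field structures
  with an optional nugget, or a known fixed diagonal).

All free parameters live in an unconstrained transformed space: variances as
``sigma2 = exp(eta)`` and autocorrelations as ``rho = tanh(psi)``, so the
optimizer never has to handle bound constraints explicitly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ar1_matrix",
    "KernelStructure",
    "ScaledKernel",
    "UnstructuredKron",
    "ResidualStructure",
    "IIDResidual",
    "KnownDiagonalResidual",
    "GridAR1Residual",
]

# bounds in transformed space; exp(+/-25) spans ~1e-11 .. 7e10
_ETA_LIM = 25.0
_PSI_LIM = 6.0


def _clip_eta(eta: float) -> float:
    return float(np.clip(eta, -_ETA_LIM, _ETA_LIM))


def ar1_matrix(n: int, rho: float) -> np.ndarray:
    """First-order autoregressive correlation matrix, entry (i, j) = rho^|i-j|.

    Parameters
    ----------
    n
        Dimension (number of field rows or columns).
    rho
        Autocorrelation, must satisfy ``|rho| < 1``.
    """
    if n < 1:
        raise ValueError(f"ar1_matrix requires n >= 1, got {n}")
    if not abs(rho) < 1:
        raise ValueError(f"ar1_matrix requires |rho| < 1, got rho={rho}")
    lag = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return np.power(float(rho), lag)


def _dar1_matrix(n: int, rho: float) -> np.ndarray:
    """Entrywise derivative of :func:`ar1_matrix` with respect to rho."""
    lag = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    base = np.ones_like(lag, dtype=float)
    np.power(float(rho), lag - 1, where=lag > 0, out=base)
    d = lag * base
    d[lag == 0] = 0.0
    if rho == 0.0:
        # rho^0 * lag on the first off-diagonal, zero beyond
        d = np.where(lag == 1, 1.0, 0.0)
    return d


class KernelStructure:
    """Covariance of a random-effect vector, linear in its coefficients."""

    n_params: int = 0

    def bases(self) -> list[np.ndarray]:
        raise NotImplementedError

    def coefs(self, theta: np.ndarray) -> np.ndarray:
        """Coefficients c_j(theta), one per basis matrix."""
        raise NotImplementedError

    def dcoefs(self, theta: np.ndarray) -> np.ndarray:
        """(n_params, n_bases) array of coefficient derivatives."""
        raise NotImplementedError

    def init_params(self, var0: float) -> np.ndarray:
        raise NotImplementedError

    def n_variance_slots(self) -> int:
        """How many shares of the initial variance split this structure claims."""
        raise NotImplementedError

    def param_dict(self, theta: np.ndarray) -> dict[str, float]:
        """Natural-scale parameter values for reporting."""
        raise NotImplementedError

    def matrix(self, theta: np.ndarray) -> np.ndarray:
        B = self.bases()
        c = self.coefs(theta)
        out = np.zeros_like(B[0], dtype=float)
        for cj, Bj in zip(c, B):
            out += cj * Bj
        return out


class ScaledKernel(KernelStructure):
    """``K = sigma2 * K0`` with a fixed kernel K0 (identity, GRM, Kronecker...).

    ``fixed_value`` pins sigma2 to a known constant (no free parameter), which
    is how second-step models hold first-step variance components exactly.
    """

    def __init__(self, K0: np.ndarray, fixed_value: float | None = None,
                 name: str = "var"):
        K0 = np.asarray(K0, dtype=float)
        if K0.ndim != 2 or K0.shape[0] != K0.shape[1]:
            raise ValueError("kernel must be square")
        self.K0 = K0
        self.fixed_value = fixed_value
        self.name = name
        self.n_params = 0 if fixed_value is not None else 1

    def bases(self):
        return [self.K0]

    def coefs(self, theta):
        if self.fixed_value is not None:
            return np.array([self.fixed_value])
        return np.array([np.exp(_clip_eta(theta[0]))])

    def dcoefs(self, theta):
        if self.fixed_value is not None:
            return np.zeros((0, 1))
        return np.array([[np.exp(_clip_eta(theta[0]))]])

    def init_params(self, var0):
        if self.fixed_value is not None:
            return np.zeros(0)
        return np.array([np.log(max(var0, 1e-8))])

    def n_variance_slots(self):
        return 0 if self.fixed_value is not None else 1

    def param_dict(self, theta):
        return {self.name: float(self.coefs(theta)[0])}


class UnstructuredKron(KernelStructure):
    """``K = Sigma (x) I_m`` with Sigma a small unstructured covariance.

    Sigma (d x d) is parameterized through its log-Cholesky factor
    (log diagonal, free off-diagonal), giving d(d+1)/2 free parameters.
    Levels are ordered group-major: (group_1, unit_1..m), (group_2, ...).
    Used for the hybrid-by-location term of the multi-trial model, where the
    groups are the two trial locations.
    """

    def __init__(self, dim: int, m: int, group_names: list[str] | None = None):
        if dim < 1 or m < 1:
            raise ValueError("dim and m must be >= 1")
        self.dim = dim
        self.m = m
        self.group_names = group_names or [f"g{i+1}" for i in range(dim)]
        self.n_params = dim * (dim + 1) // 2
        # parameter order: column-major lower triangle (l11, l21, .., l22, ..)
        self._idx = [(i, j) for j in range(dim) for i in range(j, dim)]

    def bases(self):
        d, m = self.dim, self.m
        Im = np.eye(m)
        out = []
        for i in range(d):
            for j in range(i, d):
                E = np.zeros((d, d))
                E[i, j] = 1.0
                if i != j:
                    E[j, i] = 1.0
                out.append(np.kron(E, Im))
        return out

    def _chol(self, theta):
        d = self.dim
        L = np.zeros((d, d))
        for t, (i, j) in zip(theta, self._idx):
            L[i, j] = np.exp(_clip_eta(t)) if i == j else t
        return L

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        L = self._chol(theta)
        return L @ L.T

    def coefs(self, theta):
        S = self.sigma(theta)
        d = self.dim
        return np.array([S[i, j] for i in range(d) for j in range(i, d)])

    def dcoefs(self, theta):
        d = self.dim
        L = self._chol(theta)
        out = np.zeros((self.n_params, self.n_params))
        for p, (pi, pj) in enumerate(self._idx):
            dL = np.zeros((d, d))
            dL[pi, pj] = np.exp(_clip_eta(theta[p])) if pi == pj else 1.0
            dS = dL @ L.T + L @ dL.T
            out[p] = [dS[i, j] for i in range(d) for j in range(i, d)]
        return out

    def init_params(self, var0):
        # Sigma starts at var0 * I
        v = max(var0, 1e-8)
        theta = np.zeros(self.n_params)
        for p, (i, j) in enumerate(self._idx):
            theta[p] = 0.5 * np.log(v) if i == j else 0.0
        return theta

    def n_variance_slots(self):
        return 1

    def param_dict(self, theta):
        S = self.sigma(theta)
        out = {}
        for i in range(self.dim):
            out[f"var_{self.group_names[i]}"] = float(S[i, i])
        for i in range(self.dim):
            for j in range(i + 1, self.dim):
                out[f"cov_{self.group_names[i]}_{self.group_names[j]}"] = float(S[i, j])
        return out


class ResidualStructure:
    """Observation-level error covariance R(theta)."""

    n_params: int = 0

    def matrix(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dmatrices(self, theta: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    def init_params(self, var0: float) -> np.ndarray:
        raise NotImplementedError

    def n_variance_slots(self) -> int:
        raise NotImplementedError

    def param_dict(self, theta: np.ndarray) -> dict[str, float]:
        raise NotImplementedError


class IIDResidual(ResidualStructure):
    """R = sigma2_e * I."""

    n_params = 1

    def __init__(self, n_obs: int):
        self.n_obs = n_obs

    def matrix(self, theta):
        return np.exp(_clip_eta(theta[0])) * np.eye(self.n_obs)

    def dmatrices(self, theta):
        return [np.exp(_clip_eta(theta[0])) * np.eye(self.n_obs)]

    def init_params(self, var0):
        return np.array([np.log(max(var0, 1e-8))])

    def n_variance_slots(self):
        return 1

    def param_dict(self, theta):
        return {"var_e": float(np.exp(_clip_eta(theta[0])))}


class KnownDiagonalResidual(ResidualStructure):
    """R = diag(w) with known weights; no free parameter and no rescaling.

    Used in second-stage models where each observation's residual variance is
    fixed at its first-stage squared standard error.
    """

    n_params = 0

    def __init__(self, weights: np.ndarray):
        w = np.asarray(weights, dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("known residual weights must be finite and > 0")
        self.weights = w

    def matrix(self, theta):
        return np.diag(self.weights)

    def dmatrices(self, theta):
        return []

    def init_params(self, var0):
        return np.zeros(0)

    def n_variance_slots(self):
        return 0

    def param_dict(self, theta):
        return {}


class GridAR1Residual(ResidualStructure):
    """Spatial residual on a field grid, marginalized to the observed cells.

    R = sigma2_e * (Sigma_r(rho_r) (x) Sigma_c(rho_c))[obs, obs]
        [+ sigma2_nugget * I]

    ``row_ar1=False`` replaces Sigma_r by the identity (AR1 along columns
    only); ``nugget=False`` drops the spatially independent error term.
    Cells are indexed row-major: cell = row_index * n_cols + col_index.
    """

    def __init__(self, n_rows: int, n_cols: int, obs_cells: np.ndarray,
                 row_ar1: bool = False, nugget: bool = False):
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self.obs = np.asarray(obs_cells, dtype=int)
        if self.obs.size and (self.obs.min() < 0 or self.obs.max() >= n_rows * n_cols):
            raise ValueError("observed cell index outside the field grid")
        self.row_ar1 = bool(row_ar1)
        self.nugget = bool(nugget)
        self.n_params = 1 + (1 if row_ar1 else 0) + 1 + (1 if nugget else 0)
        # parameter order: eta_e, [psi_r], psi_c, [eta_nugget]

    def _unpack(self, theta):
        k = 0
        s2e = np.exp(_clip_eta(theta[k])); k += 1
        if self.row_ar1:
            rho_r = np.tanh(np.clip(theta[k], -_PSI_LIM, _PSI_LIM)); k += 1
        else:
            rho_r = 0.0
        rho_c = np.tanh(np.clip(theta[k], -_PSI_LIM, _PSI_LIM)); k += 1
        s2n = np.exp(_clip_eta(theta[k])) if self.nugget else 0.0
        return s2e, rho_r, rho_c, s2n

    def _corr_parts(self, theta):
        s2e, rho_r, rho_c, s2n = self._unpack(theta)
        Sr = ar1_matrix(self.n_rows, rho_r) if self.row_ar1 else np.eye(self.n_rows)
        Sc = ar1_matrix(self.n_cols, rho_c)
        return s2e, rho_r, rho_c, s2n, Sr, Sc

    def matrix(self, theta):
        s2e, _, _, s2n, Sr, Sc = self._corr_parts(theta)
        S = np.kron(Sr, Sc)[np.ix_(self.obs, self.obs)]
        R = s2e * S
        if self.nugget:
            R = R + s2n * np.eye(self.obs.size)
        return R

    def dmatrices(self, theta):
        s2e, rho_r, rho_c, s2n, Sr, Sc = self._corr_parts(theta)
        ix = np.ix_(self.obs, self.obs)
        out = [s2e * np.kron(Sr, Sc)[ix]]  # d/d eta_e
        if self.row_ar1:
            dSr = _dar1_matrix(self.n_rows, rho_r)
            out.append(s2e * (1 - rho_r ** 2) * np.kron(dSr, Sc)[ix])
        dSc = _dar1_matrix(self.n_cols, rho_c)
        out.append(s2e * (1 - rho_c ** 2) * np.kron(Sr, dSc)[ix])
        if self.nugget:
            out.append(s2n * np.eye(self.obs.size))
        return out

    def init_params(self, var0):
        v = max(var0, 1e-8)
        theta = [np.log(v)]
        if self.row_ar1:
            theta.append(0.0)
        theta.append(0.0)
        if self.nugget:
            theta.append(np.log(v))
        return np.array(theta)

    def n_variance_slots(self):
        return 1 + (1 if self.nugget else 0)

    def param_dict(self, theta):
        s2e, rho_r, rho_c, s2n = self._unpack(theta)
        out = {"var_e": float(s2e)}
        if self.row_ar1:
            out["rho_row"] = float(rho_r)
        out["rho_col"] = float(rho_c)
        if self.nugget:
            out["var_nugget"] = float(s2n)
        return out
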