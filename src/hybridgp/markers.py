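"""Marker QC, PCA, and genomic relationship matrices.

Genotypes are a pandas DataFrame of allele dosages (individuals x SNPs,
values 0/1/2, NaN for missing calls).  The additive relationship follows
VanRaden's first method; the dominance relationship uses the
Vitezica-style heterozygosity coding.  LD between sites is measured with a
kinship-corrected squared correlation (rv2) so that shared population
history does not inflate the plain r2 statistic; pruning keeps the most
informative (highest-PIC) site of any high-LD pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

__all__ = ["filter_snps", "pic", "allele_freqs", "ld_rv2", "prune_ld",
           "pca", "PcaResult", "grm_vanraden", "dominance_matrix",
           "check_rel_matrix"]

_PSD_TOL = -1e-8


def allele_freqs(g: pd.DataFrame) -> pd.Series:
    """Alternate-allele frequency per SNP, from non-missing calls."""
    return g.mean(axis=0, skipna=True) / 2.0


def filter_snps(g: pd.DataFrame, maf_min: float = 0.05,
                miss_max: float = 0.10) -> list[str]:
    """SNP IDs passing minor-allele-frequency and missingness thresholds.

    Both bounds are inclusive (MAF >= maf_min, missingness <= miss_max) and
    MAF is computed on non-missing calls only.  Input column order is
    preserved.
    """
    if g.shape[0] == 0 or g.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    p = allele_freqs(g)
    maf = np.minimum(p, 1.0 - p)
    miss = g.isna().mean(axis=0)
    keep = [s for s in g.columns
            if maf[s] >= maf_min - 1e-12 and miss[s] <= miss_max + 1e-12]
    if not keep:
        raise ValueError("all SNPs removed by MAF/missingness filtering")
    return keep


def pic(p) -> np.ndarray | float:
    """Polymorphism information content of a biallelic SNP (Botstein).

    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2, maximal (0.375) at p = 0.5.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    q = 1.0 - p
    out = 1.0 - (p ** 2 + q ** 2) - 2.0 * (p ** 2) * (q ** 2)
    out = np.maximum(out, 0.0)  # guard against cancellation at p ~ 0 or 1
    return float(out) if out.ndim == 0 else out


def _impute_center(g: pd.DataFrame) -> np.ndarray:
    """Column-center dosages; missing calls are mean-imputed (centered to 0)."""
    X = g.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    Z = X - mu
    Z[np.isnan(Z)] = 0.0
    return Z


def _whiten(k: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Multiply column vectors by the inverse Cholesky factor of k."""
    try:
        L = cholesky(k, lower=True)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "kinship matrix is singular; add a small ridge "
            "(k + eps*I) before LD correction") from e
    return solve_triangular(L, vectors, lower=True)


def _rv2_from_whitened(a: np.ndarray, b: np.ndarray, one_w: np.ndarray) -> float:
    # project out the whitened intercept = GLS centering
    def resid(v):
        return v - one_w * (one_w @ v) / (one_w @ one_w)
    ra, rb = resid(a), resid(b)
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0:
        return 0.0
    return float((ra @ rb) ** 2 / ((ra @ ra) * (rb @ rb)))


def ld_rv2(x_a, x_b, k: np.ndarray) -> float:
    """Kinship-corrected squared LD correlation between two dosage vectors.

    Both vectors are whitened by the inverse Cholesky factor of the kinship
    matrix and correlated after projecting out the whitened intercept
    (equivalently, a GLS regression of one site on the other under residual
    covariance k).  With k = I this is the plain squared Pearson r.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape:
        raise ValueError("dosage vectors must have equal length")
    k = np.asarray(k, dtype=float)
    if k.shape != (x_a.size, x_a.size):
        raise ValueError("kinship matrix not conformable with dosage vectors")
    W = _whiten(k, np.column_stack([x_a, x_b, np.ones(x_a.size)]))
    return _rv2_from_whitened(W[:, 0], W[:, 1], W[:, 2])


def prune_ld(g: pd.DataFrame, k: np.ndarray, rv2_max: float = 0.5) -> list[str]:
    """Greedy LD pruning: keep the highest-PIC SNP of any high-LD pair.

    SNPs are scanned in descending PIC order (ties broken by input order);
    a SNP is kept only if its rv2 with every already-kept SNP is below
    ``rv2_max``.  Within any clique of mutually linked sites exactly the
    max-PIC member survives, and the result is deterministic.  Returned IDs
    are in the original column order.
    """
    snps = list(g.columns)
    if not snps:
        return []
    p = allele_freqs(g).to_numpy()
    pics = pic(np.clip(p, 0.0, 1.0))
    Z = _impute_center(g)
    k = np.asarray(k, dtype=float)
    W = _whiten(k, np.column_stack([Z, np.ones(Z.shape[0])]))
    one_w = W[:, -1]
    Wz = W[:, :-1]
    order = sorted(range(len(snps)), key=lambda j: (-pics[j], j))
    kept: list[int] = []
    for j in order:
        ok = all(_rv2_from_whitened(Wz[:, j], Wz[:, i], one_w) < rv2_max
                 for i in kept)
        if ok:
            kept.append(j)
    kept_set = set(kept)
    return [s for j, s in enumerate(snps) if j in kept_set]


@dataclass
class PcaResult:
    """Principal components of the centered marker matrix (P = U S)."""
    scores: pd.DataFrame          # lines x components
    eigenvalues: np.ndarray       # of the marker covariance matrix
    var_fractions: np.ndarray     # per-component, sums to 1
    cum_var: np.ndarray


def pca(g: pd.DataFrame) -> PcaResult:
    """SVD-based PCA of the column-centered (mean-imputed) dosage matrix."""
    if g.shape[0] < 2:
        raise ValueError("PCA requires at least two lines")
    Z = _impute_center(g)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U * s
    tot = float(np.sum(s ** 2))
    frac = s ** 2 / tot if tot > 0 else np.zeros_like(s)
    eig = s ** 2 / (g.shape[0] - 1)
    cols = [f"PC{i + 1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=g.index.copy(), columns=cols),
        eigenvalues=eig, var_fractions=frac, cum_var=np.cumsum(frac))


def check_rel_matrix(G: pd.DataFrame, sym_tol: float = 1e-10) -> pd.DataFrame:
    """Validate symmetry and positive semi-definiteness of a relationship matrix."""
    A = G.to_numpy()
    if not np.allclose(A, A.T, atol=sym_tol):
        raise ValueError("relationship matrix not symmetric")
    w = np.linalg.eigvalsh(A)
    if w.min() < _PSD_TOL * max(1.0, abs(w.max())):
        raise ValueError(f"relationship matrix not PSD (min eigenvalue {w.min():.3g})")
    return G


def grm_vanraden(g: pd.DataFrame) -> pd.DataFrame:
    """VanRaden additive genomic relationship matrix.

    G = Z Z' / (2 * sum_j p_j (1 - p_j)) with Z the column-centered dosage
    matrix and p the allele frequencies of the supplied panel itself.
    Fully homozygous inbred panels have diagonal near 2.
    """
    p = allele_freqs(g).to_numpy()
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ZeroDivisionError("all SNPs monomorphic: VanRaden denominator is 0")
    Z = _impute_center(g)
    G = Z @ Z.T / denom
    G = 0.5 * (G + G.T)
    out = pd.DataFrame(G, index=g.index.copy(), columns=g.index.copy())
    return check_rel_matrix(out)


def dominance_matrix(g: pd.DataFrame) -> pd.DataFrame:
    """Dominance relationship matrix (Vitezica coding) on hybrid dosages.

    Per SNP with allele frequency p: dosage 0 -> -2p^2, 1 -> 2pq,
    2 -> -2q^2; D = W W' / sum_j (2 p_j q_j)^2.
    """
    p = allele_freqs(g).to_numpy()
    q = 1.0 - p
    denom = float(np.sum((2.0 * p * q) ** 2))
    if denom <= 0:
        raise ZeroDivisionError("all SNPs monomorphic: dominance denominator is 0")
    X = g.to_numpy(dtype=float)
    W = np.full_like(X, np.nan)
    W[X == 0] = np.broadcast_to(-2.0 * p ** 2, X.shape)[X == 0]
    W[X == 1] = np.broadcast_to(2.0 * p * q, X.shape)[X == 1]
    W[X == 2] = np.broadcast_to(-2.0 * q ** 2, X.shape)[X == 2]
    W[np.isnan(W)] = 0.0  # missing calls contribute nothing
    D = W @ W.T / denom
    D = 0.5 * (D + D.T)
    out = pd.DataFrame(D, index=g.index.copy(), columns=g.index.copy())
    return check_rel_matrix(out)
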