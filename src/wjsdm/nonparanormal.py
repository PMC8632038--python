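"""Rank-based covariance estimation for expression data with dropout.

Each group/platform expression matrix is modelled as draws from a
nonparanormal (Gaussian copula) distribution: every gene's marginal is an
unknown strictly monotone transform of a latent Gaussian coordinate, so the
conditional-independence structure lives in the latent precision matrix.
The latent correlation is recovered without estimating the marginal
transforms: Kendall's tau is computed only over sample pairs in which both
genes are observed (dropout zeros and NaNs are treated as unobserved), and
the sine transform ``sin(pi/2 * tau)`` maps it to the latent Pearson
correlation. A final eigenvalue projection makes each estimate positive
semidefinite so the downstream D-trace loss is convex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "CovarianceSet",
    "observed_mask",
    "revised_kendall_tau",
    "kendall_matrix",
    "npn_covariance",
    "nearest_psd",
    "estimate_covariances",
]

logger = logging.getLogger(__name__)


def observed_mask(values: np.ndarray, zeros_as_missing: bool = True) -> np.ndarray:
    """Boolean mask of recorded entries.

    An entry counts as observed iff it is finite and (by default) nonzero;
    exact zeros emulate scRNA-seq dropout and explicit missing markers.
    """
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values)
    if zeros_as_missing:
        mask &= values != 0
    return mask


@dataclass
class ExpressionMatrix:
    """One group's expression matrix on one platform (samples x genes)."""

    values: np.ndarray
    gene_ids: Sequence[str]
    group_label: int = 1
    platform_label: int = 1
    zeros_as_missing: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError("need at least 2 samples and 2 genes")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length must match the number of columns")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids must be unique")
        if self.group_label not in (1, 2):
            raise ValueError("group_label must be 1 or 2")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        return observed_mask(self.values, self.zeros_as_missing)


@dataclass
class CovarianceSet:
    """Nonparanormal covariance estimates, indexed (platform, group).

    ``matrices`` has shape (K, 2, p, p); ``get(k, c)`` uses the 1-based
    platform/group labels used throughout the package.
    """

    matrices: np.ndarray
    gene_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.matrices.ndim != 4 or self.matrices.shape[1] != 2:
            raise ValueError("matrices must have shape (K, 2, p, p)")
        if self.matrices.shape[2] != self.matrices.shape[3]:
            raise ValueError("covariance matrices must be square")
        if self.matrices.shape[2] != len(self.gene_ids):
            raise ValueError("gene_ids length must match matrix dimension")

    @property
    def n_platforms(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrices.shape[2]

    def get(self, platform: int, group: int) -> np.ndarray:
        return self.matrices[platform - 1, group - 1]


def revised_kendall_tau(
    x: np.ndarray, y: np.ndarray, zeros_as_missing: bool = True
) -> float:
    """Kendall's tau over sample pairs where both genes are observed.

    Concordance signs are summed over ordered pairs (l, l') of samples in
    which both x and y are recorded, and normalized by n_ij * (n_ij - 1)
    where n_ij is the number of jointly observed samples. Ties contribute
    zero (sign(0) = 0). Degenerate pairs with n_ij <= 1 return 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    both = observed_mask(x, zeros_as_missing) & observed_mask(y, zeros_as_missing)
    n_ij = int(both.sum())
    if n_ij <= 1:
        return 0.0
    xv = x[both]
    yv = y[both]
    s = np.sign(xv[:, None] - xv[None, :]) * np.sign(yv[:, None] - yv[None, :])
    return float(s.sum() / (n_ij * (n_ij - 1)))


def kendall_matrix(X: "ExpressionMatrix | np.ndarray", zeros_as_missing: bool = True) -> np.ndarray:
    """Pairwise revised Kendall's tau for all gene pairs; diagonal set to 1.

    Vectorized over gene pairs: per gene a masked sign matrix over sample
    pairs is built once, and all pairwise sums reduce to one matrix product.
    All intermediate sums are integer-valued and exactly representable, so
    the result is exactly symmetric and bit-reproducible.
    """
    if isinstance(X, ExpressionMatrix):
        vals, mask = X.values, X.mask
    else:
        vals = np.asarray(X, dtype=float)
        mask = observed_mask(vals, zeros_as_missing)
    n, p = vals.shape
    filled = np.where(mask, vals, 0.0)
    signs = np.empty((p, n * n), dtype=np.int8)
    for j in range(p):
        sj = np.sign(filled[:, j][:, None] - filled[:, j][None, :])
        dj = mask[:, j]
        sj[~dj, :] = 0.0
        sj[:, ~dj] = 0.0
        signs[j] = sj.astype(np.int8).ravel()
    # products of {-1,0,1} summed over <= n^2 terms: exact in float64
    a = signs.astype(np.float64)
    num = a @ a.T
    dm = mask.astype(np.float64)
    n_ij = dm.T @ dm
    den = n_ij * (n_ij - 1.0)
    tau = np.zeros((p, p))
    ok = den > 0
    tau[ok] = num[ok] / den[ok]
    np.fill_diagonal(tau, 1.0)
    return tau


def npn_covariance(tau: np.ndarray) -> np.ndarray:
    """Map a Kendall's tau matrix to the latent Gaussian correlation.

    Off-diagonals become sin(pi/2 * tau); the diagonal is set to 1.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.ndim != 2 or tau.shape[0] != tau.shape[1]:
        raise ValueError("tau must be square")
    if np.any(np.abs(tau) > 1.0 + 1e-12):
        raise ValueError("tau entries must lie in [-1, 1]")
    sigma = np.sin(0.5 * np.pi * np.clip(tau, -1.0, 1.0))
    np.fill_diagonal(sigma, 1.0)
    return sigma


def nearest_psd(M: np.ndarray, sym_tol: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone, keeping a unit diagonal.

    Negative eigenvalues are clipped to zero and the matrix reassembled;
    because clipping can perturb the diagonal, a symmetric rescaling
    restores unit diagonal (a congruence, so positive semidefiniteness is
    preserved). Already-PSD input is returned unchanged, which also makes
    the projection idempotent.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(M, M.T, atol=sym_tol, rtol=0.0):
        raise ValueError("input must be symmetric")
    M = 0.5 * (M + M.T)
    w, v = np.linalg.eigh(M)
    if w[0] >= 0.0:
        return M.copy()
    a = (v * np.clip(w, 0.0, None)) @ v.T
    a = 0.5 * (a + a.T)
    d = np.diag(a).copy()
    d[d <= 1e-12] = 1.0  # isolated genes: leave their row untouched
    scale = 1.0 / np.sqrt(d)
    a = a * np.outer(scale, scale)
    np.fill_diagonal(a, 1.0)
    return a


def estimate_covariances(data: Sequence[ExpressionMatrix]) -> CovarianceSet:
    """Full pipeline: revised tau -> sine transform -> PSD projection.

    Expects one ExpressionMatrix per (platform, group) combination, all
    sharing the same ordered gene_ids.
    """
    if not data:
        raise ValueError("no expression matrices provided")
    gene_ids = data[0].gene_ids
    for X in data:
        if X.gene_ids != gene_ids:
            raise ValueError("all expression matrices must share gene_ids")
    platforms = sorted({X.platform_label for X in data})
    if platforms != list(range(1, len(platforms) + 1)):
        raise ValueError("platform labels must be 1..K")
    K = len(platforms)
    p = len(gene_ids)
    mats = np.full((K, 2, p, p), np.nan)
    seen = set()
    for X in data:
        key = (X.platform_label, X.group_label)
        if key in seen:
            raise ValueError(f"duplicate expression matrix for {key}")
        seen.add(key)
        tau = kendall_matrix(X)
        mats[X.platform_label - 1, X.group_label - 1] = nearest_psd(npn_covariance(tau))
    if len(seen) != 2 * K:
        missing = sorted({(k, c) for k in platforms for c in (1, 2)} - seen)
        raise ValueError(f"missing expression matrices for {missing}")
    return CovarianceSet(mats, gene_ids)
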