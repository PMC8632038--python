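"""Scoring of estimated differential networks against simulated truth.

TPR pools true-positive counts over platforms and unordered gene pairs:
TPR = sum_k sum_{i<j} I(est != 0 and true != 0) / sum_k sum_{i<j} I(true != 0),
and FPR analogously over true-zero pairs. Performance curves trace
(FPR, TPR) along a descending lambda grid, and hub genes are ranked by
total degree in the estimated differential networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .priors import DEWeights, PriorKnowledge
from .simulation import SimulationTruth
from .solver import SUPPORT_TOL, DifferentialNetworkSet, SolverConfig, fit

__all__ = [
    "EvaluationResult",
    "tpr_fpr",
    "performance_curve",
    "curve_auc",
    "hub_rank",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    tpr: float  # NaN when there are no true edges
    fpr: float  # NaN when there are no true-zero pairs
    counts: pd.DataFrame  # per-platform TP, FP, FN, TN over i<j pairs

    def total(self, col: str) -> int:
        return int(self.counts[col].sum())


def _support_array(networks, tol: float) -> np.ndarray:
    if isinstance(networks, DifferentialNetworkSet):
        return networks.support(tol)
    arr = np.asarray(networks, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return np.abs(arr) > tol


def _truth_deltas(truth) -> np.ndarray:
    if isinstance(truth, SimulationTruth):
        return truth.true_deltas
    arr = np.asarray(truth, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def tpr_fpr(estimated, truth, tol: float = SUPPORT_TOL) -> EvaluationResult:
    """True/false positive rates over unordered pairs, pooled over platforms."""
    est = _support_array(estimated, tol)
    tru = np.abs(_truth_deltas(truth)) > tol
    if est.shape != tru.shape:
        raise ValueError("estimate and truth have mismatched shapes")
    K, p, _ = est.shape
    iu = np.triu_indices(p, 1)
    rows = []
    for k in range(K):
        e = est[k][iu]
        t = tru[k][iu]
        rows.append(
            {
                "platform": k + 1,
                "TP": int(np.sum(e & t)),
                "FP": int(np.sum(e & ~t)),
                "FN": int(np.sum(~e & t)),
                "TN": int(np.sum(~e & ~t)),
            }
        )
    counts = pd.DataFrame(rows)
    pos = counts["TP"].sum() + counts["FN"].sum()
    neg = counts["FP"].sum() + counts["TN"].sum()
    tpr = float(counts["TP"].sum() / pos) if pos > 0 else float("nan")
    fpr = float(counts["FP"].sum() / neg) if neg > 0 else float("nan")
    return EvaluationResult(tpr=tpr, fpr=fpr, counts=counts)


def performance_curve(
    covariances,
    de_weights: DEWeights,
    prior: "PriorKnowledge | None",
    truth,
    lambdas: Sequence[float],
    solver_config: "SolverConfig | None" = None,
) -> pd.DataFrame:
    """(FPR, TPR) along a descending lambda grid, warm-started between fits."""
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly descending")
    if solver_config is None:
        solver_config = SolverConfig()
    K = covariances.n_platforms
    p = covariances.n_genes
    warm = np.zeros((K, p, p))
    rows = []
    for lam in lambdas:
        cfg = replace(solver_config, lambda_value=float(lam), init=warm)
        net = fit(covariances, de_weights, prior, cfg)
        warm = net.deltas
        res = tpr_fpr(net, truth)
        rows.append({"lambda": float(lam), "tpr": res.tpr, "fpr": res.fpr})
    return pd.DataFrame(rows)


def curve_auc(curve: pd.DataFrame) -> float:
    """Trapezoidal area under the (FPR, TPR) points, anchored at (0,0), (1,1)."""
    fpr = np.concatenate([[0.0], np.asarray(curve["fpr"], float), [1.0]])
    tpr = np.concatenate([[0.0], np.asarray(curve["tpr"], float), [1.0]])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def hub_rank(
    network: DifferentialNetworkSet, top_n: int = 10, tol: float = SUPPORT_TOL
) -> pd.DataFrame:
    """Genes ranked by total differential-network degree across platforms.

    Degree counts incident nonzero off-diagonal entries per platform; ties
    in total degree are broken lexicographically by gene identifier.
    """
    if top_n < 1:
        raise ValueError("top_n must be at least 1")
    sup = network.support(tol)
    K, p, _ = sup.shape
    off = sup.copy()
    for k in range(K):
        np.fill_diagonal(off[k], False)
    degrees = off.sum(axis=2)  # (K, p)
    total = degrees.sum(axis=0)
    genes = list(network.gene_ids)
    order = sorted(range(p), key=lambda i: (-total[i], genes[i]))[:top_n]
    rows = []
    for rank, i in enumerate(order, start=1):
        rows.append(
            {
                "rank": rank,
                "gene": genes[i],
                "degree_total": int(total[i]),
                "degree_by_platform": "|".join(str(int(degrees[k, i])) for k in range(K)),
                **{f"degree_platform_{k + 1}": int(degrees[k, i]) for k in range(K)},
            }
        )
    return pd.DataFrame(rows)
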