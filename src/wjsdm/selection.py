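"""Stability-based selection of the sparsity parameter lambda (StARS).

For each lambda on a descending grid the model is refit on N subsamples
drawn without replacement within each group (covariances and DE weights
recomputed per subsample, so the whole pipeline is honestly resampled).
Per edge and platform the selection frequency theta is turned into the
instability 2 * theta * (1 - theta); the mean over off-diagonal pairs and
platforms is the total instability D(lambda). After monotonizing D along
decreasing lambda, the smallest lambda whose monotonized instability stays
below the threshold beta is selected — the densest stable model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .nonparanormal import ExpressionMatrix, estimate_covariances
from .priors import PriorKnowledge, compute_de_weights
from .solver import SUPPORT_TOL, SolverConfig, fit

__all__ = [
    "StarsConfig",
    "StarsResult",
    "subsample_size",
    "edge_instability",
    "select_from_path",
    "stars_select",
]

logger = logging.getLogger(__name__)


@dataclass
class StarsConfig:
    n_subsamples: int = 20
    beta: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsamples < 2:
            raise ValueError("need at least 2 subsamples")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")


@dataclass
class StarsResult:
    lambda_selected: float
    path: pd.DataFrame  # columns: lambda, instability, instability_monotone, selected


def subsample_size(n: int) -> int:
    """Canonical StARS rule: b = min(floor(10 sqrt(n)), n - 1)."""
    return max(2, min(int(np.floor(10.0 * np.sqrt(n))), n - 1))


def edge_instability(supports: Sequence[np.ndarray]) -> float:
    """Mean edge instability 2 theta (1 - theta) over pairs and platforms.

    ``supports``: one (K, p, p) boolean support array per subsample.
    """
    arr = np.asarray([np.asarray(s, dtype=float) for s in supports])
    if arr.ndim != 4:
        raise ValueError("each support must be a (K, p, p) array")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 subsamples")
    theta = arr.mean(axis=0)
    xi = 2.0 * theta * (1.0 - theta)
    p = xi.shape[-1]
    iu = np.triu_indices(p, 1)
    return float(np.mean([xi[k][iu] for k in range(xi.shape[0])]))


def select_from_path(lambdas: np.ndarray, instability: np.ndarray, beta: float):
    """Monotonized StARS selection rule on a precomputed instability path.

    ``lambdas`` must be strictly descending. Returns (selected index,
    monotonized instability). If no lambda qualifies, the largest grid
    value is returned with a warning.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    instability = np.asarray(instability, dtype=float)
    if lambdas.size == 0 or lambdas.size != instability.size:
        raise ValueError("grid and instability path must be nonempty and matched")
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly descending")
    monotone = np.maximum.accumulate(instability)
    ok = monotone <= beta
    if ok.any():
        idx = int(np.nonzero(ok)[0][-1])  # smallest qualifying lambda
    else:
        idx = 0
        logger.warning(
            "no lambda met the instability threshold %.3g; returning the largest grid value",
            beta,
        )
    return idx, monotone


def stars_select(
    data: Sequence[ExpressionMatrix],
    prior: "PriorKnowledge | None",
    grid: Sequence[float],
    config: StarsConfig,
    solver_config: SolverConfig,
) -> StarsResult:
    """Run the full StARS procedure over a lambda grid."""
    grid = np.sort(np.unique(np.asarray(grid, dtype=float)))[::-1]
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("lambda grid must be nonempty and positive")

    group_sizes: dict[int, int] = {}
    for X in data:
        n_prev = group_sizes.setdefault(X.group_label, X.n_samples)
        if n_prev != X.n_samples:
            raise ValueError("group sample counts must agree across platforms")
    if set(group_sizes) != {1, 2}:
        raise ValueError("need both groups")
    if min(group_sizes.values()) < 4:
        raise ValueError("each group needs at least 4 samples for subsampling")
    b = {c: subsample_size(n) for c, n in group_sizes.items()}
    if min(b.values()) < 2:
        raise ValueError("subsample size below 2")

    rng = np.random.default_rng(config.seed)
    sub_cov = []
    sub_de = []
    for _ in range(config.n_subsamples):
        idx = {c: rng.choice(n, size=b[c], replace=False) for c, n in group_sizes.items()}
        sub_data = [
            ExpressionMatrix(
                X.values[idx[X.group_label]],
                X.gene_ids,
                group_label=X.group_label,
                platform_label=X.platform_label,
                zeros_as_missing=X.zeros_as_missing,
            )
            for X in data
        ]
        sub_cov.append(estimate_covariances(sub_data))
        sub_de.append(compute_de_weights(sub_data))

    K = sub_cov[0].n_platforms
    p = sub_cov[0].n_genes
    warm = [np.zeros((K, p, p)) for _ in range(config.n_subsamples)]
    instability = np.zeros(grid.size)
    for li, lam in enumerate(grid):
        supports = []
        for s in range(config.n_subsamples):
            cfg = replace(solver_config, lambda_value=float(lam), init=warm[s])
            net = fit(sub_cov[s], sub_de[s], prior, cfg)
            warm[s] = net.deltas
            supports.append(net.support(SUPPORT_TOL))
        instability[li] = edge_instability(supports)

    idx, monotone = select_from_path(grid, instability, config.beta)
    path = pd.DataFrame(
        {
            "lambda": grid,
            "instability": instability,
            "instability_monotone": monotone,
            "selected": [i == idx for i in range(grid.size)],
        }
    )
    return StarsResult(float(grid[idx]), path)
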