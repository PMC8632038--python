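"""Weighted joint sparse penalized D-trace estimation of differential networks.

Estimates the precision-matrix differences Delta^(k) = Theta^(k2) - Theta^(k1)
for K data platforms directly, without estimating either precision matrix.
The smooth part is the D-trace loss summed over platforms,

    L(Delta; S1, S2) = 1/4 (<S1 Delta, Delta S2> + <S2 Delta, Delta S1>)
                       - <Delta, S1 - S2>,      <A, B> = tr(A B'),

whose unique minimizer (for positive definite inputs) is the true difference.
Sparsity and cross-platform structure come from a weighted group bridge
penalty

    P(Delta) = sum_ij W_ij * sqrt( sum_k tau_ij^(k) |Delta_ij^(k)| ),

where tau are differential-expression pair weights and W prior-knowledge
weights. The concave square root is handled by local linear approximation
(LLA): each outer round replaces the penalty by its tangent weighted-L1
surrogate and solves K independent convex subproblems with an accelerated
proximal gradient (APG) method with Nesterov momentum and restart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nonparanormal import CovarianceSet
from .priors import DEWeights, PriorKnowledge

__all__ = [
    "SUPPORT_TOL",
    "SolverConfig",
    "DifferentialNetworkSet",
    "dtrace_loss",
    "joint_loss",
    "dtrace_gradient",
    "prox_weighted_l1",
    "lla_weights",
    "group_bridge_penalty",
    "penalized_objective",
    "apg_minimize",
    "fit",
    "lambda_max",
]

logger = logging.getLogger(__name__)

#: entries with absolute value above this count as edges
SUPPORT_TOL = 1e-8

_RIDGE = 1e-8  # added to the covariance diagonals before optimization


@dataclass
class SolverConfig:
    lambda_value: float = 0.1
    step_sizes: "str | Sequence[float]" = "auto"
    inner_tol: float = 1e-5
    inner_max_iter: int = 500
    outer_max_iter: int = 5
    lla_floor: float = 1e-8
    init: "str | np.ndarray" = "zero"

    def __post_init__(self) -> None:
        if self.lambda_value < 0:
            raise ValueError("lambda_value must be nonnegative")
        if self.inner_tol <= 0 or self.lla_floor <= 0:
            raise ValueError("tolerances must be positive")
        if self.inner_max_iter < 1 or self.outer_max_iter < 1:
            raise ValueError("iteration limits must be at least 1")


@dataclass
class DifferentialNetworkSet:
    """Estimated Delta^(k), one symmetric p x p matrix per platform."""

    deltas: np.ndarray
    gene_ids: Sequence[str]
    lambda_value: float
    objective_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.deltas.ndim != 3 or self.deltas.shape[1] != self.deltas.shape[2]:
            raise ValueError("deltas must have shape (K, p, p)")

    @property
    def n_platforms(self) -> int:
        return self.deltas.shape[0]

    def support(self, tol: float = SUPPORT_TOL) -> np.ndarray:
        return np.abs(self.deltas) > tol


def _check_square(*mats: np.ndarray) -> int:
    p = mats[0].shape[0]
    for M in mats:
        if M.ndim != 2 or M.shape != (p, p):
            raise ValueError("matrices must all be p x p")
    return p


def dtrace_loss(delta: np.ndarray, S1: np.ndarray, S2: np.ndarray) -> float:
    delta = np.asarray(delta, dtype=float)
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    _check_square(delta, S1, S2)
    quad = np.sum((S1 @ delta) * (delta @ S2)) + np.sum((S2 @ delta) * (delta @ S1))
    return float(0.25 * quad - np.sum(delta * (S1 - S2)))


def joint_loss(deltas: np.ndarray, covariances: "CovarianceSet | np.ndarray") -> float:
    """Sum of D-trace losses over platforms."""
    mats = covariances.matrices if isinstance(covariances, CovarianceSet) else np.asarray(covariances)
    deltas = np.asarray(deltas, dtype=float)
    if deltas.shape[0] != mats.shape[0]:
        raise ValueError("platform count mismatch")
    return float(
        sum(dtrace_loss(deltas[k], mats[k, 0], mats[k, 1]) for k in range(deltas.shape[0]))
    )


def dtrace_gradient(delta: np.ndarray, S1: np.ndarray, S2: np.ndarray) -> np.ndarray:
    delta = np.asarray(delta, dtype=float)
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    _check_square(delta, S1, S2)
    return 0.5 * (S1 @ delta @ S2 + S2 @ delta @ S1) - (S1 - S2)


def prox_weighted_l1(M: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Entrywise soft-thresholding followed by symmetrization."""
    M = np.asarray(M, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds < 0):
        raise ValueError("thresholds must be nonnegative")
    out = np.sign(M) * np.maximum(np.abs(M) - thresholds, 0.0)
    return 0.5 * (out + out.T)


def lla_weights(
    deltas_prev: np.ndarray, pair_weights: np.ndarray, floor: float
) -> np.ndarray:
    """Tangent weights of the square-root group bridge at the previous iterate.

    phi_ij^(k) = tau_ij^(k) / (2 sqrt(max(sum_k tau_ij^(k) |Delta_ij^(k)|, floor))).
    The floor keeps the linearization finite at zero iterates.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    deltas_prev = np.asarray(deltas_prev, dtype=float)
    pair_weights = np.asarray(pair_weights, dtype=float)
    if np.any(pair_weights < 0):
        raise ValueError("pair weights must be nonnegative")
    if deltas_prev.shape != pair_weights.shape:
        raise ValueError("shape mismatch between deltas and pair weights")
    group = np.sum(pair_weights * np.abs(deltas_prev), axis=0)
    denom = 2.0 * np.sqrt(np.maximum(group, floor))
    phi = pair_weights / denom[None, :, :]
    return 0.5 * (phi + np.transpose(phi, (0, 2, 1)))


def group_bridge_penalty(
    deltas: np.ndarray, pair_weights: np.ndarray, W: np.ndarray
) -> float:
    """P(Delta) = sum_ij W_ij sqrt(sum_k tau_ij^(k) |Delta_ij^(k)|)."""
    group = np.sum(np.asarray(pair_weights) * np.abs(np.asarray(deltas)), axis=0)
    return float(np.sum(np.asarray(W) * np.sqrt(group)))


def penalized_objective(
    deltas: np.ndarray,
    covariances: "CovarianceSet | np.ndarray",
    de_weights: DEWeights,
    prior: "PriorKnowledge | None",
    lambda_value: float,
) -> float:
    """Full objective: joint D-trace loss + lambda * group bridge penalty."""
    p = np.asarray(deltas).shape[1]
    W = prior.W if prior is not None else np.ones((p, p))
    return joint_loss(deltas, covariances) + lambda_value * group_bridge_penalty(
        deltas, de_weights.pair_weights, W
    )


def _backtracking_step(Y, S1, S2, thresholds, step):
    grad = dtrace_gradient(Y, S1, S2)
    loss_y = dtrace_loss(Y, S1, S2)
    st = step
    Z = Y
    loss_z = loss_y
    for _ in range(60):
        Z = prox_weighted_l1(Y - st * grad, st * thresholds)
        loss_z = dtrace_loss(Z, S1, S2)
        diff = Z - Y
        bound = loss_y + np.sum(grad * diff) + np.sum(diff * diff) / (2.0 * st)
        if loss_z <= bound + 1e-12 * (1.0 + abs(loss_y)):
            break
        st *= 0.5
    return Z, loss_z


def apg_minimize(
    S1: np.ndarray,
    S2: np.ndarray,
    thresholds_base: np.ndarray,
    step: "float | None" = None,
    init: "np.ndarray | None" = None,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> np.ndarray:
    """Weighted-lasso penalized D-trace subproblem for one platform.

    Minimizes dtrace_loss(Delta) + sum_ij T_ij |Delta_ij| over symmetric
    Delta via accelerated proximal gradient with Nesterov momentum. The
    momentum is restarted whenever the objective would increase, and the
    restarted plain proximal step is a guaranteed descent step, so the
    accepted objective sequence is nonincreasing and the final objective
    never exceeds the objective at the initial point.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    thresholds_base = np.asarray(thresholds_base, dtype=float)
    p = _check_square(S1, S2, thresholds_base)
    if np.any(thresholds_base < 0):
        raise ValueError("thresholds must be nonnegative")
    if step is None:
        step = 1.0 / max(np.linalg.norm(S1, 2) * np.linalg.norm(S2, 2), 1e-12)
    if step <= 0:
        raise ValueError("step must be positive")
    D = np.zeros((p, p)) if init is None else 0.5 * (np.asarray(init, float) + np.asarray(init, float).T)
    Y = D.copy()
    theta = 1.0

    def pen(M):
        return float(np.sum(thresholds_base * np.abs(M)))

    obj_cur = dtrace_loss(D, S1, S2) + pen(D)
    for _ in range(max_iter):
        Z, loss_z = _backtracking_step(Y, S1, S2, thresholds_base, step)
        obj_z = loss_z + pen(Z)
        if obj_z > obj_cur + 1e-12 * (1.0 + abs(obj_cur)):
            # momentum overshoot: restart from the last accepted iterate
            Y = D.copy()
            theta = 1.0
            Z, loss_z = _backtracking_step(Y, S1, S2, thresholds_base, step)
            obj_z = loss_z + pen(Z)
        if not np.all(np.isfinite(Z)):
            raise FloatingPointError("non-finite iterate in APG; check inputs/step size")
        rel = np.linalg.norm(Z - D) / max(1.0, np.linalg.norm(D))
        theta_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * theta * theta))
        Y = Z + ((theta - 1.0) / theta_new) * (Z - D)
        D = Z
        obj_cur = obj_z
        theta = theta_new
        if rel < tol:
            break
    return 0.5 * (D + D.T)


def _prepare_inputs(covariances, de_weights, prior):
    S = covariances.matrices
    K = S.shape[0]
    p = S.shape[2]
    taus = np.asarray(de_weights.pair_weights, dtype=float)
    if taus.shape != (K, p, p):
        raise ValueError("DE pair weights must have shape (K, p, p)")
    W = prior.W if prior is not None else np.ones((p, p))
    if W.shape != (p, p):
        raise ValueError("prior weight matrix has wrong shape")
    return S, taus, W, K, p


def fit(
    covariances: CovarianceSet,
    de_weights: DEWeights,
    prior: "PriorKnowledge | None",
    config: SolverConfig,
) -> DifferentialNetworkSet:
    """Run the full LLA / APG optimization for all K platforms.

    Round 0 uses plain weights phi = tau (the tangent form is undefined at
    the zero start); later rounds use the floored tangent weights. The full
    penalized objective is recomputed after every round and must be
    nonincreasing (checked; a violation aborts the fit).
    """
    S, taus, W, K, p = _prepare_inputs(covariances, de_weights, prior)
    for k in range(K):
        for c in range(2):
            if np.linalg.eigvalsh(S[k, c])[0] < -1e-6:
                raise ValueError(f"covariance for platform {k + 1}, group {c + 1} is not PSD")
    eye = np.eye(p)
    Sr = S + _RIDGE * eye  # broadcast over (K, 2)
    lam = float(config.lambda_value)

    if isinstance(config.step_sizes, str):
        steps = [
            1.0 / max(np.linalg.norm(Sr[k, 0], 2) * np.linalg.norm(Sr[k, 1], 2), 1e-12)
            for k in range(K)
        ]
    else:
        steps = [float(s) for s in config.step_sizes]
        if len(steps) != K or any(s <= 0 for s in steps):
            raise ValueError("need one positive step size per platform")

    if isinstance(config.init, str):
        deltas = np.zeros((K, p, p))
    else:
        deltas = np.array(config.init, dtype=float, copy=True)
        if deltas.shape != (K, p, p):
            raise ValueError("init must have shape (K, p, p)")

    prev_obj = np.inf
    trace: list[float] = []
    for rnd in range(config.outer_max_iter):
        phi = taus if rnd == 0 else lla_weights(deltas, taus, config.lla_floor)
        for k in range(K):
            thresholds = lam * phi[k] * W
            deltas[k] = apg_minimize(
                Sr[k, 0],
                Sr[k, 1],
                thresholds,
                step=steps[k],
                init=deltas[k],
                tol=config.inner_tol,
                max_iter=config.inner_max_iter,
            )
        obj = joint_loss(deltas, Sr) + lam * group_bridge_penalty(deltas, taus, W)
        trace.append(obj)
        if obj > prev_obj + 1e-7 * (1.0 + abs(prev_obj)):
            raise RuntimeError(
                f"penalized objective increased across LLA rounds ({prev_obj} -> {obj})"
            )
        if np.isfinite(prev_obj) and abs(prev_obj - obj) <= config.inner_tol * max(1.0, abs(prev_obj)):
            break
        prev_obj = obj
    return DifferentialNetworkSet(deltas, covariances.gene_ids, lam, trace)


def lambda_max(
    covariances: CovarianceSet,
    de_weights: DEWeights,
    prior: "PriorKnowledge | None" = None,
    return_unpenalized: bool = False,
):
    """Smallest lambda at which the all-zero solution is stationary.

    Zero is a solution of the round-0 weighted-lasso problem iff
    |S^(k1) - S^(k2)|_ij <= lambda * tau_ij^(k) * W_ij for every penalized
    entry. Entries with zero penalty weight cannot be forced to zero by any
    lambda; they are excluded from the bound and reported separately.
    """
    S, taus, W, K, p = _prepare_inputs(covariances, de_weights, prior)
    best = 0.0
    unpenalized: list[tuple[int, int, int]] = []
    for k in range(K):
        C = S[k, 0] - S[k, 1]
        wmat = taus[k] * W
        pos = wmat > 1e-300
        if pos.any():
            best = max(best, float(np.max(np.abs(C[pos]) / wmat[pos])))
        viol = (~pos) & (np.abs(C) > SUPPORT_TOL)
        for i, j in zip(*np.nonzero(viol)):
            if i <= j:
                unpenalized.append((k + 1, int(i), int(j)))
    if unpenalized:
        logger.warning(
            "%d penalty-free entries have nonzero gradient at zero and are "
            "excluded from the lambda_max bound",
            len(unpenalized),
        )
    if return_unpenalized:
        return best, unpenalized
    return best
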