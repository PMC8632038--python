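"""Differential-expression pair weights and prior-knowledge penalty weights.

Two kinds of side information reweight the sparsity penalty:

* per-gene differential-expression levels ``r_i`` in [0, 1], from a
  two-sided Wilcoxon rank-sum test between the groups, combined per gene
  pair as ``tau_ij = 1 - (1 - r_i)(1 - r_j)`` so a pair is up-weighted as
  soon as either endpoint is differentially expressed;
* a prior weight matrix W built from known gene-gene interactions (matrix
  G) and co-pathway membership (matrix F): known interactions get a small
  penalty weight w_g < 1, same-pathway pairs weight 1, and cross-pathway
  pairs a large weight w_f > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .nonparanormal import ExpressionMatrix

__all__ = [
    "DEFAULT_WG",
    "DEFAULT_WF",
    "PriorKnowledge",
    "DEWeights",
    "wilcoxon_de_level",
    "pair_weight",
    "build_prior_weights",
    "copathway_matrix",
    "interaction_matrix",
    "compute_de_weights",
]

logger = logging.getLogger(__name__)

DEFAULT_WG = 0.3
DEFAULT_WF = 10.0


def wilcoxon_de_level(x1, x2, mapping: str = "one_minus_p") -> float:
    """Differential-expression level of one gene from a rank-sum test.

    Uses the two-sided Wilcoxon rank-sum (Mann-Whitney) test with the
    normal approximation and tie correction, no continuity correction, so
    perfectly balanced rank sums give p = 1 exactly. The p-value is mapped
    to [0, 1] as ``1 - p`` (default) or a capped ``-log10(p) / 10``.
    All-constant pooled input returns 0.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    x1 = x1[np.isfinite(x1)]
    x2 = x2[np.isfinite(x2)]
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 recorded values")
    pooled = np.concatenate([x1, x2])
    if np.ptp(pooled) == 0:
        return 0.0
    res = stats.mannwhitneyu(
        x1, x2, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    p = float(res.pvalue)
    if not np.isfinite(p):
        return 0.0
    if mapping == "one_minus_p":
        r = 1.0 - p
    elif mapping == "neg_log10_p":
        r = min(-np.log10(max(p, 1e-10)), 10.0) / 10.0
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    return float(min(max(r, 0.0), 1.0))


def pair_weight(r_i: float, r_j: float) -> float:
    """Combine two DE levels: 1 - (1 - r_i)(1 - r_j)."""
    if not (0.0 <= r_i <= 1.0 and 0.0 <= r_j <= 1.0):
        raise ValueError("DE levels must lie in [0, 1]")
    return 1.0 - (1.0 - r_i) * (1.0 - r_j)


@dataclass
class DEWeights:
    """Per-platform DE levels r (K x p) and pairwise weights (K x p x p)."""

    r: np.ndarray
    pair_weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        if np.any(self.r < 0) or np.any(self.r > 1):
            raise ValueError("DE levels must lie in [0, 1]")
        K, p = self.r.shape
        pw = np.empty((K, p, p))
        for k in range(K):
            one_minus = 1.0 - self.r[k]
            pw[k] = 1.0 - np.outer(one_minus, one_minus)
        self.pair_weights = pw

    @property
    def n_platforms(self) -> int:
        return self.r.shape[0]


def compute_de_weights(
    data: Sequence[ExpressionMatrix], mapping: str = "one_minus_p"
) -> DEWeights:
    """Wilcoxon DE levels per platform from the raw recorded values.

    Zeros are kept in the test: in dropout data part of the DE signal lives
    in the zero rates themselves.
    """
    by_platform: dict[int, dict[int, ExpressionMatrix]] = {}
    for X in data:
        by_platform.setdefault(X.platform_label, {})[X.group_label] = X
    platforms = sorted(by_platform)
    if platforms != list(range(1, len(platforms) + 1)):
        raise ValueError("platform labels must be 1..K")
    p = data[0].n_genes
    r = np.zeros((len(platforms), p))
    for k in platforms:
        groups = by_platform[k]
        if set(groups) != {1, 2}:
            raise ValueError(f"platform {k} needs both groups")
        x1, x2 = groups[1].values, groups[2].values
        for i in range(p):
            r[k - 1, i] = wilcoxon_de_level(x1[:, i], x2[:, i], mapping=mapping)
    return DEWeights(r)


def build_prior_weights(
    G: np.ndarray, F: np.ndarray, w_g: float = DEFAULT_WG, w_f: float = DEFAULT_WF
) -> np.ndarray:
    """Prior weight matrix: w_g on known interactions, 1 within pathways,
    w_f across pathways."""
    G = np.asarray(G)
    F = np.asarray(F)
    if G.shape != F.shape or G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G and F must be square matrices of the same size")
    for name, M in (("G", G), ("F", F)):
        if not np.array_equal(M, M.T):
            raise ValueError(f"{name} must be symmetric")
        if not np.isin(M, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    W = np.where(G == 1, w_g, np.where(F == 1, 1.0, w_f))
    return 0.5 * (W + W.T)


def copathway_matrix(
    pathways: "Iterable[Iterable[str]] | Mapping[str, Iterable[str]]",
    gene_ids: Sequence[str],
) -> np.ndarray:
    """Binary co-membership matrix: F_ij = 1 iff i, j share a pathway."""
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("empty gene universe")
    index = {g: i for i, g in enumerate(gene_ids)}
    if isinstance(pathways, Mapping):
        sets = list(pathways.values())
    else:
        sets = list(pathways)
    p = len(gene_ids)
    F = np.zeros((p, p), dtype=int)
    unmapped: set[str] = set()
    for members in sets:
        idx = []
        for g in members:
            if g in index:
                idx.append(index[g])
            else:
                unmapped.add(g)
        idx = np.asarray(sorted(set(idx)), dtype=int)
        if idx.size >= 2:
            F[np.ix_(idx, idx)] = 1
    np.fill_diagonal(F, 0)
    if unmapped:
        logger.warning(
            "%d pathway members not in the gene universe were ignored", len(unmapped)
        )
    return F


def interaction_matrix(
    edges: Iterable[tuple[str, str]], gene_ids: Sequence[str]
) -> np.ndarray:
    """Binary interaction matrix G from a list of gene-identifier pairs.

    Pairs referencing genes outside the universe are dropped with a warning.
    """
    gene_ids = list(gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    p = len(gene_ids)
    G = np.zeros((p, p), dtype=int)
    dropped = 0
    for a, b in edges:
        if a in index and b in index and a != b:
            i, j = index[a], index[b]
            G[i, j] = G[j, i] = 1
        else:
            dropped += 1
    if dropped:
        logger.warning("%d prior interactions referenced unknown genes", dropped)
    return G


@dataclass
class PriorKnowledge:
    """Prior interaction matrix G, co-pathway matrix F and weights w_g, w_f."""

    G: np.ndarray
    F: np.ndarray
    w_g: float = DEFAULT_WG
    w_f: float = DEFAULT_WF
    gene_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=int)
        self.F = np.asarray(self.F, dtype=int)
        # validates symmetry / binarity as a side effect
        build_prior_weights(self.G, self.F, self.w_g, self.w_f)

    @property
    def W(self) -> np.ndarray:
        return build_prior_weights(self.G, self.F, self.w_g, self.w_f)

    @classmethod
    def uninformative(cls, p: int, gene_ids: Sequence[str] | None = None) -> "PriorKnowledge":
        """W identically 1 (no interactions, everything co-pathway)."""
        return cls(np.zeros((p, p), dtype=int), np.ones((p, p), dtype=int), gene_ids=gene_ids)
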