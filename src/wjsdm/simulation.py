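"""Synthetic ground truth and expression data for the recovery study.

The generator emulates the study conditions of the simulation protocol:

* three pathways of 0.4 p genes each, the second and third sharing 0.2 p
  genes; a scale-free (preferential attachment, one edge per arriving node)
  support is grown inside each pathway and the union forms a state-1
  skeleton shared by all K platforms;
* 10% of each pathway's edges become differential, sampled with 3x weight
  for edges incident to the differentially expressed (DE) gene set (30% of
  genes); 10% of the differential set is platform-specific; differential
  edges are realized half as deletions (present in state 1 only) and half
  as additions (present in state 2 only) — no differential edge ever joins
  genes from disjoint pathways;
* off-diagonal weights are drawn uniformly from +-[0.5, 1.0]; positive
  definiteness comes from setting each diagonal to the row's absolute
  off-diagonal sum plus 0.1 (strict diagonal dominance) followed by a
  symmetric rescaling to unit diagonal;
* expression is multivariate normal with covariance Theta^-1, DE genes
  mean-shifted in group 2, and each entry is independently zeroed
  (dropout-style missingness) with probability tau;
* the prior network G samples a fraction delta of the union of the six
  true supports.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import networkx as nx
import numpy as np

from .nonparanormal import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "pathway_structure",
    "generate_truth",
    "sample_expression",
    "sample_prior",
    "simulate_scenario",
]

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


@dataclass
class SimulationConfig:
    p: int = 100
    K: int = 3
    n: int = 100
    missing_rate: float = 0.6
    prior_rate: float = 0.1
    diff_edge_frac: float = 0.10
    platform_specific_frac: float = 0.10
    de_gene_frac: float = 0.30
    de_mean_shift: float = 0.8
    de_bias: float = 3.0  # sampling weight multiplier for DE-incident edges
    edge_weight_range: tuple[float, float] = (0.5, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 10:
            raise ValueError("p must be at least 10")
        if self.K < 1 or self.n < 2:
            raise ValueError("need K >= 1 platforms and n >= 2 samples")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for name in ("prior_rate", "diff_edge_frac", "platform_specific_frac", "de_gene_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.edge_weight_range
        if not 0.0 < lo <= hi:
            raise ValueError("edge_weight_range must be a positive interval")


@dataclass
class SimulationTruth:
    precisions: np.ndarray  # (K, 2, p, p)
    true_deltas: np.ndarray  # (K, p, p)
    gene_ids: list
    pathways: list  # list of np.ndarray of gene indices
    de_genes: np.ndarray
    skeleton_edges: list  # state-agnostic pathway-union support
    diff_edges: list  # all designed differential edges
    diff_edges_by_pathway: list
    platform_specific_edges: dict  # platform (1-based) -> set of edges
    supports: np.ndarray = field(default=None)  # (K, 2, p, p) boolean

    @property
    def n_platforms(self) -> int:
        return self.precisions.shape[0]


def pathway_structure(p: int) -> list[np.ndarray]:
    """Three pathways of 0.4 p genes; pathways 2 and 3 share 0.2 p genes."""
    if p < 10:
        raise ValueError("p must be at least 10")
    if p % 10 != 0:
        logger.warning("p=%d not divisible by 10; pathway sizes are rounded", p)
    size = round(0.4 * p)
    overlap = round(0.2 * p)
    genes = np.arange(p)
    pw1 = genes[:size]
    pw2 = genes[size : 2 * size]
    pw3 = genes[2 * size - overlap :]
    return [pw1, pw2, pw3]


def _scale_free_edges(members: np.ndarray, rng: np.random.Generator) -> set[Edge]:
    if members.size < 2:
        raise ValueError("pathway needs at least 2 genes")
    g = nx.barabasi_albert_graph(members.size, 1, seed=int(rng.integers(2**31)))
    perm = rng.permutation(members)  # detach hub position from gene index
    return {tuple(sorted((int(perm[a]), int(perm[b])))) for a, b in g.edges}


def generate_truth(config: SimulationConfig, rng: "np.random.Generator | None" = None) -> SimulationTruth:
    """Build the 2K ground-truth precision matrices and their differences."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    p, K = config.p, config.K
    gene_ids = [f"G{i:04d}" for i in range(p)]
    pathways = pathway_structure(p)

    pathway_edges: list[list[Edge]] = []
    skeleton: set[Edge] = set()
    for pw in pathways:
        e = _scale_free_edges(pw, rng)
        pathway_edges.append(sorted(e))
        skeleton |= e

    n_de = ceil(config.de_gene_frac * p)
    de_genes = np.sort(rng.choice(p, size=n_de, replace=False))
    de_set = set(int(g) for g in de_genes)

    diff_by_pathway: list[list[Edge]] = []
    diff: list[Edge] = []
    seen: set[Edge] = set()
    for elist in pathway_edges:
        m = ceil(config.diff_edge_frac * len(elist))
        w = np.array(
            [config.de_bias if (i in de_set or j in de_set) else 1.0 for i, j in elist]
        )
        sel = rng.choice(len(elist), size=m, replace=False, p=w / w.sum())
        chosen = [elist[s] for s in sorted(sel)]
        diff_by_pathway.append(chosen)
        for e in chosen:
            if e not in seen:
                seen.add(e)
                diff.append(e)

    n_spec = ceil(config.platform_specific_frac * len(diff))
    spec_idx = rng.choice(len(diff), size=n_spec, replace=False)
    platform_specific: dict[int, set[Edge]] = {k: set() for k in range(1, K + 1)}
    specific_all: set[Edge] = set()
    for s in sorted(spec_idx):
        k = int(rng.integers(1, K + 1))
        platform_specific[k].add(diff[s])
        specific_all.add(diff[s])
    shared = [e for e in diff if e not in specific_all]

    order = rng.permutation(len(diff))
    half = len(diff) // 2
    deletions = {diff[i] for i in order[:half]}
    additions = {diff[i] for i in order[half:]}

    lo, hi = config.edge_weight_range
    weights = {
        e: float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])) for e in sorted(skeleton)
    }

    def build_precision(support: set[Edge]) -> np.ndarray:
        M = np.zeros((p, p))
        for i, j in support:
            M[i, j] = M[j, i] = weights[(i, j)]
        diag = np.abs(M).sum(axis=1) + 0.1
        scale = 1.0 / np.sqrt(diag)
        theta = M * np.outer(scale, scale)
        np.fill_diagonal(theta, 1.0)
        return theta

    state1_support = skeleton - additions  # shared across platforms
    precisions = np.zeros((K, 2, p, p))
    supports = np.zeros((K, 2, p, p), dtype=bool)
    for k in range(1, K + 1):
        diff_k = set(shared) | platform_specific[k]
        sup2 = (state1_support | (additions & diff_k)) - (deletions & diff_k)
        for c, sup in ((1, state1_support), (2, sup2)):
            theta = build_precision(sup)
            precisions[k - 1, c - 1] = theta
            supports[k - 1, c - 1] = np.abs(theta) > 0
    true_deltas = precisions[:, 1] - precisions[:, 0]

    return SimulationTruth(
        precisions=precisions,
        true_deltas=true_deltas,
        gene_ids=gene_ids,
        pathways=pathways,
        de_genes=de_genes,
        skeleton_edges=sorted(skeleton),
        diff_edges=diff,
        diff_edges_by_pathway=diff_by_pathway,
        platform_specific_edges=platform_specific,
        supports=supports,
    )


def sample_expression(
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: "np.random.Generator | None" = None,
) -> list[ExpressionMatrix]:
    """Draw n multivariate-normal samples per (platform, group), with dropout.

    Group 2 means are shifted by ``de_mean_shift`` on the DE genes; each
    entry is then zeroed independently with probability ``missing_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    K = truth.n_platforms
    p = truth.precisions.shape[2]
    out = []
    for k in range(1, K + 1):
        for c in (1, 2):
            cov = np.linalg.inv(truth.precisions[k - 1, c - 1])
            cov = 0.5 * (cov + cov.T)
            L = np.linalg.cholesky(cov)
            X = rng.standard_normal((config.n, p)) @ L.T
            if c == 2 and config.de_mean_shift != 0:
                X[:, truth.de_genes] += config.de_mean_shift
            if config.missing_rate > 0:
                lost = rng.random((config.n, p)) < config.missing_rate
                X[lost] = 0.0
            out.append(
                ExpressionMatrix(X, truth.gene_ids, group_label=c, platform_label=k)
            )
    return out


def sample_prior(
    truth: SimulationTruth,
    prior_rate: float,
    seed: "int | np.random.Generator | None" = None,
) -> np.ndarray:
    """Prior interaction matrix G: a fraction delta of the union support."""
    if not 0.0 <= prior_rate <= 1.0:
        raise ValueError("prior_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = truth.precisions.shape[2]
    union: set[Edge] = set()
    for k in range(truth.n_platforms):
        for c in range(2):
            sup = truth.supports[k, c]
            ii, jj = np.nonzero(np.triu(sup, 1))
            union |= {(int(a), int(b)) for a, b in zip(ii, jj)}
    union_sorted = sorted(union)
    G = np.zeros((p, p), dtype=int)
    if prior_rate > 0 and union_sorted:
        m = ceil(prior_rate * len(union_sorted))
        sel = rng.choice(len(union_sorted), size=m, replace=False)
        for s in sel:
            i, j = union_sorted[s]
            G[i, j] = G[j, i] = 1
    return G


def simulate_scenario(config: SimulationConfig):
    """Generate (truth, expression data, prior G) from one seed."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    truth = generate_truth(config, np.random.default_rng(children[0]))
    data = sample_expression(truth, config, np.random.default_rng(children[1]))
    G = sample_prior(truth, config.prior_rate, np.random.default_rng(children[2]))
    return truth, data, G
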