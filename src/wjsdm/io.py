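"""Plain-text format plumbing: expression TSV, prior edge lists, GMT, outputs.

Expression files are tab-separated with gene identifiers in the first row
and sample identifiers in the first column; empty cells parse as missing.
Prior interactions are two-column TSV gene pairs (any extra columns are
ignored). Pathways use the GMT convention: name, description, then member
genes, one pathway per line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nonparanormal import ExpressionMatrix
from .solver import SUPPORT_TOL, DifferentialNetworkSet

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_prior_edges",
    "read_gmt",
    "write_gmt",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_edge_list",
    "write_manifest",
]

logger = logging.getLogger(__name__)


def read_expression_tsv(
    path, group_label: int = 1, platform_label: int = 1, zeros_as_missing: bool = True
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(g) for g in df.columns],
        group_label=group_label,
        platform_label=platform_label,
        zeros_as_missing=zeros_as_missing,
    )


def write_expression_tsv(path, data: ExpressionMatrix) -> None:
    df = pd.DataFrame(
        data.values,
        index=[f"S{i:04d}" for i in range(data.n_samples)],
        columns=data.gene_ids,
    )
    df.to_csv(path, sep="\t")


def read_prior_edges(path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] and parts[1]:
                edges.append((parts[0], parts[1]))
    return edges


def read_gmt(path) -> dict[str, list[str]]:
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                pathways[parts[0]] = [g for g in parts[2:] if g]
    return pathways


def write_gmt(path, pathways: dict[str, Sequence[str]]) -> None:
    with open(path, "w") as fh:
        for name, members in pathways.items():
            fh.write("\t".join([name, "na", *map(str, members)]) + "\n")


def write_matrix_tsv(path, matrix: np.ndarray, gene_ids: Sequence[str]) -> None:
    pd.DataFrame(matrix, index=gene_ids, columns=gene_ids).to_csv(path, sep="\t")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(g) for g in df.columns]


def write_edge_list(path, network: DifferentialNetworkSet, tol: float = SUPPORT_TOL) -> None:
    """Per-platform differential edges (i < j) above the support threshold."""
    genes = list(network.gene_ids)
    rows = []
    for k in range(network.n_platforms):
        d = network.deltas[k]
        ii, jj = np.nonzero(np.triu(np.abs(d) > tol, 1))
        for i, j in zip(ii, jj):
            rows.append(
                {
                    "gene_i": genes[i],
                    "gene_j": genes[j],
                    "platform": k + 1,
                    "delta_value": d[i, j],
                }
            )
    pd.DataFrame(rows, columns=["gene_i", "gene_j", "platform", "delta_value"]).to_csv(
        path, sep="\t", index=False
    )


def write_manifest(path, payload: dict) -> None:
    """JSON manifest stamped with a hash of its own configuration."""
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload = dict(payload)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
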