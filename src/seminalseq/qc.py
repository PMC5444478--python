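"""Sample-relationship diagnostics: PCA and correlation-based clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ValidationError

__all__ = ["QCReport", "pca_samples", "hcluster_samples", "sample_qc"]


@dataclass
class QCReport:
    pc_scores: pd.DataFrame | None = None
    explained_variance: np.ndarray | None = None
    linkage: np.ndarray | None = None
    leaf_order: list[str] | None = None


def pca_samples(logexpr: pd.DataFrame, n_components: int | None = None) -> QCReport:
    """PCA of samples from a genes x samples log-expression matrix.

    Genes are centered (zero-variance genes dropped); the SVD of the centered
    matrix gives sample scores and explained-variance fractions.
    """
    if logexpr.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    X = logexpr.to_numpy(dtype=float)
    X = X[X.std(axis=1) > 0]
    Xc = X - X.mean(axis=1, keepdims=True)
    # samples as rows for the decomposition
    U, S, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    scores = U * S
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else var
    k = n_components or min(scores.shape[1], logexpr.shape[1])
    cols = [f"PC{i + 1}" for i in range(k)]
    return QCReport(
        pc_scores=pd.DataFrame(scores[:, :k], index=logexpr.columns, columns=cols),
        explained_variance=frac[:k],
    )


def hcluster_samples(expr: pd.DataFrame, linkage: str = "average") -> QCReport:
    """Agglomerative clustering of samples on 1 - Pearson correlation."""
    if expr.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = expr.columns[np.flatnonzero(sd == 0)[0]]
        raise ValidationError(f"sample {bad!r} has zero variance")
    R = np.corrcoef(X)
    D = np.clip(1.0 - R, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    order = hierarchy.leaves_list(Z)
    return QCReport(linkage=Z, leaf_order=[expr.columns[i] for i in order])


def sample_qc(logexpr: pd.DataFrame, linkage: str = "average") -> QCReport:
    """PCA plus hierarchical clustering in one report."""
    pca = pca_samples(logexpr)
    hc = hcluster_samples(logexpr, linkage=linkage)
    return QCReport(
        pc_scores=pca.pc_scores,
        explained_variance=pca.explained_variance,
        linkage=hc.linkage,
        leaf_order=hc.leaf_order,
    )
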