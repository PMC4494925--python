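"""Sample-structure discovery: PCA, clustering on components, gene scoring.

The zone gradient of the cohort is recovered by principal component
analysis of the expression matrix (samples as observations), hierarchical
clustering on the retained component scores (HCPC), and a per-gene
informativeness score — the absolute correlation of each gene with the
first principal component, used to reduce the matrix to its most
informative genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "PcaResult",
    "ClusterAssignment",
    "run_pca",
    "hcpc",
    "eigen_gene_score",
    "select_top_genes",
]


@dataclass
class PcaResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # genes x components
    variance_fraction: np.ndarray   # non-increasing, sums to <= 1
    centered: bool
    scaled: bool
    dropped_genes: list[str]
    data: pd.DataFrame              # the gene x sample matrix analysed


@dataclass
class ClusterAssignment:
    labels: pd.Series               # sample -> cluster in 1..k
    linkage: np.ndarray
    k: int
    n_components: int


def run_pca(X: pd.DataFrame, center: bool = True, scale: bool = True) -> PcaResult:
    """Exact SVD-based PCA of a gene x sample matrix (samples as observations).

    Genes are centered and optionally scaled to unit variance; constant
    genes are dropped with a warning when scaling.  Component signs are
    fixed so each loading vector's largest-magnitude entry is positive.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if X.isna().any().any():
        raise ValueError("missing values not allowed in PCA input")
    A = X.T.to_numpy(dtype=float)  # samples x genes
    genes = list(X.index)
    dropped: list[str] = []
    if scale:
        sd = A.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [g for g, k in zip(genes, keep) if not k]
            warnings.warn(f"dropping {len(dropped)} constant gene(s) before scaling")
            A = A[:, keep]
            genes = [g for g, k in zip(genes, keep) if k]
            sd = sd[keep]
    if center:
        A = A - A.mean(axis=0)
    if scale:
        A = A / sd
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    # fix signs: largest-|loading| entry positive per component
    for j in range(len(S)):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U * S
    total_var = (A ** 2).sum()
    var_frac = (S ** 2) / total_var if total_var > 0 else np.zeros_like(S)
    comps = [f"PC{j + 1}" for j in range(len(S))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.columns, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=genes, columns=comps),
        variance_fraction=var_frac,
        centered=center,
        scaled=scale,
        dropped_genes=dropped,
        data=X,
    )


def _default_n_components(var_frac: np.ndarray, coverage: float = 0.8,
                          cap: int = 10) -> int:
    cum = np.cumsum(var_frac)
    n = int(np.searchsorted(cum, coverage) + 1)
    return max(1, min(n, cap, len(var_frac)))


def hcpc(pca: PcaResult, k: int = 4, n_components: int | None = None) -> ClusterAssignment:
    """Hierarchical clustering (Ward, Euclidean) on retained PC scores.

    The tree is cut into exactly ``k`` clusters.  Cluster labels are
    renumbered by decreasing mean PC1 score of their members, so label 1
    always sits at the same end of the core->periphery axis.  By default
    the smallest number of components covering 80% of variance (capped at
    10) is retained.
    """
    if n_components is None:
        n_components = _default_n_components(pca.variance_fraction)
    if n_components > pca.scores.shape[1]:
        raise ValueError("n_components exceeds available components")
    n_samples = len(pca.scores)
    if k > n_samples:
        raise ValueError("k exceeds number of samples")
    S = pca.scores.iloc[:, :n_components].to_numpy()
    Z = hierarchy.linkage(S, method="ward", metric="euclidean")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    pc1 = pca.scores.iloc[:, 0].to_numpy()
    order = sorted(np.unique(flat), key=lambda g: -pc1[flat == g].mean())
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[g] for g in flat], index=pca.scores.index,
                       name="cluster")
    return ClusterAssignment(labels=labels, linkage=Z, k=int(labels.nunique()),
                             n_components=n_components)


def eigen_gene_score(pca: PcaResult) -> pd.Series:
    """Per-gene informativeness: |Pearson r| with the PC1 sample scores.

    Zero-variance genes score 0 (with a warning).  Scores lie in [0, 1].
    """
    X = pca.data.loc[pca.loadings.index]
    A = X.to_numpy(dtype=float)
    pc1 = pca.scores.iloc[:, 0].to_numpy()
    pc1c = pc1 - pc1.mean()
    Ac = A - A.mean(axis=1, keepdims=True)
    denom = np.sqrt((Ac ** 2).sum(axis=1)) * np.sqrt((pc1c ** 2).sum())
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance gene(s) scored 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac @ pc1c) / denom
    score = np.abs(np.where(zero, 0.0, r))
    return pd.Series(score, index=X.index, name="eigen_score")


def select_top_genes(scores: pd.Series, n: int = 8000) -> list[str]:
    """The ``n`` highest-scoring genes; ties broken by lexicographic gene id."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(scores):
        raise ValueError("n exceeds number of genes")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return order[:n]
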