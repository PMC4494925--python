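"""Signed weighted co-expression network analysis.

The gene-gene Pearson correlation matrix is mapped to a signed adjacency
``a_ij = ((1 + r_ij) / 2) ** beta`` (soft power, default 12), transformed
into topological overlap (a similarity that credits shared network
neighbors), and hierarchically clustered; modules are branches of the
dendrogram with at least ``min_module_size`` genes.  Each module is
summarized by its eigengene (first principal component of the module
submatrix); module membership (MM) is the correlation of any gene with an
eigengene, gene significance (GS) the -log10 adjusted ANOVA p against the
sample clusters, and a module is significant when its mean GS beats a
gene-label permutation null.  The "core" of a module is the upper MM
quartile of its members.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ModuleSet",
    "signed_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_membership",
    "gene_significance",
    "module_significance",
    "core_module",
    "build_module_set",
    "eigengene_dendrogram",
]

UNASSIGNED = "unassigned"


def _corr(X: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation (genes x samples input)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc ** 2).sum(axis=1))
    if (norm == 0).any():
        raise ValueError("zero-variance gene in correlation input")
    Xn = Xc / norm[:, None]
    r = Xn @ Xn.T
    np.clip(r, -1.0, 1.0, out=r)
    return r


def signed_adjacency(X: pd.DataFrame, beta: int = 12) -> pd.DataFrame:
    """Signed soft-threshold adjacency: ((1 + r) / 2) ** beta, unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if X.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    r = _corr(X.to_numpy(dtype=float))
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=X.index, columns=X.index)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a signed adjacency.

    TO_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu;
    TO_ii = 1.  Symmetric, in [0, 1].
    """
    A = adj.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    # unit diagonal assumed; l_ij excludes u in {i, j}
    L = A @ A - 2.0 * A  # subtracts the u=i and u=j terms (a_ii = a_jj = 1)
    k = A.sum(axis=0) - 1.0
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        to = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(to, 1.0)
    to = np.clip(0.5 * (to + to.T), 0.0, 1.0)
    return pd.DataFrame(to, index=adj.index, columns=adj.columns)


def detect_modules(to: pd.DataFrame, min_module_size: int = 175,
                   merge_threshold: float = 0.7,
                   quality_factor: float = 2.0,
                   shed_fraction: float = 0.5,
                   cut_height: float | None = None,
                   max_validate: int = 256) -> pd.Series:
    """Branch detection on the 1 - TO dendrogram with split validation.

    The topological-overlap dissimilarity is clustered by average linkage
    and the tree is explored from the root, with every structural decision
    validated against the TO data rather than raw merge heights:

    * a split of a branch into two sub-branches of at least
      ``min_module_size`` genes each is accepted when the mean
      between-branch TO falls below ``merge_threshold`` times the smaller
      within-branch mean — otherwise the branch is kept whole;
    * fragments smaller than ``min_module_size`` hanging off a branch are
      shed (left unassigned) while their mean TO to the branch core stays
      below ``shed_fraction`` of the core's internal mean — tightly
      attached late-joining members are kept;
    * a branch becomes a module only if it is cohesive: mean within TO
      above ``quality_factor`` times its mean TO to the remaining genes,
      which leaves structureless input almost entirely unassigned.

    Modules are labeled M1, M2, ... by decreasing size.  Passing
    ``cut_height`` switches to a simple static cut instead (maximal
    subtrees below that height, size-filtered).
    """
    n = to.shape[0]
    if min_module_size > n:
        raise ValueError("min_module_size exceeds number of genes")
    T = to.to_numpy(dtype=float)
    d = 1.0 - T
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    nn = 2 * n - 1
    left = np.zeros(nn, dtype=int)
    right = np.zeros(nn, dtype=int)
    dist = np.zeros(nn)
    count = np.ones(nn, dtype=int)
    for i in range(n - 1):
        v = n + i
        left[v], right[v] = int(Z[i, 0]), int(Z[i, 1])
        dist[v], count[v] = Z[i, 2], int(Z[i, 3])

    def _leaves(v: int) -> np.ndarray:
        out, st = [], [v]
        while st:
            u = st.pop()
            if u < n:
                out.append(u)
            else:
                st.extend((left[u], right[u]))
        return np.asarray(out, dtype=int)

    clusters: list[np.ndarray] = []

    if cut_height is not None:
        stack = [nn - 1]
        while stack:
            v = stack.pop()
            if count[v] < min_module_size:
                continue
            if dist[v] <= cut_height:
                clusters.append(_leaves(v))
            elif v >= n:
                stack.extend((left[v], right[v]))
    else:
        all_idx = np.arange(n)

        def _sample(idx: np.ndarray) -> np.ndarray:
            if len(idx) <= max_validate:
                return idx
            return idx[np.linspace(0, len(idx) - 1, max_validate).astype(int)]

        def _within(idx: np.ndarray) -> float:
            s = _sample(idx)
            blk = T[np.ix_(s, s)]
            m = len(s)
            return float((blk.sum() - m) / (m * (m - 1)))

        def _quality(idx: np.ndarray) -> bool:
            rest = np.setdiff1d(all_idx, idx, assume_unique=True)
            if len(rest) == 0:
                # a module is a proper subset with outside contrast; the
                # full gene set is never one module
                return False
            to_rest = float(T[np.ix_(_sample(idx), _sample(rest))].mean())
            return _within(idx) > quality_factor * to_rest

        stack = [nn - 1]
        while stack:
            v = stack.pop()
            candidate = -1
            while count[v] >= min_module_size:
                a, b = left[v], right[v]
                if count[a] >= min_module_size and count[b] >= min_module_size:
                    ia, ib = _sample(_leaves(a)), _sample(_leaves(b))
                    between = float(T[np.ix_(ia, ib)].mean())
                    if between < merge_threshold * min(_within(ia), _within(ib)):
                        stack.extend((a, b))
                    else:
                        candidate = v  # children belong together
                    break
                # chain node: one side is a small fragment
                small, big = (a, b) if count[a] < count[b] else (b, a)
                if count[big] < min_module_size:
                    candidate = v  # no further splittable core below
                    break
                core = _sample(_leaves(big))
                cross = float(T[np.ix_(_sample(_leaves(small)), core)].mean())
                if cross >= shed_fraction * _within(core) and _quality(_leaves(v)):
                    candidate = v  # fragment is a tight late-joining member
                    break
                v = big  # shed the fragment, keep walking down
            if candidate >= 0:
                idx = _leaves(candidate)
                if _quality(idx):
                    clusters.append(idx)

    clusters.sort(key=lambda c: (-len(c), int(c.min())))
    flat = np.full(n, UNASSIGNED, dtype=object)
    for i, c in enumerate(clusters):
        flat[c] = f"M{i + 1}"
    return pd.Series(flat, index=to.index, name="module")


def module_eigengene(X: pd.DataFrame, labels: pd.Series
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Module eigengenes and their variance explained.

    The eigengene is the first principal component (unit-norm sample
    vector) of the gene-standardized module submatrix, oriented to
    correlate positively with the module's mean expression profile.
    """
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    modules.sort(key=lambda m: (-(labels == m).sum(), m))
    eig = {}
    varexp = {}
    for m in modules:
        genes = labels.index[labels == m]
        sub = X.loc[genes].to_numpy(dtype=float)
        z = sub - sub.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        z = z / sd[:, None]
        U, S, Vt = np.linalg.svd(z.T, full_matrices=False)  # samples x genes
        e = U[:, 0]
        mean_profile = z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        eig[m] = e
        varexp[m] = float(S[0] ** 2 / (S ** 2).sum())
    eigengenes = pd.DataFrame(eig, index=X.columns)
    return eigengenes, pd.Series(varexp, name="variance_explained")


def module_membership(X: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """MM(g, m): Pearson r of every gene with every module eigengene."""
    A = X.to_numpy(dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    an = np.sqrt((Ac ** 2).sum(axis=1))
    E = eigengenes.to_numpy(dtype=float)
    Ec = E - E.mean(axis=0)
    en = np.sqrt((Ec ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        mm = (Ac @ Ec) / np.outer(an, en)
    mm[an == 0] = np.nan
    return pd.DataFrame(np.clip(mm, -1, 1), index=X.index,
                        columns=eigengenes.columns)


def gene_significance(adjusted_p: pd.Series, cap: float = 1e-16) -> pd.Series:
    """GS(g) = -log10(max(adjusted p, cap)); NA p propagates to NA GS."""
    p = adjusted_p.to_numpy(dtype=float)
    gs = np.where(np.isnan(p), np.nan, -np.log10(np.maximum(p, cap)))
    return pd.Series(gs, index=adjusted_p.index, name="gs")


def module_significance(gs: pd.Series, labels: pd.Series, n_perm: int = 1000,
                        alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Permutation test for zone-associated modules.

    The observed statistic is each module's mean GS; the null permutes GS
    values over genes ``n_perm`` times.  One-sided empirical p (high mean
    GS); significant iff p <= alpha.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    gs = gs.reindex(labels.index)
    rng = np.random.default_rng(seed)
    vals = gs.to_numpy(dtype=float)
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    modules.sort(key=lambda m: (-(labels == m).sum(), m))
    masks = {m: (labels == m).to_numpy() for m in modules}
    obs = {m: np.nanmean(vals[masks[m]]) for m in modules}
    exceed = {m: 0 for m in modules}
    for _ in range(n_perm):
        perm = rng.permutation(vals)
        for m in modules:
            if np.nanmean(perm[masks[m]]) >= obs[m]:
                exceed[m] += 1
    rows = []
    for m in modules:
        p = (1 + exceed[m]) / (n_perm + 1)
        rows.append({"module": m, "n_genes": int(masks[m].sum()),
                     "mean_gs": obs[m], "p": p, "significant": p <= alpha})
    return pd.DataFrame(rows).set_index("module")


def core_module(mm: pd.DataFrame, labels: pd.Series) -> dict[str, list[str]]:
    """Upper MM quartile of each module: the ceil(n/4) genes with highest
    own-module membership, ties broken by gene id."""
    cores: dict[str, list[str]] = {}
    for m in (x for x in labels.unique() if x != UNASSIGNED):
        genes = list(labels.index[labels == m])
        if not genes:
            raise ValueError(f"empty module {m}")
        ranked = sorted(genes, key=lambda g: (-mm.loc[g, m], g))
        cores[m] = ranked[: ceil(len(genes) / 4)]
    return cores


@dataclass
class ModuleSet:
    labels: pd.Series
    eigengenes: pd.DataFrame
    variance_explained: pd.Series
    mm: pd.DataFrame
    gs: pd.Series
    stats: pd.DataFrame             # mean GS, permutation p, significant flag
    cores: dict[str, list[str]]

    @property
    def significant_modules(self) -> list[str]:
        return list(self.stats.index[self.stats["significant"]])


def build_module_set(X: pd.DataFrame, labels: pd.Series, adjusted_p: pd.Series,
                     n_perm: int = 1000, alpha: float = 0.05,
                     seed: int = 0) -> ModuleSet:
    """Assemble eigengenes, MM, GS, significance and cores for a labeling."""
    eigengenes, varexp = module_eigengene(X, labels)
    mm = module_membership(X, eigengenes)
    gs = gene_significance(adjusted_p.reindex(labels.index))
    stats = module_significance(gs, labels, n_perm=n_perm, alpha=alpha, seed=seed)
    cores = core_module(mm, labels)
    return ModuleSet(labels, eigengenes, varexp, mm, gs, stats, cores)


def eigengene_dendrogram(eigengenes: pd.DataFrame) -> np.ndarray:
    """Convenience: average-linkage tree of eigengenes on 1 - r distance."""
    r = np.corrcoef(eigengenes.to_numpy().T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return hierarchy.linkage(squareform(d, checks=False), method="average")
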