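"""Key-gene signature construction and transcriptional subtype assignment.

The heterogeneity signature takes, from each significant co-expression
module, the differentially expressed member genes that jointly rank best
on PCA informativeness and own-module membership (rank product), 25 per
module by default.  Samples are assigned to transcriptional subtypes
(Proneural, Neural, Classical, Mesenchymal) either by a single-sample
enrichment score over subtype gene sets or by correlation with subtype
centroids; the per-patient diversity of assigned subtypes across biopsy
zones quantifies intratumor subtype heterogeneity.  A delta-delta-Ct
helper supports qPCR validation of signature genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .network import ModuleSet
from .structure import ClusterAssignment

__all__ = [
    "KeySignature",
    "SubtypeAssignment",
    "select_key_genes",
    "signature_structure_check",
    "subtype_scores",
    "assign_subtype",
    "ddct",
]


@dataclass
class KeySignature:
    table: pd.DataFrame          # gene, module, eigen_score, mm, de, [anticorr]
    per_module: int
    complete: bool               # False when some module had < per_module candidates

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def _dense_rank_desc(values: pd.Series) -> pd.Series:
    """Rank with 1 = largest; ties share the average rank."""
    return values.rank(ascending=False, method="average")


def select_key_genes(eigen_scores: pd.Series, de_table: pd.DataFrame,
                     module_set: ModuleSet, per_module: int = 25,
                     anticorr_flags: pd.Series | None = None) -> KeySignature:
    """Top rank-product genes per significant module, DE-filtered.

    Within each significant module, candidates are the DE-flagged member
    genes; they are ranked by the product of their (descending) eigen-score
    rank and own-module MM rank and the best ``per_module`` are taken,
    ties broken by gene id.  Modules are concatenated in label order.  A
    module with fewer than ``per_module`` DE candidates contributes all of
    them, with a warning, and the signature is flagged incomplete.
    """
    rows = []
    complete = True
    for m in sorted(module_set.significant_modules):
        members = module_set.labels.index[module_set.labels == m]
        de_flags = de_table["de"].reindex(members).fillna(False).astype(bool)
        candidates = list(members[de_flags.to_numpy()])
        if len(candidates) < per_module:
            warnings.warn(f"module {m}: only {len(candidates)} DE candidates "
                          f"(< {per_module}); taking all")
            complete = False
        es = eigen_scores.reindex(candidates)
        mm = module_set.mm.loc[candidates, m]
        rank_prod = _dense_rank_desc(es) * _dense_rank_desc(mm)
        chosen = sorted(candidates, key=lambda g: (rank_prod[g], g))[:per_module]
        for g in chosen:
            rows.append({
                "gene": g, "module": m,
                "eigen_score": float(es[g]), "mm": float(mm[g]),
                "de": True,
                "anticorr": bool(anticorr_flags.get(g, False))
                if anticorr_flags is not None else False,
            })
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["module", "eigen_score", "mm", "de", "anticorr"])
    return KeySignature(table=table, per_module=per_module, complete=complete)


@dataclass
class StructureCheck:
    sample_order: list[str]
    gene_order: list[str]
    labels: pd.Series
    ari: float


def signature_structure_check(X: pd.DataFrame, signature_genes: list[str],
                              reference: ClusterAssignment) -> StructureCheck:
    """Does clustering on the signature reproduce the reference structure?

    Samples are hierarchically clustered (Pearson correlation distance,
    average linkage) on the signature submatrix and the tree is cut to the
    reference k; the adjusted Rand index against the reference assignment
    is returned, together with leaf orders for display.
    """
    if not signature_genes:
        raise ValueError("empty signature")
    sub = X.loc[signature_genes]
    if reference.k > sub.shape[1]:
        raise ValueError("reference k exceeds sample count")

    def _corr_linkage(M: np.ndarray) -> np.ndarray:
        r = np.corrcoef(M)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        d = np.maximum(d, 0.0)
        return hierarchy.linkage(squareform(0.5 * (d + d.T), checks=False),
                                 method="average")

    Zs = _corr_linkage(sub.T.to_numpy(dtype=float))
    flat = hierarchy.fcluster(Zs, t=reference.k, criterion="maxclust")
    labels = pd.Series(flat, index=sub.columns, name="signature_cluster")
    ref = reference.labels.reindex(sub.columns)
    ari = float(adjusted_rand_score(ref.to_numpy(), flat))
    sample_order = [sub.columns[i] for i in hierarchy.leaves_list(Zs)]
    Zg = _corr_linkage(sub.to_numpy(dtype=float))
    gene_order = [signature_genes[i] for i in hierarchy.leaves_list(Zg)]
    return StructureCheck(sample_order, gene_order, labels, ari)


def _enrichment_score(ranked_weights: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov running-sum statistic (single sample).

    ``ranked_weights``: |z| weights in ranking order; ``in_set``: boolean
    membership in the same order.  Returns the running-sum value at its
    extremum (signed).
    """
    nh = in_set.sum()
    n = len(in_set)
    if nh == 0 or nh == n:
        raise ValueError("gene set empty or exhaustive after matching")
    w = np.where(in_set, ranked_weights, 0.0)
    wsum = w.sum()
    if wsum == 0:
        w = in_set.astype(float)
        wsum = float(nh)
    p_hit = np.cumsum(w) / wsum
    p_miss = np.cumsum(~in_set) / (n - nh)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def subtype_scores(X: pd.DataFrame,
                   gene_sets: dict[str, list[str]] | None = None,
                   centroids: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample subtype scores.

    Enrichment mode (``gene_sets``): genes are z-scored across samples,
    ranked per sample by decreasing z, and each subtype's score is the
    weighted KS running-sum enrichment of its gene set (weight |z|).
    Centroid mode (``centroids``, genes x subtypes): the score is the
    Pearson correlation of the sample's profile with each centroid over
    the centroid genes; a sample lying exactly on a centroid scores 1.
    """
    if (gene_sets is None) == (centroids is None):
        raise ValueError("provide exactly one of gene_sets or centroids")
    if centroids is not None:
        genes = centroids.index.intersection(X.index)
        if len(genes) < 3:
            raise ValueError("centroid genes do not overlap the matrix")
        sub = X.loc[genes].to_numpy(dtype=float)
        C = centroids.loc[genes].to_numpy(dtype=float)
        sc = sub - sub.mean(axis=0)
        cc = C - C.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (sc.T @ cc) / np.outer(
                np.sqrt((sc ** 2).sum(axis=0)), np.sqrt((cc ** 2).sum(axis=0)))
        return pd.DataFrame(r, index=X.columns, columns=centroids.columns)
    if len(gene_sets) < 2:
        raise ValueError("need at least 2 subtypes")
    A = X.to_numpy(dtype=float)
    mu = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (A - mu) / sd
    gene_index = {g: i for i, g in enumerate(X.index)}
    memberships = {}
    for name, gset in gene_sets.items():
        mask = np.zeros(len(X.index), dtype=bool)
        hits = [gene_index[g] for g in gset if g in gene_index]
        if not hits:
            raise ValueError(f"gene set {name!r} is disjoint from the matrix")
        mask[hits] = True
        memberships[name] = mask
    scores = np.empty((X.shape[1], len(gene_sets)))
    names = list(gene_sets)
    for s in range(X.shape[1]):
        order = np.argsort(-z[:, s], kind="mergesort")
        w = np.abs(z[order, s])
        for j, name in enumerate(names):
            scores[s, j] = _enrichment_score(w, memberships[name][order])
    return pd.DataFrame(scores, index=X.columns, columns=names)


@dataclass
class SubtypeAssignment:
    labels: pd.Series                   # sample -> subtype
    scores: pd.DataFrame
    patient_subtypes: pd.Series | None  # patient -> sorted tuple of subtypes


def assign_subtype(scores: pd.DataFrame,
                   annotation: pd.DataFrame | None = None) -> SubtypeAssignment:
    """Argmax subtype per sample; ties go to the first subtype in column order.

    With a sample annotation (``patient`` column), also reports the set of
    distinct subtypes observed across each patient's biopsies.
    """
    if scores.isna().all(axis=1).any():
        raise ValueError("sample with all-NA scores")
    vals = scores.to_numpy(dtype=float)
    best = np.nanargmax(vals, axis=1)
    # ties resolved toward the earliest column
    for i in range(len(best)):
        row = vals[i]
        top = np.nanmax(row)
        best[i] = int(np.flatnonzero(row == top)[0])
    labels = pd.Series([scores.columns[j] for j in best], index=scores.index,
                       name="subtype")
    patient_subtypes = None
    if annotation is not None:
        joined = annotation.join(labels)
        patient_subtypes = joined.groupby("patient")["subtype"].agg(
            lambda s: tuple(sorted(set(s))))
    return SubtypeAssignment(labels=labels, scores=scores,
                             patient_subtypes=patient_subtypes)


def ddct(ct_target_sample: float, ct_ref_sample: float,
         ct_target_calibrator: float, ct_ref_calibrator: float) -> float:
    """Relative expression by the delta-delta-Ct method.

    2 ** -[(Ct_target,sample - Ct_ref,sample)
           - (Ct_target,calibrator - Ct_ref,calibrator)].
    """
    ddc = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddc))
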