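"""Per-gene differential expression across sample clusters.

Welch's heteroscedastic one-way ANOVA is applied gene-wise across the
discovered clusters, p-values are adjusted by the Benjamini-Hochberg
step-up procedure, and pairwise fold changes are computed on the log2
scale.  A gene is called differentially expressed when its adjusted p is
below 0.001 and its maximal absolute fold change exceeds 2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["welch_anova", "bh_adjust", "fold_changes", "de_table"]

P_ADJ_THRESHOLD = 0.001
MIN_FOLD_CHANGE = 2.0


def _group_stats(X: pd.DataFrame, labels: pd.Series):
    labels = labels.reindex(X.columns)
    groups = sorted(labels.dropna().unique())
    A = X.to_numpy(dtype=float)
    ns, means, variances = [], [], []
    for g in groups:
        cols = np.flatnonzero((labels == g).to_numpy())
        sub = A[:, cols]
        ns.append(len(cols))
        means.append(sub.mean(axis=1))
        variances.append(sub.var(axis=1, ddof=1) if len(cols) > 1
                         else np.full(A.shape[0], np.nan))
    return groups, np.array(ns), np.vstack(means), np.vstack(variances)


def welch_anova(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Gene-wise Welch F test across groups.

    Returns a DataFrame (statistic, df1, df2, p) indexed by gene.  All
    genes are NA when any group has fewer than 2 samples; a gene with zero
    within-group variance in every group is NA.
    """
    groups, ns, means, variances = _group_stats(X, labels)
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n_genes = X.shape[0]
    out = pd.DataFrame(
        {"statistic": np.nan, "df1": np.nan, "df2": np.nan, "p": np.nan},
        index=X.index,
    )
    if (ns < 2).any():
        warnings.warn("a group has fewer than 2 samples; all genes reported NA")
        return out
    all_zero = (variances == 0).all(axis=0)
    if all_zero.any():
        warnings.warn(f"{int(all_zero.sum())} gene(s) with zero variance in all "
                      "groups reported NA")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = ns[:, None] / variances              # k x genes
        sw = w.sum(axis=0)
        mw = (w * means).sum(axis=0) / sw        # weighted grand mean
        num = (w * (means - mw) ** 2).sum(axis=0) / (k - 1)
        tmp = ((1.0 - w / sw) ** 2 / (ns[:, None] - 1)).sum(axis=0)
        denom = 1.0 + 2.0 * (k - 2) / (k ** 2 - 1.0) * tmp
        F = num / denom
        df2 = (k ** 2 - 1.0) / (3.0 * tmp)
    valid = ~all_zero & np.isfinite(F)
    # a zero-variance group with distinct mean drives F to infinity: p -> 0
    inf_F = ~all_zero & np.isinf(F)
    out.loc[X.index[valid], "statistic"] = F[valid]
    out.loc[X.index[valid], "df1"] = float(k - 1)
    out.loc[X.index[valid], "df2"] = df2[valid]
    out.loc[X.index[valid], "p"] = stats.f.sf(F[valid], k - 1, df2[valid])
    if inf_F.any():
        out.loc[X.index[inf_F], ["statistic", "df1", "df2", "p"]] = \
            [np.inf, float(k - 1), np.inf, 0.0]
    return out


def bh_adjust(p) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment; NAs are propagated.

    q_i = min over j >= i (sorted order) of p_j * m / j, capped at 1.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    vals = arr[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(vals)
    if m:
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.minimum(q, 1.0)
        adj = np.empty(m)
        adj[order] = q
        out[mask] = adj
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="p_adj")
    return out


def fold_changes(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Max pairwise fold change per gene on log2-scale expression.

    FC between clusters a, b is 2**|mean_a - mean_b|; the maximum over all
    cluster pairs is reported together with the attaining pair.
    """
    groups, ns, means, _ = _group_stats(X, labels)
    if (ns == 0).any():
        raise ValueError("empty cluster")
    k = len(groups)
    best = np.zeros(X.shape[0])
    best_pair = np.zeros(X.shape[0], dtype=int)
    pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
    for pi, (a, b) in enumerate(pairs):
        d = np.abs(means[a] - means[b])
        upd = d > best
        best[upd] = d[upd]
        best_pair[upd] = pi
    pair_names = [f"{groups[a]}-{groups[b]}" for a, b in pairs]
    return pd.DataFrame({
        "max_abs_log2_fc": best,
        "fold_change": 2.0 ** best,
        "pair": [pair_names[i] for i in best_pair],
    }, index=X.index)


def de_table(X: pd.DataFrame, labels: pd.Series,
             p_adj_threshold: float = P_ADJ_THRESHOLD,
             min_fc: float = MIN_FOLD_CHANGE) -> pd.DataFrame:
    """Full DE table: Welch ANOVA + BH + fold changes + DE flag."""
    anova = welch_anova(X, labels)
    anova["p_adj"] = bh_adjust(anova["p"])
    fc = fold_changes(X, labels)
    table = pd.concat([anova, fc], axis=1)
    table["de"] = (table["p_adj"] < p_adj_threshold) & (table["fold_change"] > min_fc)
    table.loc[table["p_adj"].isna(), "de"] = False
    return table
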