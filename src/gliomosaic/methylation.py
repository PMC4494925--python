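"""Methylome processing and expression-methylation anti-correlation.

Beta-values (the methylated fraction of signal at a CpG) are computed
from methylated/unmethylated intensities, missing entries are imputed by
k-nearest-neighbor averaging over CpG rows, per-gene Pearson correlations
between expression and methylation are screened at r < -0.6, and the
enrichment of anti-correlated genes among the most PCA-informative genes
is assessed against a resampling null (median and 99% CI of the
anti-correlated percentage in random gene subsets of the same size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

__all__ = [
    "ANTICORR_THRESHOLD",
    "BootstrapCurve",
    "beta_value",
    "impute_knn",
    "expr_meth_correlation",
    "anticorrelation_curve",
    "default_subset_sizes",
]

ANTICORR_THRESHOLD = -0.6


def beta_value(M, U):
    """Methylation beta: Max(M,0) / [Max(M,0) + Max(U,0) + 100].

    The +100 offset regularizes low-intensity probes; output lies in [0, 1).
    Accepts scalars or arrays.
    """
    m = np.maximum(np.asarray(M, dtype=float), 0.0)
    u = np.maximum(np.asarray(U, dtype=float), 0.0)
    out = m / (m + u + 100.0)
    return float(out) if out.ndim == 0 else out


def impute_knn(B: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing beta entries from the k nearest CpG rows.

    Distances are Euclidean over co-observed columns; the imputed value is
    the mean of the neighbors' entries at that column, clamped to [0, 1].
    """
    if B.isna().all(axis=1).any():
        raise ValueError("row with all values missing cannot be imputed")
    if k > len(B) - 1:
        raise ValueError("k must be smaller than the number of rows")
    if not B.isna().any().any():
        return B.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(B.to_numpy(dtype=float))
    return pd.DataFrame(np.clip(filled, 0.0, 1.0), index=B.index,
                        columns=B.columns)


def expr_meth_correlation(X: pd.DataFrame, B: pd.DataFrame,
                          threshold: float = ANTICORR_THRESHOLD) -> pd.DataFrame:
    """Per-gene Pearson r between expression and methylation.

    Computed over shared samples for genes present on both levels; pairs
    with missing beta are dropped per gene.  Genes with fewer than 3
    complete pairs or zero variance on either level get NA and are never
    flagged.  The anti-correlation flag is r < ``threshold``.
    """
    genes = X.index.intersection(B.index)
    samples = X.columns.intersection(B.columns)
    x = X.loc[genes, samples].to_numpy(dtype=float)
    b = B.loc[genes, samples].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(b)
    n = ok.sum(axis=1)
    xm = np.where(ok, x, 0.0)
    bm = np.where(ok, b, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = xm.sum(axis=1) / n
        mb = bm.sum(axis=1) / n
        xc = np.where(ok, x - mx[:, None], 0.0)
        bc = np.where(ok, b - mb[:, None], 0.0)
        cov = (xc * bc).sum(axis=1)
        denom = np.sqrt((xc ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
        r = cov / denom
    r[(n < 3) | (denom == 0) | ~np.isfinite(r)] = np.nan
    out = pd.DataFrame({"r": r, "n": n}, index=genes)
    out["anticorr"] = out["r"] < threshold
    out.loc[out["r"].isna(), "anticorr"] = False
    return out


def default_subset_sizes(n_genes: int) -> list[int]:
    """Evaluation grid: 100..1000 in steps of 10, then 50 log-spaced sizes
    up to the whole gene set."""
    sizes = list(range(100, min(1000, n_genes) + 1, 10))
    if n_genes > 1000:
        logs = np.unique(np.round(np.geomspace(1000, n_genes, 50)).astype(int))
        sizes.extend(int(s) for s in logs)
    sizes = sorted({s for s in sizes if s <= n_genes})
    if sizes[-1] != n_genes:
        sizes.append(n_genes)
    return sizes


@dataclass
class BootstrapCurve:
    table: pd.DataFrame      # size, observed, null_median, ci_low, ci_high, significant
    peak_size: int
    peak_percent: float
    ci: float
    n_boot: int


def anticorrelation_curve(flags: pd.Series, ranking: pd.Series,
                          subset_sizes: list[int] | None = None,
                          n_boot: int = 1000, ci: float = 0.99,
                          seed: int = 0) -> BootstrapCurve:
    """Anti-correlated percentage among top-ranked genes vs a resampling null.

    For each subset size n the observed value is the percentage of flagged
    genes among the top n of the ranking (descending score, ties by gene
    id).  The null re-draws n genes uniformly without replacement n_boot
    times; since the flagged count in such a draw is exactly
    hypergeometric, the draws are realized as hypergeometric samples.
    The null median and the equal-tailed CI at level ``ci`` are reported;
    a size is significant when the observed percentage exceeds the CI
    upper bound.  The peak is the size maximizing the observed percentage.
    """
    genes = flags.index.intersection(ranking.index)
    flags = flags.loc[genes].fillna(False).astype(bool)
    ranking = ranking.loc[genes]
    N = len(genes)
    K = int(flags.sum())
    if subset_sizes is None:
        subset_sizes = default_subset_sizes(N)
    if max(subset_sizes) > N:
        raise ValueError("subset size exceeds gene count")
    order = sorted(genes, key=lambda g: (-ranking[g], g))
    flag_arr = flags.loc[order].to_numpy()
    cum = np.cumsum(flag_arr)
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1.0 - ci) / 2.0, 1.0 - (1.0 - ci) / 2.0
    rows = []
    for n in subset_sizes:
        observed = 100.0 * cum[n - 1] / n
        null = 100.0 * rng.hypergeometric(K, N - K, n, size=n_boot) / n
        med, lo, hi = np.quantile(null, [0.5, lo_q, hi_q])
        rows.append({"size": n, "observed": observed, "null_median": med,
                     "ci_low": lo, "ci_high": hi,
                     "significant": observed > hi})
    table = pd.DataFrame(rows)
    peak_idx = int(table["observed"].idxmax())
    return BootstrapCurve(table=table,
                          peak_size=int(table.loc[peak_idx, "size"]),
                          peak_percent=float(table.loc[peak_idx, "observed"]),
                          ci=ci, n_boot=n_boot)
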