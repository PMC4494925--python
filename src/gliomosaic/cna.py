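"""Copy-number analysis: normalization, segmentation, calling, and recurrence.

A sample's track is an ordered table of genomic probes with log2
tumor/constitutional ratios.  The stage pipeline is:

1. :func:`normalize_track` — merge duplicate probes by median and subtract
   the weighted median so the baseline (copy-neutral) level sits at zero.
2. :func:`segment_track` — Haar-wavelet segmentation: breakpoints are local
   maxima of normalized Haar step coefficients across dyadic scales, kept
   under a per-scale FDR control.
3. :func:`call_segments` — assign each segment a discrete state
   (-1 loss, 0 normal, +1 gain, +2 amplification) from its mean log2 ratio.
4. :func:`percent_altered` — probe-weighted alteration percentages; samples
   below 1% altered are flagged as potential normal brain.
5. :func:`cluster_call_profiles` — Ward clustering of per-probe state
   vectors into altered vs unaltered-like groups.
6. :func:`find_mcr` — minimal common regions recurrently altered across
   samples, significance assessed by within-chromosome cyclic permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "CallThresholds",
    "CallProfile",
    "AlteredSummary",
    "weighted_median",
    "normalize_track",
    "segment_track",
    "call_segments",
    "percent_altered",
    "cluster_call_profiles",
    "find_mcr",
    "calls_to_seg",
    "mcr_to_bed",
]


@dataclass(frozen=True)
class CallThresholds:
    """Fixed log2-ratio thresholds for 4-state calling.

    Defaults approximate single-copy events at ~60% tumor purity:
    segments at or below ``t_loss`` are losses, at or above ``t_amp``
    amplifications, between ``t_gain`` and ``t_amp`` gains.
    """

    t_loss: float = -0.30
    t_gain: float = 0.30
    t_amp: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t_loss < 0 < self.t_gain < self.t_amp):
            raise ValueError("thresholds must satisfy t_loss < 0 < t_gain < t_amp")


@dataclass
class CallProfile:
    """Called segments plus the per-probe expanded state vector."""

    segments: pd.DataFrame  # chrom, start, end, n_probes, mean, state
    probes: pd.DataFrame    # chrom, pos, state


@dataclass
class AlteredSummary:
    percent_loss: float
    percent_gain: float
    percent_amp: float
    percent_normal: float
    is_non_tumor: bool

    @property
    def percent_altered(self) -> float:
        return 100.0 - self.percent_normal


def weighted_median(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half."""
    values = np.asarray(values, dtype=float)
    if weights is None:
        return float(np.median(values))
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="mergesort")
    cw = np.cumsum(weights[order])
    cutoff = 0.5 * cw[-1]
    idx = np.searchsorted(cw, cutoff)
    # exact half-mass between two values -> midpoint, matching the unweighted
    # even-length convention
    if np.isclose(cw[idx], cutoff) and idx + 1 < len(values):
        return float(0.5 * (values[order[idx]] + values[order[idx + 1]]))
    return float(values[order[idx]])


def normalize_track(track: pd.DataFrame,
                    weights: np.ndarray | None = None) -> pd.DataFrame:
    """Merge duplicate probe ids by median, sort, and center the array.

    Centering subtracts the weighted median of the log2 ratios (unit
    weights when none are supplied), so a copy-neutral genome sits at 0.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    t = track.copy()
    if weights is not None:
        if len(weights) != len(t):
            raise ValueError("weights length mismatch")
        t = t.assign(_w=np.asarray(weights, dtype=float))
    if t["probe"].duplicated().any():
        agg = {"chrom": "first", "pos": "first", "log2": "median"}
        if "_w" in t:
            agg["_w"] = "mean"
        t = t.groupby("probe", as_index=False, sort=False).agg(agg)
    t = t.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    w = t.pop("_w").to_numpy() if "_w" in t else None
    t["log2"] = t["log2"] - weighted_median(t["log2"].to_numpy(), w)
    return t


def _haar_breakpoints(y: np.ndarray, fdr_level: float, max_scale: int = 8) -> list[int]:
    """Breakpoint indices (segment starts) for one chromosome.

    At scale ``s`` (half-window ``h = 2**(s-1)``) the Haar coefficient at
    boundary ``i`` contrasts the ``h`` probes on each side.  Coefficients
    are z-scored against a robust noise estimate; per scale, candidate
    boundaries are kept by a step-up FDR rule and reduced to local maxima
    of |coefficient|.  Scales are unified fine-to-coarse: a coarse-scale
    breakpoint is kept only if no finer breakpoint lies within ``h``.
    """
    n = len(y)
    if n < 2:
        return []
    diffs = np.diff(y)
    sigma = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0)
    if sigma < 1e-12:
        # noise-free profile: exact step edges
        return [int(i) + 1 for i in np.flatnonzero(diffs != 0)]
    c = np.concatenate([[0.0], np.cumsum(y)])
    breakpoints: list[int] = []
    for s in range(1, max_scale + 1):
        h = 2 ** (s - 1)
        if 2 * h > n:
            break
        idx = np.arange(h, n - h + 1)
        w = ((c[idx + h] - c[idx]) - (c[idx] - c[idx - h])) / np.sqrt(2.0 * h)
        z = np.abs(w) / sigma
        p = 2.0 * stats.norm.sf(z)
        m = len(p)
        order = np.sort(p)
        passed = np.flatnonzero(order <= fdr_level * np.arange(1, m + 1) / m)
        if len(passed) == 0:
            continue
        pcut = order[passed[-1]]
        sig = p <= pcut
        absw = np.abs(w)
        for j in np.flatnonzero(sig):
            lo, hi = max(0, j - h), min(m, j + h + 1)
            if absw[j] < absw[lo:hi].max():
                continue
            if absw[j] == absw[lo:j].max(initial=-np.inf):
                continue  # plateau: keep the leftmost maximum only
            bp = int(idx[j])
            if all(abs(bp - b) > h for b in breakpoints):
                breakpoints.append(bp)
    return sorted(breakpoints)


def segment_track(track: pd.DataFrame, fdr_level: float = 0.05,
                  max_scale: int = 8) -> pd.DataFrame:
    """Per-chromosome Haar segmentation of a normalized track.

    Returns segments with columns chrom, start, end, n_probes, mean.
    A flat (or single-probe) chromosome yields exactly one segment.
    """
    if not 0.0 < fdr_level < 1.0:
        raise ValueError("fdr_level must lie in (0, 1)")
    rows = []
    for chrom, sub in track.groupby("chrom", sort=True):
        y = sub["log2"].to_numpy()
        pos = sub["pos"].to_numpy()
        bps = _haar_breakpoints(y, fdr_level, max_scale)
        bounds = [0, *bps, len(y)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(pos[a]), int(pos[b - 1]), b - a,
                         float(y[a:b].mean())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes", "mean"])


def call_segments(segments: pd.DataFrame,
                  thresholds: CallThresholds | None = None,
                  track: pd.DataFrame | None = None) -> CallProfile:
    """Assign states -1/0/+1/+2 to segments from their mean log2 ratio.

    When the normalized ``track`` the segments came from is supplied, the
    expanded per-probe state vector carries the probe positions, which
    :func:`find_mcr` uses to report genomic coordinates.
    """
    thresholds = thresholds or CallThresholds()
    m = segments["mean"].to_numpy()
    state = np.zeros(len(segments), dtype=int)
    state[m <= thresholds.t_loss] = -1
    state[m >= thresholds.t_gain] = 1
    state[m >= thresholds.t_amp] = 2
    seg = segments.assign(state=state)
    probes = pd.DataFrame({
        "chrom": np.repeat(seg["chrom"].to_numpy(), seg["n_probes"].to_numpy()),
        "state": np.repeat(state, seg["n_probes"].to_numpy()),
    })
    if track is not None:
        if len(track) != len(probes):
            raise ValueError("track does not match segment probe counts")
        probes.insert(1, "pos", track["pos"].to_numpy())
    return CallProfile(segments=seg, probes=probes)


def percent_altered(profile: CallProfile,
                    non_tumor_threshold: float = 1.0) -> AlteredSummary:
    """Probe-weighted alteration percentages and the <1%-altered rule."""
    s = profile.probes["state"].to_numpy()
    n = len(s)
    pct = lambda k: 100.0 * np.count_nonzero(s == k) / n
    loss, gain, amp = pct(-1), pct(1), pct(2)
    normal = 100.0 - loss - gain - amp
    return AlteredSummary(loss, gain, amp, normal,
                          is_non_tumor=(100.0 - normal) < non_tumor_threshold)


def cluster_call_profiles(call_matrix: pd.DataFrame):
    """Ward clustering of per-probe state vectors; 2-group cut.

    ``call_matrix`` is samples x probes of states.  Returns
    ``(linkage, clusters, unaltered_like)`` where ``clusters`` maps each
    sample to group 1 or 2 and ``unaltered_like`` is the group with the
    lower mean altered-percentage.
    """
    if len(call_matrix) < 2:
        raise ValueError("need at least 2 samples")
    X = call_matrix.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    flat = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    clusters = pd.Series(flat, index=call_matrix.index, name="cna_cluster")
    altered = (X != 0).mean(axis=1)
    means = {g: altered[flat == g].mean() for g in np.unique(flat)}
    unaltered_like = min(means, key=lambda g: (means[g], g))
    return Z, clusters, int(unaltered_like)


def find_mcr(call_profiles: dict[str, CallProfile], n_perm: int = 1000,
             alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Minimal common regions recurrently altered across samples.

    For losses (state < 0) and gains (state > 0) separately, and per
    chromosome: candidate regions are maximal probe runs whose cross-sample
    alteration frequency reaches the (1 - alpha) quantile of a null built
    by cyclically shifting each sample's calls within the chromosome
    (``n_perm`` shifts, preserving each sample's alteration load and
    segment lengths).  A region's empirical p is the fraction of
    permutations whose chromosome-wide maximum frequency reaches the
    region's minimum frequency; regions with p <= alpha are reported
    together with their minimal shared span (the probes attaining the
    run's maximum frequency).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable null")
    samples = list(call_profiles)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    first = call_profiles[samples[0]].probes
    chroms = first["chrom"].to_numpy()
    states = np.vstack([call_profiles[s].probes["state"].to_numpy() for s in samples])
    if states.shape[1] != len(chroms):
        raise ValueError("profiles are not on a shared probe grid")
    # probe genomic positions, if the grid carries them
    pos = first["pos"].to_numpy() if "pos" in first else np.arange(len(chroms))

    results = []
    for direction, name in ((states < 0, "loss"), (states > 0, "gain")):
        for chrom in pd.unique(chroms):
            cols = np.flatnonzero(chroms == chrom)
            M = direction[:, cols].astype(np.int8)
            L = M.shape[1]
            if L < 2 or not M.any():
                continue
            obs = M.mean(axis=0)
            offsets = rng.integers(0, L, size=(n_perm, len(samples)))
            base = np.arange(L)
            null_max = np.empty(n_perm)
            null_all = np.empty((n_perm, L), dtype=np.float32)
            for t in range(n_perm):
                idx = (base[None, :] - offsets[t][:, None]) % L
                freq = np.take_along_axis(M, idx, axis=1).mean(axis=0)
                null_all[t] = freq
                null_max[t] = freq.max()
            thresh = np.quantile(null_all.ravel(), 1.0 - alpha)
            hot = obs >= max(thresh, 1.0 / len(samples) + 1e-12)
            if not hot.any():
                continue
            # maximal runs of hot probes
            edges = np.diff(np.concatenate([[0], hot.view(np.int8), [0]]))
            starts = np.flatnonzero(edges == 1)
            ends = np.flatnonzero(edges == -1)
            for a, b in zip(starts, ends):
                run = obs[a:b]
                fmin, fmax = run.min(), run.max()
                pval = (1 + np.count_nonzero(null_max >= fmin)) / (n_perm + 1)
                if pval > alpha:
                    continue
                core = np.flatnonzero(run == fmax)
                results.append({
                    "chrom": chrom,
                    "start": int(pos[cols[a]]),
                    "end": int(pos[cols[b - 1]]),
                    "core_start": int(pos[cols[a + core[0]]]),
                    "core_end": int(pos[cols[a + core[-1]]]),
                    "n_probes": int(b - a),
                    "type": name,
                    "max_freq": float(fmax),
                    "min_freq": float(fmin),
                    "p": float(pval),
                })
    cols = ["chrom", "start", "end", "core_start", "core_end", "n_probes",
            "type", "max_freq", "min_freq", "p"]
    out = pd.DataFrame(results, columns=cols)
    return out.sort_values(["chrom", "start", "type"], kind="mergesort").reset_index(drop=True)


def calls_to_seg(profiles: dict[str, CallProfile]) -> pd.DataFrame:
    """SEG-like table: sample, chrom, loc.start, loc.end, num.mark, seg.mean, state."""
    rows = []
    for sample, prof in profiles.items():
        seg = prof.segments.copy()
        seg.insert(0, "sample", sample)
        rows.append(seg)
    out = pd.concat(rows, ignore_index=True)
    return out.rename(columns={"start": "loc.start", "end": "loc.end",
                               "n_probes": "num.mark", "mean": "seg.mean"})


def mcr_to_bed(mcr: pd.DataFrame) -> pd.DataFrame:
    """BED export of MCRs: 0-based half-open (1-based inclusive start-1, end)."""
    return pd.DataFrame({
        "chrom": mcr["chrom"].map(lambda c: f"chr{c}"),
        "chromStart": mcr["start"] - 1,
        "chromEnd": mcr["end"],
        "name": mcr["type"] + "_" + mcr["p"].map(lambda p: f"p{p:.4g}"),
    })
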