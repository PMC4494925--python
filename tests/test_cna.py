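"""Copy-number stage: normalization, segmentation, calling, clustering, MCRs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from gliomosaic import cna

from conftest import make_track


class TestNormalize:
    def test_constant_track_centers_to_zero(self):
        t = cna.normalize_track(make_track([0.3, 0.3, 0.3]))
        assert np.allclose(t["log2"], 0.0)

    def test_duplicate_probes_merged_by_median(self):
        t = make_track([1.0, 2.0, 9.0])
        t["probe"] = "same"
        out = cna.normalize_track(t)
        assert len(out) == 1
        # median 2 then centered: single probe -> 0
        assert out["log2"].iloc[0] == 0.0

    def test_idempotent_on_median_zero_track(self, rng):
        vals = rng.normal(0, 0.2, 101)
        vals -= np.median(vals)
        t = make_track(vals)
        out = cna.normalize_track(t)
        assert np.allclose(out["log2"], vals, atol=1e-12)

    def test_weighted_median_used_when_weights_given(self):
        t = make_track([0.0, 0.0, 5.0])
        out = cna.normalize_track(t, weights=np.array([1.0, 1.0, 100.0]))
        # weighted median is 5 -> that probe centered to 0
        assert out["log2"].iloc[2] == 0.0

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            cna.normalize_track(make_track([]))


def _ls_breakpoint(y):
    """Oracle: exhaustive single-breakpoint least squares."""
    n = len(y)
    best, best_i = np.inf, None
    for i in range(1, n):
        sse = ((y[:i] - y[:i].mean()) ** 2).sum() + ((y[i:] - y[i:].mean()) ** 2).sum()
        if sse < best:
            best, best_i = sse, i
    return best_i


class TestSegment:
    def test_flat_noiseless_signal_gives_one_segment_per_chromosome(self):
        t1 = make_track([0.1] * 50, chrom=1)
        t2 = make_track([-0.2] * 30, chrom=2)
        segs = cna.segment_track(pd.concat([t1, t2], ignore_index=True))
        assert len(segs) == 2
        assert set(segs["chrom"]) == {1, 2}

    def test_step_breakpoint_matches_least_squares_oracle(self, rng):
        y = np.concatenate([np.zeros(50), np.ones(50)]) + rng.normal(0, 0.1, 100)
        segs = cna.segment_track(make_track(y))
        assert len(segs) == 2
        found = segs["n_probes"].iloc[0]
        oracle = _ls_breakpoint(y)
        assert abs(found - oracle) <= 2
        assert abs(found - 50) <= 2

    def test_false_breakpoint_rate_under_pure_noise(self):
        rng = np.random.default_rng(0)
        extra = 0
        n_runs = 40
        for _ in range(n_runs):
            y = rng.normal(0, 0.2, 500)
            segs = cna.segment_track(make_track(y), fdr_level=0.05)
            extra += len(segs) - 1
        assert extra / n_runs <= 1.0

    def test_segment_means_are_probe_means(self, rng):
        y = np.concatenate([np.full(40, 1.0), np.full(60, -0.5)])
        segs = cna.segment_track(make_track(y))
        assert np.allclose(sorted(segs["mean"]), [-0.5, 1.0])
        assert segs["n_probes"].sum() == 100

    def test_reversed_track_yields_mirrored_segments(self, rng):
        y = np.concatenate([np.zeros(60), np.full(40, 0.9), np.zeros(30)])
        y = y + rng.normal(0, 0.1, len(y))
        fwd = cna.segment_track(make_track(y))
        rev = cna.segment_track(make_track(y[::-1]))
        assert sorted(fwd["n_probes"]) == sorted(rev["n_probes"])

    def test_invalid_fdr_rejected(self):
        with pytest.raises(ValueError):
            cna.segment_track(make_track([0.0] * 10), fdr_level=1.5)


class TestCall:
    def _segs(self, means):
        return pd.DataFrame({
            "chrom": 1, "start": np.arange(len(means)) * 10 + 1,
            "end": np.arange(len(means)) * 10 + 9,
            "n_probes": 5, "mean": means,
        })

    def test_threshold_application(self):
        prof = cna.call_segments(self._segs([0.0, -0.8, 1.6, 0.5, -0.31]))
        assert list(prof.segments["state"]) == [0, -1, 2, 1, -1]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            cna.CallThresholds(t_loss=0.1)
        with pytest.raises(ValueError):
            cna.CallThresholds(t_gain=1.2, t_amp=1.0)

    @given(hst.floats(-2, 2), hst.floats(0.01, 1.5))
    @settings(max_examples=50, deadline=None)
    def test_calling_is_monotone_in_segment_mean(self, m, delta):
        lo = cna.call_segments(self._segs([m])).segments["state"].iloc[0]
        hi = cna.call_segments(self._segs([m + delta])).segments["state"].iloc[0]
        assert hi >= lo

    def test_single_copy_loss_called_reliably(self):
        """Planted loss at log2 -0.42, 20 probes, noise 0.15: state -1 nearly always."""
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            y = np.concatenate([rng.normal(0, 0.15, 40),
                                rng.normal(-0.42, 0.15, 20),
                                rng.normal(0, 0.15, 40)])
            segs = cna.segment_track(make_track(y))
            prof = cna.call_segments(segs)
            if (prof.segments["state"] == -1).any():
                hits += 1
        assert hits / n_sim >= 0.95


class TestPercentAltered:
    def _profile(self, states):
        seg = pd.DataFrame({"chrom": 1, "start": 1, "end": 2,
                            "n_probes": 1, "mean": 0.0, "state": states})
        probes = pd.DataFrame({"chrom": 1, "state": states})
        return cna.CallProfile(segments=seg, probes=probes)

    def test_all_normal_flagged_non_tumor(self):
        s = cna.percent_altered(self._profile([0] * 200))
        assert s.percent_altered == 0.0 and s.is_non_tumor

    def test_half_loss(self):
        s = cna.percent_altered(self._profile([-1] * 100 + [0] * 100))
        assert s.percent_loss == 50.0 and not s.is_non_tumor

    def test_rule_boundary_half_percent_altered(self):
        s = cna.percent_altered(self._profile([1] * 1 + [0] * 199))  # 0.5%
        assert s.is_non_tumor

    @given(hst.lists(hst.sampled_from([-1, 0, 1, 2]), min_size=1, max_size=300))
    @settings(max_examples=50, deadline=None)
    def test_percentages_sum_to_100(self, states):
        s = cna.percent_altered(self._profile(states))
        total = s.percent_loss + s.percent_gain + s.percent_amp + s.percent_normal
        assert abs(total - 100.0) < 1e-9


class TestClusterProfiles:
    def test_identical_profiles_distance_zero(self):
        m = pd.DataFrame([[1, 0, -1]] * 2, index=["a", "b"])
        Z, clusters, _ = cna.cluster_call_profiles(m)
        assert Z[0, 2] == 0.0

    def test_altered_vs_normal_separate_perfectly(self, rng):
        template = rng.choice([-1, 1], size=100)
        altered = np.tile(template, (5, 1))
        flips = rng.random((5, 100)) < 0.1  # small private deviations
        altered[flips] = 0
        normal = np.zeros((5, 100), dtype=int)
        m = pd.DataFrame(np.vstack([altered, normal]),
                         index=[f"s{i}" for i in range(10)])
        _, clusters, unaltered = cna.cluster_call_profiles(m)
        assert clusters.iloc[:5].nunique() == 1
        assert clusters.iloc[5:].nunique() == 1
        assert clusters.iloc[0] != clusters.iloc[5]
        assert (clusters.iloc[5:] == unaltered).all()

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            cna.cluster_call_profiles(pd.DataFrame([[0, 1]]))


def _profile_from_states(states, chrom=1):
    probes = pd.DataFrame({"chrom": chrom, "pos": np.arange(len(states)) + 1,
                           "state": states})
    return cna.CallProfile(segments=pd.DataFrame(), probes=probes)


class TestMcr:
    def test_shared_focal_loss_found_with_minimal_p(self):
        states = np.zeros(200, dtype=int)
        states[80:90] = -1
        profiles = {f"s{i}": _profile_from_states(states.copy()) for i in range(6)}
        mcr = cna.find_mcr(profiles, n_perm=200, alpha=0.05, seed=0)
        assert len(mcr) == 1
        row = mcr.iloc[0]
        assert row["type"] == "loss"
        assert row["start"] <= 81 and row["end"] >= 90
        assert row["p"] <= 1 / 201 + 1e-12

    def test_all_normal_profiles_give_empty_list(self):
        profiles = {f"s{i}": _profile_from_states(np.zeros(100, dtype=int))
                    for i in range(4)}
        mcr = cna.find_mcr(profiles, n_perm=200, seed=0)
        assert len(mcr) == 0

    def test_single_altered_sample_not_reported(self):
        normal = np.zeros(200, dtype=int)
        hot = normal.copy()
        hot[50:70] = 1
        profiles = {"odd": _profile_from_states(hot)}
        profiles.update({f"s{i}": _profile_from_states(normal.copy())
                         for i in range(19)})
        mcr = cna.find_mcr(profiles, n_perm=200, alpha=0.05, seed=0)
        assert len(mcr) == 0

    def test_small_n_perm_rejected(self):
        profiles = {f"s{i}": _profile_from_states(np.zeros(10, dtype=int))
                    for i in range(2)}
        with pytest.raises(ValueError):
            cna.find_mcr(profiles, n_perm=50)


def test_seg_and_bed_export_roundtrip():
    y = np.concatenate([np.zeros(30), np.full(20, 1.6), np.zeros(30)])
    track = cna.normalize_track(make_track(y))
    prof = cna.call_segments(cna.segment_track(track), track=track)
    seg = cna.calls_to_seg({"s1": prof})
    assert {"sample", "chrom", "loc.start", "loc.end", "num.mark",
            "seg.mean", "state"} <= set(seg.columns)
    mcr = pd.DataFrame({"chrom": [7], "start": [1001], "end": [5000],
                        "type": ["gain"], "p": [0.01]})
    bed = cna.mcr_to_bed(mcr)
    assert bed["chromStart"].iloc[0] == 1000  # 0-based half-open
    assert bed["chromEnd"].iloc[0] == 5000
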