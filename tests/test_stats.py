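import math

import numpy as np
import pytest

import ciliatransport as ct
from ciliatransport.events import TransportEvent
from ciliatransport.stats import (
    compare_groups,
    event_frequencies,
    segment_restricted_velocities,
    velocity_stats,
)


def ev(direction, v, tid=0):
    return TransportEvent(trace_id=tid, direction=direction, velocity_um_s=v,
                          run_length_um=5.0, first_frame=0, last_frame=10)


class TestVelocityStats:
    def test_closed_form_mean_and_sem(self):
        events = [ev("anterograde", v, i) for i, v in enumerate([1.0, 2.0, 3.0])]
        st = velocity_stats(events, total_time_min=1.0)
        a = st.anterograde
        assert a.n == 3
        assert a.mean_velocity_um_s == pytest.approx(2.0)
        assert a.sem_velocity_um_s == pytest.approx(1.0 / math.sqrt(3))
        assert a.frequency_per_min == pytest.approx(3.0)
        assert st.retrograde.n == 0
        assert math.isnan(st.retrograde.mean_velocity_um_s)

    def test_single_event_sem_missing(self):
        st = velocity_stats([ev("retrograde", 0.8)], total_time_min=2.0)
        assert st.retrograde.mean_velocity_um_s == pytest.approx(0.8)
        assert math.isnan(st.retrograde.sem_velocity_um_s)
        assert st.retrograde.frequency_per_min == pytest.approx(0.5)

    def test_order_invariance(self):
        events = [ev("anterograde", v, i) for i, v in enumerate([0.5, 1.5, 2.5, 1.0])]
        a = velocity_stats(events, 1.0).anterograde
        b = velocity_stats(events[::-1], 1.0).anterograde
        assert a.mean_velocity_um_s == b.mean_velocity_um_s
        assert a.sem_velocity_um_s == b.sem_velocity_um_s
        assert np.array_equal(a.histogram_counts, b.histogram_counts)

    def test_histogram_binning_from_zero(self):
        st = velocity_stats([ev("anterograde", 0.31)], 1.0, bin_width_um_s=0.2)
        counts, edges = st.anterograde.histogram_counts, st.anterograde.histogram_edges_um_s
        assert edges[0] == 0.0
        assert counts[1] == 1  # 0.31 falls in [0.2, 0.4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            velocity_stats([], total_time_min=0.0)
        with pytest.raises(ValueError):
            velocity_stats([], total_time_min=1.0, bin_width_um_s=-0.1)


class TestEventFrequencies:
    def test_no_events(self):
        f = event_frequencies([], 10.0)
        assert f == {"anterograde": 0.0, "retrograde": 0.0}

    def test_published_counts_give_published_frequencies(self):
        events = [ev("anterograde", 1.0, i) for i in range(134)]
        events += [ev("retrograde", 0.8, 200 + i) for i in range(88)]
        f = event_frequencies(events, 34.0)
        assert f["anterograde"] == pytest.approx(134 / 34)
        assert f["retrograde"] == pytest.approx(88 / 34)

    def test_pooling_rule(self):
        # (10 min, 5 events) + (20 min, 10 events) -> 15/30
        events = [ev("anterograde", 1.0, i) for i in range(15)]
        assert event_frequencies(events, 30.0)["anterograde"] == pytest.approx(0.5)


class TestCompareGroups:
    def test_identical_samples_null(self):
        a = [ev("anterograde", v, i) for i, v in enumerate([1.0, 1.2, 1.4])]
        c = compare_groups(a, a, "anterograde")
        assert c.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert c.p_value == pytest.approx(1.0)
        assert c.ratio_of_means == pytest.approx(1.0)

    def test_closed_form_welch_example(self):
        a = [ev("anterograde", v, i) for i, v in enumerate([1.0, 2.0, 3.0])]
        b = [ev("anterograde", v, i) for i, v in enumerate([4.0, 5.0, 6.0])]
        c = compare_groups(a, b, "anterograde")
        assert c.t_statistic == pytest.approx(-3.674, abs=0.001)
        assert c.degrees_of_freedom == pytest.approx(4.0, abs=0.01)
        assert c.p_value == pytest.approx(0.0213, abs=0.001)
        assert c.ratio_of_means == pytest.approx(2.5)

    def test_welch_agrees_with_permutation(self):
        rng = np.random.default_rng(0)
        va = rng.normal(1.1, 0.3, 25)
        vb = rng.normal(0.8, 0.25, 20)
        a = [ev("anterograde", v, i) for i, v in enumerate(va)]
        b = [ev("anterograde", v, i) for i, v in enumerate(vb)]
        c = compare_groups(a, b, "anterograde")
        pooled = np.concatenate([va, vb])
        obs = abs(va.mean() - vb.mean())
        hits = 0
        n_perm = 20000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[:25].mean() - pooled[25:].mean()) >= obs:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        mc_err = 3 * math.sqrt(max(p_perm, c.p_value) / n_perm) + 2e-3
        assert abs(c.p_value - p_perm) <= max(0.3 * max(p_perm, c.p_value), mc_err)

    def test_insufficient_n_rejected(self):
        a = [ev("anterograde", 1.0)]
        with pytest.raises(ValueError, match=">= 2"):
            compare_groups(a, a, "anterograde")

    def test_t_sign_matches_mean_difference(self):
        a = [ev("anterograde", v, i) for i, v in enumerate([2.0, 2.2, 2.1])]
        b = [ev("anterograde", v, i) for i, v in enumerate([1.0, 1.1, 0.9])]
        c = compare_groups(a, b, "anterograde")
        assert c.t_statistic > 0
        assert c.ratio_of_means < 1


def segmented_trace(slope_pieces, start_pos=0.0, dt=0.5):
    """Trace + segments for a piecewise-constant-velocity particle."""
    frames, pos, f, p = [], [], 0, start_pos
    for n, slope in slope_pieces:
        for _ in range(n):
            frames.append(f)
            pos.append(p)
            p += slope * dt
            f += 1
    tr = ct.ParticleTrace(0, np.array(frames), np.array(pos))
    segs = ct.segment_trace(tr, frame_interval_s=dt)
    return tr, segs


class TestSegmentRestrictedVelocities:
    def test_uniform_speed_profile_equal_means(self):
        tr, segs = segmented_trace([(30, 0.6)])
        middle, distal = segment_restricted_velocities([(tr, segs)], 4.0,
                                                       path_length_um=9.0)
        assert middle.mean_velocity_um_s == pytest.approx(0.6, abs=0.02)
        assert distal.mean_velocity_um_s == pytest.approx(0.6, abs=0.02)

    def test_two_speed_profile_recovers_both(self):
        # 0.4 um/s below 4 um, 1.0 um/s above: the packaged IFT geometry
        tr, segs = segmented_trace([(20, 0.4), (7, 1.0)])
        middle, distal = segment_restricted_velocities([(tr, segs)], 4.0,
                                                       path_length_um=8.0)
        assert middle.mean_velocity_um_s == pytest.approx(0.4, abs=0.05)
        assert distal.mean_velocity_um_s == pytest.approx(1.0, abs=0.1)

    def test_segment_below_junction_leaves_distal_empty(self):
        tr, segs = segmented_trace([(10, 0.5)])  # spans 0 .. 2.25 um
        middle, distal = segment_restricted_velocities([(tr, segs)], 4.0,
                                                       path_length_um=9.0)
        assert middle.n == 1
        assert distal.n == 0
        assert math.isnan(distal.mean_velocity_um_s)

    def test_junction_outside_path_rejected(self):
        tr, segs = segmented_trace([(10, 0.5)])
        with pytest.raises(ValueError):
            segment_restricted_velocities([(tr, segs)], 12.0, path_length_um=9.0)


class TestParameterRecoveryAcrossSeeds:
    def test_recovered_anterograde_mean_is_unbiased(self):
        """Grand mean of recovered anterograde means over several short
        sessions lies close to the generator mean."""
        preset = ct.load_preset("WT").replace(duration_min=2.0)
        means = []
        for seed in range(6):
            sess = ct.run_transport_session(preset, seed=seed, n_movies=1)
            if sess.stats.anterograde.n >= 2:
                means.append(sess.stats.anterograde.mean_velocity_um_s)
        grand = float(np.mean(means))
        assert abs(grand - 1.11) < 0.09
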