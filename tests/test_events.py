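import numpy as np
import pytest

import ciliatransport as ct
from ciliatransport.events import (
    Candidate,
    classify_event,
    detect_candidates,
    link_traces,
    segment_trace,
    split_terminal_reversals,
)
from ciliatransport.kymograph import Kymograph


def kymo(values, step=0.1, dt=0.5):
    return Kymograph(np.asarray(values, dtype=float), step, dt)


def ridge_matrix(n_frames, n_cols, tracks, amplitude=100.0, background=0.0):
    """Noiseless kymograph with Gaussian ridges along given (col(t)) tracks."""
    vals = np.full((n_frames, n_cols), background)
    cols = np.arange(n_cols)
    for track in tracks:
        for t in range(n_frames):
            c = track(t)
            if 0 <= c <= n_cols - 1:
                vals[t] += amplitude * np.exp(-((cols - c) ** 2) / (2 * 1.5**2))
    return vals


class TestDetectCandidates:
    def test_zero_kymograph_has_no_candidates(self):
        cands = detect_candidates(kymo(np.zeros((6, 40))), min_prominence=1.0)
        assert all(row == [] for row in cands)

    def test_single_ridge_one_candidate_per_row(self):
        vals = ridge_matrix(8, 50, [lambda t: 20 + t])
        cands = detect_candidates(kymo(vals), min_prominence=10.0)
        for t, row in enumerate(cands):
            assert len(row) == 1
            assert row[0].position_um == pytest.approx((20 + t) * 0.1, abs=0.05)

    def test_close_ridges_keep_the_brighter(self):
        # two peaks 2 px apart with min_separation 0.4 um (4 px): one survives
        vals = np.zeros((1, 30))
        vals[0, 10] = 50.0
        vals[0, 12] = 80.0
        cands = detect_candidates(kymo(vals), min_prominence=10.0, min_separation_um=0.4)
        assert len(cands[0]) == 1
        assert cands[0][0].position_um == pytest.approx(1.2, abs=0.06)

    def test_matches_bruteforce_maxima_scan(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, (5, 25))
        vals[:, 7] += 5.0
        vals[:, 18] += 4.0
        k = kymo(vals)
        cands = detect_candidates(k, min_prominence=2.0, min_separation_um=0.3,
                                  flatten_background=False)
        flat = vals - np.median(vals)
        for t in range(5):
            row = vals[t]
            brute = [i for i in range(1, 24)
                     if row[i] >= row[i - 1] and row[i] >= row[i + 1]
                     and row[i] >= np.median(vals) + 2.0]
            got = sorted(round(c.position_um / 0.1) for c in cands[t])
            assert got == sorted(brute)

    def test_scale_covariance(self):
        """Multiplying intensities by c > 0 changes no candidate position."""
        vals = ridge_matrix(6, 40, [lambda t: 10 + 2 * t], background=5.0)
        vals += np.random.default_rng(1).uniform(0, 1, vals.shape)
        k1, k2 = kymo(vals), kymo(vals * 37.0)
        c1 = detect_candidates(k1)
        c2 = detect_candidates(k2)
        assert [[c.position_um for c in row] for row in c1] == \
               [[c.position_um for c in row] for row in c2]

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(ValueError):
            detect_candidates(kymo(np.ones((2, 5))), min_separation_um=0.0)


def cand_rows(tracks, n_frames, dropout=()):
    """Candidate lists for ideal tracks: track = callable t -> position_um."""
    rows = []
    for t in range(n_frames):
        row = []
        for k, track in enumerate(tracks):
            if (k, t) in dropout:
                continue
            p = track(t)
            if p is not None:
                row.append(Candidate(frame=t, position_um=p, intensity=100.0))
        rows.append(row)
    return rows


class TestLinkTraces:
    def test_two_parallel_ridges_two_traces(self):
        tracks = [lambda t: 1.0 + 0.4 * t, lambda t: 4.0 + 0.4 * t]
        traces = link_traces(cand_rows(tracks, 10), frame_interval_s=0.5)
        assert len(traces) == 2
        for tr in traces:
            d = np.diff(tr.positions_um)
            assert np.all(np.abs(d - 0.4) < 1e-9)  # no identity swaps

    def test_gap_closed_within_max_gap(self):
        traces = link_traces(
            cand_rows([lambda t: 1.0 + 0.3 * t], 10, dropout={(0, 4)}),
            max_gap_frames=2, frame_interval_s=0.5,
        )
        assert len(traces) == 1
        assert len(traces[0]) == 9

    def test_trace_ends_after_max_gap(self):
        rows = cand_rows([lambda t: 1.0 + 0.3 * t if (t < 3 or t > 7) else None], 12)
        traces = link_traces(rows, max_gap_frames=2, frame_interval_s=0.5)
        assert len(traces) == 2

    def test_simulated_particles_recover_ground_truth_assignments(self):
        tracks = [lambda t: 0.5 + 0.55 * t, lambda t: 9.0 - 0.4 * t, lambda t: 5.0 + 0.0 * t]
        traces = link_traces(cand_rows(tracks, 12), frame_interval_s=0.5)
        assert len(traces) == 3
        slopes = sorted(round(np.polyfit(tr.frames * 0.5, tr.positions_um, 1)[0], 2)
                        for tr in traces)
        assert slopes == [-0.8, 0.0, 1.1]

    def test_nonpositive_jump_rejected(self):
        with pytest.raises(ValueError):
            link_traces([[]], max_jump_um=0.0)


class TestSplitTerminalReversals:
    def test_v_at_path_origin_is_split(self):
        # retrograde arrival at 0 chained onto an anterograde departure
        frames = np.arange(12)
        pos = np.concatenate([np.linspace(3.0, 0.2, 6), np.linspace(0.5, 3.5, 6)])
        tr = ct.ParticleTrace(0, frames, pos)
        parts = split_terminal_reversals([tr], path_length_um=10.0)
        assert len(parts) == 2

    def test_mid_path_reversal_kept_whole(self):
        frames = np.arange(12)
        pos = np.concatenate([np.linspace(2.0, 5.0, 6), np.linspace(4.6, 2.0, 6)])
        tr = ct.ParticleTrace(0, frames, pos)
        parts = split_terminal_reversals([tr], path_length_um=10.0)
        assert len(parts) == 1


class TestSegmentTrace:
    def test_collinear_points_single_exact_segment(self):
        frames = np.arange(10)
        pos = 0.5 + 1.2 * frames * 0.5
        segs = segment_trace(ct.ParticleTrace(0, frames, pos), frame_interval_s=0.5)
        assert len(segs) == 1
        assert segs[0].slope_um_s == pytest.approx(1.2)
        assert segs[0].rms_residual_um == pytest.approx(0.0, abs=1e-9)
        assert segs[0].run_length_um == pytest.approx(1.2 * 9 * 0.5)

    def test_v_shape_split_near_vertex(self):
        """A +v then -v trace splits into two segments; the split point is
        within one point of the brute-force optimal split."""
        v, n = 1.0, 17
        frames = np.arange(n)
        pos = np.where(frames <= 8, v * frames * 0.5, v * 8 * 0.5 - v * (frames - 8) * 0.5)
        segs = segment_trace(ct.ParticleTrace(0, frames, pos), frame_interval_s=0.5)
        assert len(segs) == 2
        assert segs[0].slope_um_s == pytest.approx(v, abs=0.05)
        assert segs[1].slope_um_s == pytest.approx(-v, abs=0.05)
        # brute-force oracle: best single split by total residual
        best = min(
            range(4, n - 4),
            key=lambda k: (
                np.sum((pos[:k] - np.polyval(np.polyfit(frames[:k] * 0.5, pos[:k], 1),
                                             frames[:k] * 0.5)) ** 2)
                + np.sum((pos[k:] - np.polyval(np.polyfit(frames[k:] * 0.5, pos[k:], 1),
                                               frames[k:] * 0.5)) ** 2)
            ),
        )
        assert abs(segs[0].point_slice[1] - best) <= 1

    def test_pure_jitter_yields_no_segments(self):
        rng = np.random.default_rng(4)
        frames = np.arange(12)
        pos = rng.normal(0.0, 1.5, 12)  # independent 1.5 um jitter
        segs = segment_trace(ct.ParticleTrace(0, frames, pos), rho_um=0.15,
                             frame_interval_s=0.5)
        assert segs == []

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="points"):
            segment_trace(ct.ParticleTrace(0, [0, 1], [0.0, 0.5]), min_points=4)


def make_trace_and_segments(pieces, dt=0.5):
    """Build a trace from (n_points, slope) pieces and segment it."""
    frames, pos, f, p = [], [], 0, 0.0
    for n, slope in pieces:
        for _ in range(n):
            frames.append(f)
            pos.append(p)
            p += slope * dt
            f += 1
    tr = ct.ParticleTrace(0, np.array(frames), np.array(pos))
    return tr, segment_trace(tr, frame_interval_s=dt)


class TestClassifyEvent:
    def test_qualifying_run_scores_one_event(self):
        # 3.5 um at 1.2 um/s anterograde (needs ~6.8 frames): use 8 points
        tr, segs = make_trace_and_segments([(8, 1.2)])
        event = classify_event(tr, segs)
        assert event is not None
        assert event.direction == "anterograde"
        assert event.velocity_um_s == pytest.approx(1.2)
        assert event.run_length_um > 3.0

    def test_short_run_scores_nothing(self):
        tr, segs = make_trace_and_segments([(5, 1.0)])  # 2.0 um
        assert classify_event(tr, segs) is None

    def test_exact_threshold_excluded(self):
        # exactly 3.0 um: 1.0 um/s over 6 frame intervals of 0.5 s
        tr, segs = make_trace_and_segments([(7, 1.0)])
        assert segs[0].run_length_um == pytest.approx(3.0)
        assert classify_event(tr, segs) is None

    def test_longest_segment_wins(self):
        # 4 um at +1.0 then 6 um at -0.7: retrograde 0.7 wins
        tr, segs = make_trace_and_segments([(9, 1.0), (18, -0.7)])
        event = classify_event(tr, segs)
        assert event is not None
        assert event.direction == "retrograde"
        assert event.velocity_um_s == pytest.approx(0.7, abs=0.02)

    def test_at_most_one_event_per_trace(self):
        tr, segs = make_trace_and_segments([(12, 1.0), (12, -1.0)])
        events = [classify_event(tr, segs)]
        assert len([e for e in events if e]) <= 1


class TestEndToEndOnSimulation:
    def test_events_at_most_traces(self, busy_movie, busy_preset):
        movie, _, _ = busy_movie
        res = ct.analyze_movie(movie, ct.preset_path(busy_preset))
        assert len(res.events) <= len(res.traces_with_segments)

    def test_velocity_recovery_against_ground_truth(self, busy_movie, busy_preset):
        """Per-event velocity within max(0.05 um/s, 5%) of the matched
        ground-truth particle, for well-observed runs."""
        movie, ground_truth, _ = busy_movie
        res = ct.analyze_movie(movie, ct.preset_path(busy_preset))
        checked = 0
        for e in res.events:
            if e.last_frame - e.first_frame < 10:
                continue
            gmatch = [g for g in ground_truth
                      if g.direction == e.direction and g.entry_frame >= 0
                      and not (e.last_frame < g.entry_frame or e.first_frame > g.exit_frame)]
            if not gmatch:
                continue
            v_true = min((abs(g.true_velocity_um_s) for g in gmatch),
                         key=lambda v: abs(v - e.velocity_um_s))
            assert abs(e.velocity_um_s - v_true) <= max(0.05, 0.05 * v_true)
            checked += 1
        assert checked >= 3

    def test_detected_counts_match_ground_truth(self, busy_movie, busy_preset):
        movie, ground_truth, _ = busy_movie
        res = ct.analyze_movie(movie, ct.preset_path(busy_preset))
        n_true = sum(1 for g in ground_truth if g.run_length_um > 3)
        assert abs(len(res.events) - n_true) <= max(2, int(0.25 * n_true))

    def test_steadiness_tolerance_stability(self, busy_movie, busy_preset):
        """Event counts are stable for rho in [0.2, 0.5] um."""
        movie, _, _ = busy_movie
        counts = []
        for rho in (0.2, 0.3, 0.5):
            res = ct.analyze_movie(movie, ct.preset_path(busy_preset),
                                   detection=ct.DetectionParams(rho_um=rho))
            counts.append(len(res.events))
        assert max(counts) - min(counts) <= max(2, int(0.2 * max(counts)))
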