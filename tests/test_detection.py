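"""Sleep-period search, movement segmentation, cross-limb attribution."""

import numpy as np
import pandas as pd
import pytest

from limbacc.detection import (
    DetectionParams,
    attribute_limbs,
    find_sleep_period,
    segment_movements,
    vector_magnitude,
)
from limbacc.errors import ConfigurationError, LimbaccError
from limbacc.ingest import NightMeta
from limbacc.synthetic import bandlimited_burst
from limbacc.types import MovementEvent

from conftest import make_trace

FS = 30.0


def trace_with_bursts(onsets_s, durations_s, amplitude=0.3, fs=FS, total_s=3600.0, seed=3):
    """Gravity + faint noise + well-defined bursts at known onsets."""
    rng = np.random.default_rng(seed)
    n = int(total_s * fs)
    data = rng.normal(0, 0.005, size=(n, 3))
    data[:, 2] += 1.0
    for onset, dur in zip(onsets_s, durations_s):
        i0, m = int(onset * fs), int(dur * fs)
        data[i0 : i0 + m] += amplitude * bandlimited_burst(m, fs, rng)
    return make_trace(data, fs=fs)


class TestVectorMagnitude:
    @pytest.mark.parametrize("row,expected", [([0, 0, 1], 1.0), ([1, 2, 2], 3.0)])
    def test_known_values(self, row, expected):
        t = make_trace([row, row, row])
        assert vector_magnitude(t) == pytest.approx([expected] * 3)

    def test_matches_brute_force(self, rng):
        data = rng.normal(size=(100, 3))
        vm = vector_magnitude(make_trace(data))
        brute = [np.sqrt(x * x + y * y + z * z) for x, y, z in data]
        assert np.allclose(vm, brute)


class TestSleepPeriod:
    def test_reported_window_is_clipped_and_used(self, quiet_trace):
        start = quiet_trace.start_time + pd.Timedelta(minutes=10)
        end = quiet_trace.start_time + pd.Timedelta(minutes=40)
        meta = NightMeta("P1", 0, True, sleep_window=(start, end))
        s0, s1 = find_sleep_period(quiet_trace, meta)
        assert s0 == int(600 * FS) and s1 == int(2400 * FS)

    def test_quiescent_trace_without_metadata_returns_whole_trace(self):
        rng = np.random.default_rng(0)
        fs = 5.0
        n = int(8 * 3600 * fs)
        data = rng.normal(0, 0.004, size=(n, 3))
        data[:, 2] += 1.0
        trace = make_trace(data, fs=fs)
        s0, s1 = find_sleep_period(trace, None)
        assert s0 == 0 and s1 >= n - int(600 * fs)

    def test_quiescent_span_found_between_active_hours(self):
        rng = np.random.default_rng(1)
        fs = 5.0
        n = int(9 * 3600 * fs)
        data = rng.normal(0, 0.004, size=(n, 3))
        data[:, 2] += 1.0
        # sustained activity outside hours 2-7
        active = np.zeros(n, dtype=bool)
        active[: int(2 * 3600 * fs)] = True
        active[int(7 * 3600 * fs) :] = True
        data[active] += rng.normal(0, 0.15, size=(active.sum(), 3))
        s0, s1 = find_sleep_period(make_trace(data, fs=fs), None)
        assert abs(s0 / fs - 2 * 3600) < 600
        assert abs(s1 / fs - 7 * 3600) < 600

    def test_no_sleep_period_raises(self):
        rng = np.random.default_rng(2)
        fs = 5.0
        n = int(2 * 3600 * fs)
        data = rng.normal(0, 0.2, size=(n, 3))  # restless whole trace
        data[:, 2] += 1.0
        with pytest.raises(LimbaccError, match="no sleep period"):
            find_sleep_period(make_trace(data, fs=fs), None)


class TestSegmentation:
    def test_flat_trace_has_no_events(self, quiet_trace):
        events = segment_movements(quiet_trace, (0, quiet_trace.n_samples))
        assert events == []

    def test_recovers_constructed_bursts(self):
        onsets = [300.0, 360.0, 420.0]
        trace = trace_with_bursts(onsets, [2.0, 3.0, 1.5])
        events = segment_movements(trace, (0, trace.n_samples))
        assert len(events) == 3
        params = DetectionParams()
        for e, onset in zip(events, onsets):
            assert abs(e.start_idx / FS - onset) <= params.envelope_window_s + 0.5

    def test_close_bursts_merge(self):
        trace = trace_with_bursts([300.0, 302.3], [2.0, 1.0])  # 0.3 s gap
        events = segment_movements(trace, (0, trace.n_samples))
        assert len(events) == 1

    def test_short_blips_discarded(self):
        # the envelope window smears a 0.5-s blip to ~1.5 s; a 3-s floor drops it
        params = DetectionParams(min_duration_s=3.0)
        trace = trace_with_bursts([300.0], [0.5], amplitude=0.4)
        events = segment_movements(trace, (0, trace.n_samples), params)
        assert events == []

    def test_dc_offset_invariance(self):
        trace = trace_with_bursts([300.0, 400.0], [2.0, 2.0])
        shifted = make_trace(trace.data + np.array([0.3, -4.0, 2.0]), fs=FS)
        a = segment_movements(trace, (0, trace.n_samples))
        b = segment_movements(shifted, (0, shifted.n_samples))
        assert [(e.start_idx, e.end_idx) for e in a] == [(e.start_idx, e.end_idx) for e in b]

    def test_exact_recovery_regime(self):
        """100% recall and precision for strong, well-separated events."""
        params = DetectionParams()
        onsets = [120.0 + 25.0 * k for k in range(12)]  # gaps >> 2 x merge gap
        trace = trace_with_bursts(onsets, [2.0] * 12, amplitude=3.5 * params.threshold_g)
        events = segment_movements(trace, (0, trace.n_samples), params)
        assert len(events) == 12  # no misses, no false alarms
        for e, onset in zip(events, onsets):
            assert abs(e.start_idx / FS - onset) < 2.0

    def test_invalid_params_rejected(self, quiet_trace):
        with pytest.raises(ConfigurationError):
            segment_movements(quiet_trace, (0, 100), DetectionParams(threshold_g=0.0))

    def test_event_invariants(self):
        trace = trace_with_bursts([200.0, 300.0], [2.0, 4.0])
        events = segment_movements(trace, (0, trace.n_samples))
        for e in events:
            assert e.end_idx > e.start_idx
            assert e.duration_s == pytest.approx((e.end_idx - e.start_idx) / FS)
        for a, b in zip(events, events[1:]):
            assert a.end_idx <= b.start_idx  # pairwise disjoint, sorted


def _ev(limb, start, end, fs=FS):
    return MovementEvent(limbs={limb}, start_idx=start, end_idx=end, sampling_rate_hz=fs)


def brute_force_grouping(events, sync_window_s, fs=FS):
    """Transitive closure of the pairwise overlap/synchrony relation."""
    n = len(events)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            a, b = events[i], events[j]
            overlap = a.start_idx < b.end_idx and b.start_idx < a.end_idx
            sync = abs(a.start_idx - b.start_idx) <= sync_window_s * fs
            adj[i][j] = overlap or sync
    seen, groups = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        seen |= comp
        groups.append(comp)
    out = []
    for comp in groups:
        members = [events[k] for k in comp]
        out.append(
            (
                min(e.start_idx for e in members),
                max(e.end_idx for e in members),
                frozenset().union(*(e.limbs for e in members)),
            )
        )
    return sorted(out)


class TestAttribution:
    def test_simultaneous_ankle_events_become_bilateral(self):
        by_placement = {
            "left_ankle": [_ev("left_ankle", 1000, 1100)],
            "right_ankle": [_ev("right_ankle", 1000, 1100)],
        }
        combined = attribute_limbs(by_placement)
        assert len(combined) == 1
        assert combined[0].limbs == frozenset({"left_ankle", "right_ankle"})

    def test_distant_events_stay_separate(self):
        by_placement = {
            "left_ankle": [_ev("left_ankle", 0, 50)],
            "right_ankle": [_ev("right_ankle", 5000, 5050)],
        }
        combined = attribute_limbs(by_placement)
        assert len(combined) == 2
        assert all(len(e.limbs) == 1 for e in combined)

    def test_matches_brute_force_on_random_schedules(self, rng):
        for _ in range(30):
            by_placement = {}
            flat = []
            for limb in ("left_ankle", "right_ankle", "wrist"):
                starts = np.sort(rng.integers(0, 4000, size=rng.integers(0, 8)))
                events, last_end = [], -1
                for s in starts:
                    s = max(int(s), last_end + 1)
                    e = s + int(rng.integers(10, 120))
                    events.append(_ev(limb, s, e))
                    last_end = e
                by_placement[limb] = events
                flat.extend(events)
            combined = attribute_limbs(by_placement, sync_window_s=1.0)
            got = sorted((e.start_idx, e.end_idx, e.limbs) for e in combined)
            assert got == brute_force_grouping(flat, 1.0)
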