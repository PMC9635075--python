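"""Sleep-period identification and movement segmentation.

Movements are extracted from the gravity-free signal: each axis is high-pass
filtered with a zero-phase Butterworth filter, the vector magnitude of the
filtered axes is enveloped with a moving RMS, and an event is a maximal span
where the envelope exceeds a threshold, with hysteresis (the span extends
outward while the envelope stays above half the threshold). Events closer
than a merge gap are fused; events shorter than a minimum duration are
dropped. Events from different limbs whose spans overlap (or whose onsets
fall within a synchrony window) are grouped into multi-limb events.

Zero-phase filtering keeps detected onsets aligned with the raw signal, and
high-pass filtering makes the whole pipeline invariant to static gravity
(any DC offset on any axis).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError, LimbaccError
from .types import AccelTrace, MovementEvent


@dataclass(frozen=True)
class DetectionParams:
    """Segmentation parameters. Thresholds are in g on the moving-RMS envelope."""

    highpass_hz: float = 0.25
    filter_order: int = 4
    envelope_window_s: float = 0.5
    threshold_g: float = 0.05
    min_duration_s: float = 0.3
    merge_gap_s: float = 0.5
    sync_window_s: float = 1.0
    sleep_rms_threshold_g: float = 0.02
    sleep_rms_window_s: float = 600.0
    min_sleep_span_s: float = 7200.0

    def validate(self):
        if self.threshold_g <= 0:
            raise ConfigurationError("threshold_g must be positive")
        if self.min_duration_s <= 0:
            raise ConfigurationError("min_duration_s must be positive")
        if self.highpass_hz <= 0 or self.envelope_window_s <= 0:
            raise ConfigurationError("filter/envelope parameters must be positive")


def vector_magnitude(trace_or_array) -> np.ndarray:
    """Euclidean norm of the three axes, sample by sample, in g."""
    data = trace_or_array.data if isinstance(trace_or_array, AccelTrace) else np.asarray(trace_or_array)
    return np.sqrt(np.sum(data * data, axis=1))


@lru_cache(maxsize=32)
def _butter_sos(order: int, cutoff_hz: float, fs: float, btype: str) -> np.ndarray:
    return signal.butter(order, cutoff_hz, btype=btype, fs=fs, output="sos")


def highpass(data: np.ndarray, fs: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass along axis 0 (gravity removal)."""
    return signal.sosfiltfilt(_butter_sos(order, cutoff_hz, fs, "highpass"), data, axis=0)


def lowpass(data: np.ndarray, fs: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0 (gravity estimate)."""
    return signal.sosfiltfilt(_butter_sos(order, cutoff_hz, fs, "lowpass"), data, axis=0)


def moving_rms(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving RMS with edge-shortened windows (same length as input)."""
    w = max(1, int(window_samples))
    sq = x.astype(float) ** 2
    kernel = np.ones(w)
    num = np.convolve(sq, kernel, mode="same")
    den = np.convolve(np.ones_like(sq), kernel, mode="same")
    return np.sqrt(num / den)


def find_sleep_period(trace: AccelTrace, metadata=None, params: DetectionParams | None = None):
    """Locate the sleep period as half-open sample indices into the trace.

    If the sleep log reports a sleep window it is trusted and simply clipped
    to the trace. Otherwise the longest contiguous span whose long-window
    moving RMS of the high-pass-filtered vector magnitude stays below the
    quiescence threshold is used; spans shorter than ``min_sleep_span_s``
    raise an error.
    """
    params = params or DetectionParams()
    fs = trace.sampling_rate_hz

    window = getattr(metadata, "sleep_window", None) if metadata is not None else None
    if window is None and trace.duration_s < 3600.0:
        raise LimbaccError("trace must span at least one hour for sleep detection")
    if window is not None:
        start_ts, end_ts = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        start = int(round((start_ts - trace.start_time).total_seconds() * fs))
        end = int(round((end_ts - trace.start_time).total_seconds() * fs))
        start = max(0, start)
        end = min(trace.n_samples, end)
        if end <= start:
            raise LimbaccError("reported sleep window does not intersect the trace")
        return start, end

    hp = highpass(trace.data, fs, params.highpass_hz, params.filter_order)
    env = moving_rms(vector_magnitude(hp), int(params.sleep_rms_window_s * fs))
    quiet = env < params.sleep_rms_threshold_g
    best = _longest_true_run(quiet)
    if best is None or (best[1] - best[0]) / fs < params.min_sleep_span_s:
        raise LimbaccError("no sleep period: no sufficiently long quiescent span found")
    return best


def _longest_true_run(mask: np.ndarray):
    if not mask.any():
        return None
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    i = int(np.argmax(ends - starts))
    return int(starts[i]), int(ends[i])


def segment_movements(
    trace: AccelTrace,
    sleep_period: tuple,
    params: DetectionParams | None = None,
    filtered: np.ndarray | None = None,
) -> list[MovementEvent]:
    """Segment discrete movement events from one limb trace.

    ``filtered`` lets a caller that already high-pass filtered the trace
    (e.g. for feature extraction) avoid filtering twice.
    """
    params = params or DetectionParams()
    params.validate()
    fs = trace.sampling_rate_hz
    s0, s1 = sleep_period
    if not (0 <= s0 < s1 <= trace.n_samples):
        raise ConfigurationError("sleep period outside trace bounds")

    hp = filtered if filtered is not None else highpass(
        trace.data, fs, params.highpass_hz, params.filter_order
    )
    vm = vector_magnitude(hp)
    env = moving_rms(vm, int(round(params.envelope_window_s * fs)))
    env = env[s0:s1]

    hi = env > params.threshold_g
    lo = env > params.threshold_g / 2.0
    spans = _hysteresis_spans(hi, lo)
    spans = _merge_close(spans, int(round(params.merge_gap_s * fs)))
    min_len = int(round(params.min_duration_s * fs))
    spans = [(a, b) for a, b in spans if (b - a) >= min_len]

    events = []
    for a, b in spans:
        events.append(
            MovementEvent(
                limbs={trace.placement},
                start_idx=s0 + a,
                end_idx=s0 + b,
                sampling_rate_hz=fs,
                axes=hp[s0 + a : s0 + b],
                vm=vm[s0 + a : s0 + b],
            )
        )
    for i in range(1, len(events)):
        events[i].prev_index = i - 1
    return events


def _hysteresis_spans(hi: np.ndarray, lo: np.ndarray):
    """Maximal spans of ``lo`` that contain at least one ``hi`` sample."""
    if not lo.any():
        return []
    padded = np.concatenate(([False], lo, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    cum = np.concatenate(([0], np.cumsum(hi.astype(np.int64))))
    keep = cum[ends] - cum[starts] > 0
    return [(int(a), int(b)) for a, b, k in zip(starts, ends, keep) if k]


def _merge_close(spans, gap_samples: int):
    if not spans:
        return []
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if a - merged[-1][1] < gap_samples:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(s) for s in merged]


def attribute_limbs(events_by_placement: dict, sync_window_s: float = 1.0) -> list[MovementEvent]:
    """Group near-simultaneous events across limbs into multi-limb events.

    Two events are grouped if their spans overlap or their onsets differ by
    at most ``sync_window_s``; grouping is transitive. The returned combined
    events carry the union limb set and the enclosing span, sorted by onset.
    """
    flat = []
    for placement, events in events_by_placement.items():
        for e in events:
            flat.append(e)
    if not flat:
        return []
    fs = flat[0].sampling_rate_hz
    sync = sync_window_s * fs
    flat.sort(key=lambda e: (e.start_idx, e.end_idx))

    groups = [[flat[0]]]
    for e in flat[1:]:
        g = groups[-1]
        g_end = max(x.end_idx for x in g)
        g_last_start = max(x.start_idx for x in g)
        if e.start_idx < g_end or (e.start_idx - g_last_start) <= sync:
            g.append(e)
        else:
            groups.append([e])

    combined = []
    for g in groups:
        combined.append(
            MovementEvent(
                limbs=frozenset().union(*(e.limbs for e in g)),
                start_idx=min(e.start_idx for e in g),
                end_idx=max(e.end_idx for e in g),
                sampling_rate_hz=fs,
            )
        )
    return combined
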