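"""Night-level features and per-night aggregation.

Periodic limb movements (PLM) follow the standard polysomnography scoring
rule: candidate leg movements last 0.5-10 s, and a PLM sequence is a run of
at least four candidates whose successive onset-to-onset intervals are
5-90 s. ``plm_pct`` is the percentage of leg movements belonging to any
sequence; ``plm_index`` is sequence movements per hour asleep.
"""

from __future__ import annotations

import numpy as np

from ..types import ANKLES

PLM_MIN_DURATION_S = 0.5
PLM_MAX_DURATION_S = 10.0
PLM_MIN_INTERVAL_S = 5.0
PLM_MAX_INTERVAL_S = 90.0
PLM_MIN_RUN = 4


def plm_movement_count(events: list) -> tuple:
    """(movements in PLM sequences, candidate count) for one limb's events.

    Events must be sorted by onset. Candidate movements (duration 0.5-10 s)
    are scanned in order; a maximal run breaks whenever the onset-to-onset
    interval between successive candidates leaves 5-90 s.
    """
    if not events:
        return 0, 0
    fs = events[0].sampling_rate_hz
    candidates = [
        e for e in events if PLM_MIN_DURATION_S <= e.duration_s <= PLM_MAX_DURATION_S
    ]
    n_in_seq = 0
    run_len = 1 if candidates else 0
    for prev, cur in zip(candidates, candidates[1:]):
        gap = (cur.start_idx - prev.start_idx) / fs
        if PLM_MIN_INTERVAL_S <= gap <= PLM_MAX_INTERVAL_S:
            run_len += 1
        else:
            if run_len >= PLM_MIN_RUN:
                n_in_seq += run_len
            run_len = 1
    if run_len >= PLM_MIN_RUN:
        n_in_seq += run_len
    return n_in_seq, len(candidates)


def plm_features(events_by_ankle: dict, time_asleep_h: float) -> dict:
    """PLM percentage and index pooled over both legs.

    ``plm_pct`` is relative to all leg movements (candidates or not);
    ``plm_index`` is PLM-sequence movements per hour asleep. With zero leg
    movements the percentage is undefined (NaN) and the index is 0.
    """
    total_events = sum(len(v) for v in events_by_ankle.values())
    in_seq = 0
    for ankle in ANKLES:
        cnt, _ = plm_movement_count(events_by_ankle.get(ankle, []))
        in_seq += cnt
    if total_events == 0:
        return {"night.plm_pct": float("nan"), "night.plm_index": 0.0}
    return {
        "night.plm_pct": 100.0 * in_seq / total_events,
        "night.plm_index": in_seq / time_asleep_h,
    }


def _limb_combo(limbs: frozenset) -> str:
    wrist = "wrist" in limbs
    n_ankles = sum(1 for a in ANKLES if a in limbs)
    if wrist:
        if n_ankles == 0:
            return "night.prop_wrist_only"
        if n_ankles == 1:
            return "night.prop_wrist_one_ankle"
        return "night.prop_wrist_both_ankles"
    if n_ankles == 2:
        return "night.prop_both_ankles"
    if "left_ankle" in limbs:
        return "night.prop_left_only"
    return "night.prop_right_only"


PROP_KEYS = (
    "night.prop_left_only",
    "night.prop_right_only",
    "night.prop_both_ankles",
    "night.prop_wrist_only",
    "night.prop_wrist_one_ankle",
    "night.prop_wrist_both_ankles",
)


def night_level_features(
    combined_events: list,
    events_by_ankle: dict,
    sleep_period: tuple,
    fs: float,
) -> dict:
    """The ten night-level features (time asleep, rates, PLM, limb shares)."""
    s0, s1 = sleep_period
    time_asleep_h = (s1 - s0) / fs / 3600.0
    out = {"night.time_asleep_h": time_asleep_h}
    n = len(combined_events)
    out["night.moves_per_hour"] = n / time_asleep_h if time_asleep_h > 0 else float("nan")
    out.update(plm_features(events_by_ankle, time_asleep_h))
    if n == 0:
        out.update({k: float("nan") for k in PROP_KEYS})
    else:
        counts = {k: 0 for k in PROP_KEYS}
        for e in combined_events:
            counts[_limb_combo(e.limbs)] += 1
        out.update({k: counts[k] / n for k in PROP_KEYS})
    return out


def aggregate_night(per_movement: list, max_feature: str = "time.duration_s") -> dict:
    """Median + IQR of every per-movement feature over one night's movements.

    IQR uses linear-interpolation (type-7) quantiles. The one max-flagged
    feature (movement duration by default) is additionally aggregated by its
    maximum. Features missing for every movement stay missing.
    """
    if not per_movement:
        raise ValueError("aggregate_night requires at least one movement")
    names = list(per_movement[0].keys())
    out = {}
    for name in names:
        vals = np.array([m[name] for m in per_movement], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            out[f"{name}__med"] = float("nan")
            out[f"{name}__iqr"] = float("nan")
            if name == max_feature:
                out[f"{name}__max"] = float("nan")
            continue
        q1, q3 = np.percentile(vals, [25, 75], method="linear")
        out[f"{name}__med"] = float(np.median(vals))
        out[f"{name}__iqr"] = float(q3 - q1)
        if name == max_feature:
            out[f"{name}__max"] = float(np.max(vals))
    return out
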