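"""PLM scoring, night-level features, and the aggregation chain."""

import numpy as np
import pandas as pd
import pytest

from limbacc.errors import ValidationError
from limbacc.features.aggregate import aggregate_participant, feature_frame, impute_missing, min_max_scale
from limbacc.features.night import (
    PLM_MAX_DURATION_S,
    PLM_MAX_INTERVAL_S,
    PLM_MIN_DURATION_S,
    PLM_MIN_INTERVAL_S,
    PLM_MIN_RUN,
    aggregate_night,
    night_level_features,
    plm_features,
    plm_movement_count,
)
from limbacc.features.registry import feature_columns
from limbacc.types import MovementEvent

FS = 30.0


def _ev(onset_s, duration_s, limb="left_ankle"):
    start = int(onset_s * FS)
    return MovementEvent(
        limbs={limb}, start_idx=start, end_idx=start + max(1, int(duration_s * FS)),
        sampling_rate_hz=FS,
    )


def brute_force_plm(onsets, durations):
    """Exhaustive enumeration of maximal candidate runs under the scoring rule."""
    candidates = [
        t for t, d in sorted(zip(onsets, durations))
        if PLM_MIN_DURATION_S <= d <= PLM_MAX_DURATION_S
    ]
    best, runs = 0, []
    i = 0
    while i < len(candidates):
        j = i
        while (
            j + 1 < len(candidates)
            and PLM_MIN_INTERVAL_S <= candidates[j + 1] - candidates[j] <= PLM_MAX_INTERVAL_S
        ):
            j += 1
        runs.append(j - i + 1)
        i = j + 1
    return sum(r for r in runs if r >= PLM_MIN_RUN), len(candidates)


class TestPlm:
    def test_minimal_qualifying_train(self):
        events = {"left_ankle": [_ev(t, 2.0) for t in (0, 20, 40, 60)], "right_ankle": []}
        out = plm_features(events, time_asleep_h=8.0)
        assert out["night.plm_pct"] == 100.0
        assert out["night.plm_index"] == pytest.approx(4 / 8.0)

    def test_two_distant_events_do_not_qualify(self):
        events = {"left_ankle": [_ev(0, 2.0), _ev(120, 2.0)], "right_ankle": []}
        assert plm_features(events, 8.0)["night.plm_pct"] == 0.0

    def test_long_movements_are_not_candidates(self):
        events = {"left_ankle": [_ev(t, 12.0) for t in (0, 20, 40, 60)], "right_ankle": []}
        assert plm_features(events, 8.0)["night.plm_pct"] == 0.0

    def test_zero_events(self):
        out = plm_features({"left_ankle": [], "right_ankle": []}, 8.0)
        assert np.isnan(out["night.plm_pct"]) and out["night.plm_index"] == 0.0

    def test_matches_brute_force_on_random_schedules(self, rng):
        """Exhaustive run-enumeration oracle over 1,000 random schedules."""
        for _ in range(1000):
            n = int(rng.integers(0, 25))
            onsets = np.sort(rng.uniform(0, 1200, size=n))
            # mix of candidate and non-candidate durations
            durations = rng.choice([0.3, 1.0, 2.5, 8.0, 12.0], size=n)
            events = [_ev(t, d) for t, d in zip(onsets, durations)]
            got, n_cand = plm_movement_count(events)
            # recompute onsets/durations from the events so both routes share
            # the same sample-quantized inputs
            q_onsets = [e.start_idx / FS for e in events]
            q_durs = [e.duration_s for e in events]
            expected, n_cand_bf = brute_force_plm(q_onsets, q_durs)
            assert got == expected
            assert n_cand == n_cand_bf


class TestNightLevel:
    def test_moves_per_hour(self):
        events = [_ev(60.0 * k, 2.0) for k in range(16)]
        out = night_level_features(events, {"left_ankle": events, "right_ankle": []},
                                   (0, int(8 * 3600 * FS)), FS)
        assert out["night.time_asleep_h"] == pytest.approx(8.0)
        assert out["night.moves_per_hour"] == pytest.approx(2.0)

    def test_all_bilateral(self):
        events = [
            MovementEvent(limbs={"left_ankle", "right_ankle"}, start_idx=int(60 * FS * k),
                          end_idx=int(60 * FS * k) + 60, sampling_rate_hz=FS)
            for k in range(1, 5)
        ]
        out = night_level_features(events, {"left_ankle": [], "right_ankle": []},
                                   (0, int(3600 * FS)), FS)
        assert out["night.prop_both_ankles"] == 1.0
        assert out["night.prop_wrist_only"] == 0.0

    def test_proportions_match_brute_force_counts(self, rng):
        limbs_pool = [
            frozenset(s) for s in (
                {"left_ankle"}, {"right_ankle"}, {"left_ankle", "right_ankle"},
                {"wrist"}, {"wrist", "left_ankle"}, {"wrist", "left_ankle", "right_ankle"},
            )
        ]
        events = []
        for k in range(40):
            limbs = limbs_pool[rng.integers(0, len(limbs_pool))]
            start = int(30 * FS * k)
            events.append(MovementEvent(limbs=limbs, start_idx=start, end_idx=start + 30,
                                        sampling_rate_hz=FS))
        out = night_level_features(events, {"left_ankle": [], "right_ankle": []},
                                   (0, int(3600 * FS)), FS)
        props = [v for k, v in out.items() if k.startswith("night.prop_")]
        assert sum(props) == pytest.approx(1.0, abs=1e-10)
        n_bilateral = sum(1 for e in events if e.limbs == frozenset({"left_ankle", "right_ankle"}))
        assert out["night.prop_both_ankles"] == pytest.approx(n_bilateral / 40)

    def test_exactly_ten_features(self):
        out = night_level_features([], {"left_ankle": [], "right_ankle": []},
                                   (0, int(3600 * FS)), FS)
        assert len(out) == 10


class TestAggregation:
    def test_median_and_iqr_linear_interpolation(self):
        rows = [{"f": v, "time.duration_s": v} for v in (1.0, 2.0, 3.0)]
        agg = aggregate_night(rows)
        assert agg["f__med"] == 2.0
        assert agg["f__iqr"] == pytest.approx(1.0)  # type-7 quantiles: Q3-Q1 = 2.5-1.5
        assert agg["time.duration_s__max"] == 3.0

    def test_single_movement_iqr_zero(self):
        agg = aggregate_night([{"f": 5.0, "time.duration_s": 2.0}])
        assert agg["f__iqr"] == 0.0

    def test_permutation_invariance(self, rng):
        vals = rng.normal(size=11)
        rows = [{"f": v, "time.duration_s": abs(v)} for v in vals]
        shuffled = [rows[i] for i in rng.permutation(11)]
        assert aggregate_night(rows) == aggregate_night(shuffled)

    def test_missing_values_skipped_then_propagated(self):
        rows = [{"f": np.nan, "time.duration_s": 1.0}, {"f": 3.0, "time.duration_s": 2.0}]
        assert aggregate_night(rows)["f__med"] == 3.0
        rows_all_nan = [{"f": np.nan, "time.duration_s": 1.0}]
        assert np.isnan(aggregate_night(rows_all_nan)["f__med"])

    def test_participant_median_across_nights(self, rng):
        nights = [{"a": float(v)} for v in (1.0, 9.0, 4.0)]
        assert aggregate_participant(nights)["a"] == 4.0
        assert aggregate_participant([{"a": 7.0}])["a"] == 7.0
        with pytest.raises(ValidationError):
            aggregate_participant([])

    def test_participant_median_matches_numpy(self, rng):
        nights = [{"a": float(rng.normal()), "b": float(rng.normal())} for _ in range(5)]
        agg = aggregate_participant(nights)
        assert agg["a"] == pytest.approx(np.median([n["a"] for n in nights]))


class TestScaling:
    def test_three_point_example(self):
        df = pd.DataFrame({"f": [2.0, 4.0, 6.0]}, index=["a", "b", "c"])
        scaled, bounds = min_max_scale(df)
        assert scaled["f"].tolist() == [0.0, 0.5, 1.0]
        assert bounds.loc["f", "min"] == 2.0 and bounds.loc["f", "max"] == 6.0

    def test_constant_feature_maps_to_midpoint(self):
        df = pd.DataFrame({"f": [3.0, 3.0, 3.0]}, index=list("abc"))
        scaled, _ = min_max_scale(df)
        assert scaled["f"].tolist() == [0.5, 0.5, 0.5]

    def test_random_matrix_hits_bounds(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 6)), columns=[f"f{i}" for i in range(6)])
        scaled, _ = min_max_scale(df)
        assert np.allclose(scaled.min(axis=0), 0.0)
        assert np.allclose(scaled.max(axis=0), 1.0)

    def test_missing_propagates_then_imputes(self):
        df = pd.DataFrame({"f": [1.0, np.nan, 3.0]}, index=list("abc"))
        scaled, _ = min_max_scale(df)
        assert np.isnan(scaled.loc["b", "f"])
        filled = impute_missing(scaled)
        assert filled.loc["b", "f"] == pytest.approx(0.5)

    def test_requires_two_participants(self):
        with pytest.raises(ValidationError):
            min_max_scale(pd.DataFrame({"f": [1.0]}))


def test_feature_frame_orders_registry_columns(rng):
    cols = feature_columns()
    vec = {c: float(rng.normal()) for c in cols}
    df = feature_frame({"P2": dict(reversed(list(vec.items()))), "P1": vec})
    assert list(df.columns) == cols
    assert len(df.columns) == 133
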