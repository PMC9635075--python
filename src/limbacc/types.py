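"""Core domain containers: accelerometer traces, nights, movement events.

All sample indexing is 0-based and half-open: an event occupying samples
``start_idx`` through ``end_idx - 1`` has ``duration_s =
(end_idx - start_idx) / fs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

PLACEMENTS = ("left_ankle", "right_ankle", "wrist")
ANKLES = ("left_ankle", "right_ankle")

#: hard device-range guard in g (ActiGraph-class wearables saturate at 16 g)
MAX_ABS_G = 16.0


@dataclass
class AccelTrace:
    """One limb's fixed-rate tri-axial acceleration record for one night.

    Axes are stored as a single ``(n, 3)`` float array in units of g;
    ``x``/``y``/``z`` views are provided for convenience.
    """

    placement: str
    sampling_rate_hz: float
    start_time: pd.Timestamp
    data: np.ndarray  # (n, 3) in g

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.placement not in PLACEMENTS:
            raise ValidationError(f"unknown placement {self.placement!r}")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValidationError("trace data must have shape (n, 3)")
        if len(self.data) == 0:
            raise ValidationError("trace must contain at least one sample")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("trace contains non-finite samples")
        if np.max(np.abs(self.data)) > MAX_ABS_G:
            raise ValidationError(f"trace exceeds the +/-{MAX_ABS_G} g device range")

    @property
    def x(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.data[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.data[:, 2]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.to_timedelta(self.duration_s, unit="s")


@dataclass
class NightRecord:
    """All traces plus sleep-log metadata for one participant-night."""

    participant_id: str
    night_index: int
    traces: dict  # placement -> AccelTrace
    typical: bool = True
    reported_sleep_window: tuple | None = None  # (start, end) timestamps
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [a for a in ANKLES if a not in self.traces]
        if missing:
            raise ValidationError(
                f"night {self.participant_id}/{self.night_index} lacks ankle "
                f"trace(s): {missing}"
            )
        # traces must overlap in time
        starts = [t.start_time for t in self.traces.values()]
        ends = [t.end_time for t in self.traces.values()]
        if max(starts) >= min(ends):
            raise ValidationError(
                f"night {self.participant_id}/{self.night_index}: traces do "
                "not overlap in time"
            )


@dataclass
class MovementEvent:
    """A segmented limb movement.

    ``limbs`` is the set of placements active during the event (a single
    placement straight out of segmentation; possibly several after cross-limb
    attribution). Signal slices refer to the high-pass-filtered record.
    """

    limbs: frozenset
    start_idx: int
    end_idx: int
    sampling_rate_hz: float
    axes: np.ndarray | None = None  # (n, 3) filtered slice
    vm: np.ndarray | None = None  # filtered vector-magnitude slice
    prev_index: int | None = None  # index of previous event on same limb

    def __post_init__(self):
        if self.end_idx <= self.start_idx:
            raise ValidationError("event end_idx must exceed start_idx")
        self.limbs = frozenset(self.limbs)

    @property
    def duration_s(self) -> float:
        return (self.end_idx - self.start_idx) / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx
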