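"""File formats and the typical-night inclusion rule.

Raw accelerometry is exchanged as plain CSV: a header row, then either an
ISO-8601 ``timestamp`` column or an integer ``sample_index`` column followed
by ``x,y,z`` in units of g at a constant sampling rate. Sleep-log metadata is
a CSV keyed by ``(participant_id, night_index)`` with a ``typical`` flag, an
optional reported sleep window, and arbitrary covariate columns carried
through verbatim. Only nights the participant marked *typical* of their
normal sleep enter the analysis; participants with no typical night are
excluded.

Readers validate rather than coerce: malformed input raises
:class:`~limbacc.errors.FormatError` naming the file and row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .types import AccelTrace, NightRecord

#: sampling rate assumed when none is supplied (GT9X-class devices)
DEFAULT_SAMPLING_RATE_HZ = 30.0

SLEEP_LOG_KEYS = ["participant_id", "night_index"]
SLEEP_LOG_KNOWN = SLEEP_LOG_KEYS + ["typical", "sleep_start", "sleep_end"]

OUTCOME_COLUMNS = [
    "participant_id",
    "lems",
    "light_touch",
    "mas_knee_L",
    "mas_knee_R",
    "mas_ankle_L",
    "mas_ankle_R",
]


def read_accel_csv(
    path,
    placement: str,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    on_gap: str = "error",
) -> AccelTrace:
    """Read one limb-night of tri-axial acceleration from CSV.

    Accepts either a ``timestamp`` (ISO-8601) or a ``sample_index`` leading
    column. Timestamps must be strictly increasing at a rate within 1% of
    ``sampling_rate_hz``; gaps larger than one sample period raise a
    :class:`FormatError` by default, or are linearly interpolated with
    ``on_gap="fill"``.
    """
    if on_gap not in ("error", "fill"):
        raise ValidationError(f"on_gap must be 'error' or 'fill', got {on_gap!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise FormatError(f"cannot parse CSV: {exc}", path=path) from exc
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}", path=path)
    if len(df) == 0:
        raise FormatError("empty trace file", path=path)

    if "timestamp" in df.columns:
        try:
            ts = pd.to_datetime(df["timestamp"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"unparseable timestamp: {exc}", path=path) from exc
        start_time = ts.iloc[0]
        if len(ts) > 1:
            dt = np.diff(ts.values.astype("datetime64[ns]").astype(np.int64)) / 1e9
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise FormatError(
                    "non-monotone or duplicated timestamp", path=path, row=int(bad[0]) + 2
                )
            period = 1.0 / sampling_rate_hz
            gap = np.nonzero(dt > 1.5 * period)[0]
            if gap.size and on_gap == "error":
                raise FormatError(
                    f"gap of {dt[gap[0]]:.3f} s exceeds one sample period",
                    path=path,
                    row=int(gap[0]) + 2,
                )
            if gap.size:
                positions = np.concatenate(([0.0], np.cumsum(dt))) * sampling_rate_hz
                df = _fill_gaps(df, positions)
            observed = 1.0 / np.median(dt)
            if abs(observed - sampling_rate_hz) / sampling_rate_hz > 0.01:
                raise FormatError(
                    f"sampling rate {observed:.2f} Hz deviates more than 1% "
                    f"from declared {sampling_rate_hz} Hz",
                    path=path,
                )
    elif "sample_index" in df.columns:
        idx = df["sample_index"].to_numpy()
        step = np.diff(idx)
        bad = np.nonzero(step <= 0)[0]
        if bad.size:
            raise FormatError("non-monotone sample_index", path=path, row=int(bad[0]) + 2)
        gap = np.nonzero(step > 1)[0]
        if gap.size and on_gap == "error":
            raise FormatError(
                f"gap of {int(step[gap[0]])} samples in sample_index",
                path=path,
                row=int(gap[0]) + 2,
            )
        if gap.size:
            df = _fill_gaps(df, (idx - idx[0]).astype(float))
        start_time = pd.Timestamp(0)
    else:
        raise FormatError("need a 'timestamp' or 'sample_index' column", path=path)

    data = df[["x", "y", "z"]].to_numpy(dtype=float)
    finite = np.isfinite(data).all(axis=1)
    if not finite.all():
        raise FormatError(
            "non-finite acceleration value", path=path, row=int(np.argmin(finite)) + 2
        )
    try:
        return AccelTrace(
            placement=placement,
            sampling_rate_hz=sampling_rate_hz,
            start_time=start_time,
            data=data,
        )
    except ValidationError as exc:
        raise FormatError(str(exc), path=path) from exc


def _fill_gaps(df: pd.DataFrame, positions: np.ndarray) -> pd.DataFrame:
    """Linearly interpolate x/y/z onto the full integer sample grid."""
    grid = np.arange(int(round(positions[-1])) + 1, dtype=float)
    return pd.DataFrame(
        {c: np.interp(grid, positions, df[c].to_numpy(dtype=float)) for c in ("x", "y", "z")}
    )


def write_accel_csv(trace: AccelTrace, path, timestamps: bool = False) -> None:
    """Write a trace in the dialect :func:`read_accel_csv` reads.

    By default the compact ``sample_index`` form is used; pass
    ``timestamps=True`` for ISO-8601 timestamps derived from ``start_time``.
    """
    if timestamps:
        t = trace.start_time + pd.to_timedelta(
            np.arange(trace.n_samples) / trace.sampling_rate_hz, unit="s"
        )
        lead = pd.Series(t.strftime("%Y-%m-%dT%H:%M:%S.%f"), name="timestamp")
    else:
        lead = pd.Series(np.arange(trace.n_samples), name="sample_index")
    out = pd.DataFrame(
        {lead.name: lead, "x": trace.x, "y": trace.y, "z": trace.z}
    )
    out.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


@dataclass
class NightMeta:
    """Sleep-log metadata for one participant-night."""

    participant_id: str
    night_index: int
    typical: bool
    sleep_window: tuple | None = None
    covariates: dict = field(default_factory=dict)


_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}


def _parse_bool(value, path, row):
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise FormatError(f"unparseable boolean {value!r} in 'typical'", path=path, row=row)


def read_sleep_log(path) -> list[NightMeta]:
    """Read the per-night sleep log; unknown columns become covariates."""
    df = pd.read_csv(path)
    for col in SLEEP_LOG_KEYS + ["typical"]:
        if col not in df.columns:
            raise FormatError(f"sleep log missing column {col!r}", path=path)
    dup = df.duplicated(subset=SLEEP_LOG_KEYS)
    if dup.any():
        raise FormatError(
            "duplicate (participant_id, night_index) key",
            path=path,
            row=int(np.nonzero(dup.to_numpy())[0][0]) + 2,
        )
    covariate_cols = [c for c in df.columns if c not in SLEEP_LOG_KNOWN]
    records = []
    for i, row in df.iterrows():
        window = None
        if "sleep_start" in df.columns and "sleep_end" in df.columns:
            if pd.notna(row["sleep_start"]) and pd.notna(row["sleep_end"]):
                window = (
                    pd.Timestamp(row["sleep_start"]),
                    pd.Timestamp(row["sleep_end"]),
                )
        records.append(
            NightMeta(
                participant_id=str(row["participant_id"]),
                night_index=int(row["night_index"]),
                typical=_parse_bool(row["typical"], path, i + 2),
                sleep_window=window,
                covariates={c: row[c] for c in covariate_cols},
            )
        )
    return records


def write_sleep_log(metas: list[NightMeta], path) -> None:
    cov_cols: list[str] = []
    for m in metas:
        for c in m.covariates:
            if c not in cov_cols:
                cov_cols.append(c)
    rows = []
    for m in metas:
        row = {
            "participant_id": m.participant_id,
            "night_index": m.night_index,
            "typical": m.typical,
            "sleep_start": m.sleep_window[0] if m.sleep_window else None,
            "sleep_end": m.sleep_window[1] if m.sleep_window else None,
        }
        row.update(m.covariates)
        rows.append(row)
    pd.DataFrame(rows, columns=SLEEP_LOG_KNOWN + cov_cols).to_csv(
        path, index=False, lineterminator="\n"
    )


def filter_typical_nights(nights: list[NightRecord]):
    """Keep only self-reported typical nights, preserving order.

    Returns ``(kept, excluded_participants)`` where the second element lists
    participants all of whose nights were atypical (excluded from analysis).
    """
    kept = [n for n in nights if n.typical]
    by_participant: dict[str, bool] = {}
    for n in nights:
        by_participant[n.participant_id] = by_participant.get(n.participant_id, False) or n.typical
    excluded = [pid for pid, any_typical in by_participant.items() if not any_typical]
    return kept, excluded


def write_feature_table(vectors: pd.DataFrame, path) -> None:
    """Write the participant x feature table with stable registry column order."""
    df = vectors.copy()
    df.index.name = "participant_id"
    df.to_csv(path, lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise FormatError("feature table missing 'participant_id'", path=path)
    return df.set_index("participant_id")


def write_outcomes_csv(outcomes, path) -> None:
    """Write per-participant clinical outcomes (see OUTCOME_COLUMNS)."""
    rows = [
        {
            "participant_id": o.participant_id,
            "lems": o.lems,
            "light_touch": o.light_touch,
            "mas_knee_L": o.mas_scores[0],
            "mas_knee_R": o.mas_scores[1],
            "mas_ankle_L": o.mas_scores[2],
            "mas_ankle_R": o.mas_scores[3],
        }
        for o in outcomes
    ]
    pd.DataFrame(rows, columns=OUTCOME_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def read_outcomes_csv(path):
    from .outcomes import ImpairmentOutcomes

    df = pd.read_csv(path, dtype={"participant_id": str})
    for col in OUTCOME_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"outcomes table missing column {col!r}", path=path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ImpairmentOutcomes(
                    participant_id=row["participant_id"],
                    lems=int(row["lems"]),
                    light_touch=int(row["light_touch"]),
                    mas_scores=(
                        row["mas_knee_L"],
                        row["mas_knee_R"],
                        row["mas_ankle_L"],
                        row["mas_ankle_R"],
                    ),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise FormatError(str(exc), path=path, row=i + 2) from exc
    return out


def write_model_report(report: dict, path) -> None:
    """Serialize a model/evaluation report as JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)


def read_model_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
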