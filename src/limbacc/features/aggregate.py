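"""Participant-level aggregation and cohort scaling."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import ValidationError
from .registry import feature_columns


def aggregate_participant(night_maps: list) -> dict:
    """Per-feature median across a participant's typical nights.

    Missing (NaN) nights are skipped per feature; a feature missing on every
    night stays missing.
    """
    if not night_maps:
        raise ValidationError("participant has zero typical nights; excluded")
    names = list(night_maps[0].keys())
    out = {}
    for name in names:
        vals = np.array([m[name] for m in night_maps], dtype=float)
        vals = vals[~np.isnan(vals)]
        out[name] = float(np.median(vals)) if len(vals) else float("nan")
    return out


def feature_frame(vectors: dict) -> pd.DataFrame:
    """Assemble per-participant feature dicts into the canonical table.

    Rows are participants (insertion order); columns follow the registry.
    """
    cols = feature_columns()
    df = pd.DataFrame.from_dict(vectors, orient="index")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"feature vectors lack registry columns: {missing[:5]}...")
    df = df[cols]
    df.index.name = "participant_id"
    return df


def min_max_scale(table: pd.DataFrame):
    """Scale each feature to [0, 1] by its min/max across participants.

    Constant features map to 0.5 everywhere (no ordering information either
    way); missing values propagate. Returns ``(scaled, bounds)`` where
    ``bounds`` holds the per-feature min and max used.
    """
    if len(table) < 2:
        raise ValidationError("min-max scaling requires at least 2 participants")
    lo = table.min(axis=0, skipna=True)
    hi = table.max(axis=0, skipna=True)
    span = hi - lo
    scaled = (table - lo) / span.replace(0.0, np.nan)
    constant = (span == 0.0) & lo.notna()
    for col in table.columns[constant]:
        scaled[col] = table[col].notna().map({True: 0.5, False: np.nan})
    bounds = pd.DataFrame({"min": lo, "max": hi})
    return scaled, bounds


def impute_missing(scaled: pd.DataFrame, warn=None) -> pd.DataFrame:
    """Mean-impute missing scaled values column-wise (used at modeling time).

    Columns missing for every participant impute to the scale midpoint 0.5.
    ``warn`` is an optional callable receiving one message per imputed column.
    """
    out = scaled.copy()
    for col in out.columns:
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        fill = out[col].mean(skipna=True)
        if np.isnan(fill):
            fill = 0.5
        out[col] = out[col].fillna(fill)
        if warn is not None:
            warn(f"imputed {n_missing} missing value(s) in {col!r} with {fill:.4f}")
    return out
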