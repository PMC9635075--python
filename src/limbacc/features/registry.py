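"""Feature registry: the canonical ordered list of LA features.

Categories (12): Stat, Freq, SC, CC, Ang, CGA, MC, RRM, VD, Time at the
movement level; PLM and LimbPct appear only among the ten night-level
features (which also include two Time members). Counts are enforced at
import: 61 movement-level features, 10 night-level features, and exactly one
movement-level feature (duration) additionally aggregated by its maximum,
for 133 participant-level columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from ..errors import ValidationError

CATEGORIES = ("Stat", "Freq", "SC", "CC", "Ang", "CGA", "MC", "RRM", "VD", "Time", "PLM", "LimbPct")

N_MOVEMENT_FEATURES = 61
N_NIGHT_FEATURES = 10
N_PARTICIPANT_COLUMNS = 133


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    category: str
    level: str  # "movement" or "night"
    aggregations: tuple  # ("med", "iqr") or ("med", "iqr", "max") or ("night",)


def _mv(name, category, max_agg=False):
    aggs = ("med", "iqr", "max") if max_agg else ("med", "iqr")
    return FeatureSpec(name, category, "movement", aggs)


def _nt(name, category):
    return FeatureSpec(name, category, "night", ("night",))


def build_registry() -> list[FeatureSpec]:
    """The ordered feature registry (movement-level block, then night-level)."""
    specs = [
        # Statistical moments of the filtered vector magnitude
        _mv("stat.mean", "Stat"),
        _mv("stat.sd", "Stat"),
        _mv("stat.max", "Stat"),
        _mv("stat.min", "Stat"),
        _mv("stat.rms", "Stat"),
        _mv("stat.skewness", "Stat"),
        _mv("stat.kurtosis", "Stat"),
        _mv("stat.range", "Stat"),
        # Frequency domain (PSD of the mean-removed vector magnitude)
        _mv("freq.dom_freq_1", "Freq"),
        _mv("freq.dom_freq_2", "Freq"),
        _mv("freq.power_dom_1", "Freq"),
        _mv("freq.power_dom_2", "Freq"),
        _mv("freq.power_dom1_over_total", "Freq"),
        _mv("freq.med_freq", "Freq"),
        _mv("freq.mean_freq", "Freq"),
        _mv("freq.total_power", "Freq"),
        _mv("freq.spectral_edge_95", "Freq"),
        _mv("freq.bandwidth", "Freq"),
        # Signal characteristics: wavelet band energies + largest Lyapunov exponent
        _mv("sc.wave_approx", "SC"),
        _mv("sc.wave_energy_1", "SC"),
        _mv("sc.wave_energy_2", "SC"),
        _mv("sc.wave_energy_3", "SC"),
        _mv("sc.wave_entropy", "SC"),
        _mv("sc.rel_energy_1", "SC"),
        _mv("sc.rel_energy_2", "SC"),
        _mv("sc.rel_energy_3", "SC"),
        _mv("sc.lyapunov_exp", "SC"),
        # Correlation coefficients between axes
        _mv("cc.corr_xy", "CC"),
        _mv("cc.corr_xz", "CC"),
        _mv("cc.corr_yz", "CC"),
        # Change in angle of inclination
        _mv("ang.incl_angle_change", "Ang"),
        _mv("ang.angle_rate_change", "Ang"),
        _mv("ang.max_angle_rate", "Ang"),
        _mv("ang.roll_flag", "Ang"),
        # Change in gravitational acceleration per axis
        _mv("cga.grav_change_x", "CGA"),
        _mv("cga.grav_change_y", "CGA"),
        _mv("cga.grav_change_z", "CGA"),
        # Median crossings
        _mv("mc.num_med_crossings", "MC"),
        _mv("mc.num_med_crossings_norm", "MC"),
        # Relationship to recent movements
        _mv("rrm.time_since_prev", "RRM"),
        _mv("rrm.max_cross_corr", "RRM"),
        _mv("rrm.max_cross_cov", "RRM"),
        _mv("rrm.num_cross_corr_peaks", "RRM"),
        _mv("rrm.num_cross_cov_peaks", "RRM"),
        _mv("rrm.close_cross_corr_peak", "RRM"),
        _mv("rrm.close_cross_cov_peak", "RRM"),
        _mv("rrm.move_next_90s", "RRM"),
        _mv("rrm.dom_freq_last_90s", "RRM"),
        _mv("rrm.corr_with_prev", "RRM"),
        _mv("rrm.consistency_score", "RRM"),
        # Velocity and distance (integrated, drift-corrected)
        _mv("vd.peak_velocity", "VD"),
        _mv("vd.mean_velocity", "VD"),
        _mv("vd.velocity_rms", "VD"),
        _mv("vd.displacement", "VD"),
        _mv("vd.path_length", "VD"),
        _mv("vd.jerk_rms", "VD"),
        _mv("vd.jerk_peak", "VD"),
        # Timing (duration is the single max-aggregated feature)
        _mv("time.duration_s", "Time", max_agg=True),
        _mv("time.onset_hours", "Time"),
        _mv("time.night_fraction", "Time"),
        _mv("time.offset_hours", "Time"),
        # Night-level features
        _nt("night.time_asleep_h", "Time"),
        _nt("night.moves_per_hour", "Time"),
        _nt("night.plm_pct", "PLM"),
        _nt("night.plm_index", "PLM"),
        _nt("night.prop_left_only", "LimbPct"),
        _nt("night.prop_right_only", "LimbPct"),
        _nt("night.prop_both_ankles", "LimbPct"),
        _nt("night.prop_wrist_only", "LimbPct"),
        _nt("night.prop_wrist_one_ankle", "LimbPct"),
        _nt("night.prop_wrist_both_ankles", "LimbPct"),
    ]
    validate_registry(specs)
    return specs


def validate_registry(specs: list[FeatureSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate feature names in registry")
    movement = [s for s in specs if s.level == "movement"]
    night = [s for s in specs if s.level == "night"]
    if len(movement) != N_MOVEMENT_FEATURES:
        raise ValidationError(f"registry has {len(movement)} movement features, expected {N_MOVEMENT_FEATURES}")
    if len(night) != N_NIGHT_FEATURES:
        raise ValidationError(f"registry has {len(night)} night features, expected {N_NIGHT_FEATURES}")
    max_flagged = [s for s in movement if "max" in s.aggregations]
    if len(max_flagged) != 1:
        raise ValidationError("exactly one movement feature must be max-aggregated")
    bad = [s.name for s in specs if s.category not in CATEGORIES]
    if bad:
        raise ValidationError(f"unknown categories on: {bad}")
    if len(feature_columns(specs)) != N_PARTICIPANT_COLUMNS:
        raise ValidationError("participant-level column count is not 133")


def feature_columns(specs: list[FeatureSpec] | None = None) -> list[str]:
    """Participant-level column names in canonical order."""
    specs = specs if specs is not None else build_registry()
    cols = []
    for s in specs:
        if s.level == "movement":
            cols.append(f"{s.name}__med")
            cols.append(f"{s.name}__iqr")
            if "max" in s.aggregations:
                cols.append(f"{s.name}__max")
        else:
            cols.append(s.name)
    return cols


def column_category(column: str, specs: list[FeatureSpec] | None = None) -> str:
    """Category of a participant-level column name."""
    specs = specs if specs is not None else build_registry()
    base = column.split("__")[0]
    for s in specs:
        if s.name == base:
            return s.category
    raise KeyError(column)


def registry_to_json(path, specs: list[FeatureSpec] | None = None) -> None:
    specs = specs if specs is not None else build_registry()
    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "name": s.name,
                    "category": s.category,
                    "level": s.level,
                    "aggregations": list(s.aggregations),
                }
                for s in specs
            ],
            fh,
            indent=2,
        )
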