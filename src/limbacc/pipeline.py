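"""End-to-end orchestration: traces -> events -> features -> models -> reports.

The flow mirrors the intended analysis of a real collection:

1. per night and ankle, find the sleep period, segment movements, and compute
   the 61 per-movement features;
2. aggregate to the night level (median + IQR per feature, max duration, ten
   night-level features) over typical nights only;
3. take the per-feature median across nights to get one 133-vector per
   participant, then min-max scale across participants;
4. fit the feature-selecting models (LASSO-LARS for strength and sensation,
   L1 multinomial logistic for the spasticity category) with 10-fold block
   cross-validation, and evaluate with the full metric suite, including the
   covariates-only vs covariates+LA comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import (
    DetectionParams,
    attribute_limbs,
    find_sleep_period,
    highpass,
    segment_movements,
    vector_magnitude,
)
from .errors import ValidationError
from .evaluation import (
    classification_report,
    compare_classification_models,
    compare_regression_models,
    confusion_matrix,
    f_change_test,
    likelihood_ratio_test,
    regression_metrics,
)
from .features import (
    MovementContext,
    aggregate_night,
    aggregate_participant,
    compute_movement_features,
    feature_columns,
    min_max_scale,
    night_level_features,
)
from .features.aggregate import feature_frame, impute_missing
from .features.registry import column_category
from .ingest import filter_typical_nights
from .modeling import (
    block_cv_folds,
    compose_feature_sets,
    select_features_l1_logistic,
    select_features_lasso_lars,
)
from .outcomes import SPASTICITY_CATEGORIES
from .synthetic import CohortConfig, iter_participants
from .types import ANKLES, NightRecord

logger = logging.getLogger("limbacc")


@dataclass
class _WindowShim:
    sleep_window: tuple | None


def extract_night_features(
    record: NightRecord, params: DetectionParams | None = None
) -> dict:
    """Compute the full night-level feature map (123 + 10 values) for one night."""
    params = params or DetectionParams()
    shim = _WindowShim(record.reported_sleep_window)

    events_by_placement = {}
    movement_rows = []
    sleep_period = None
    fs = None
    for placement, trace in record.traces.items():
        fs = trace.sampling_rate_hz
        period = find_sleep_period(trace, shim, params)
        if placement in ANKLES:
            sleep_period = period
        hp = highpass(trace.data, fs, params.highpass_hz, params.filter_order)
        events = segment_movements(trace, period, params, filtered=hp)
        events_by_placement[placement] = events
        if placement in ANKLES and events:
            ctx = MovementContext(
                fs=fs,
                sleep_period=period,
                vm_filtered=vector_magnitude(hp),
                raw_data=trace.data,
                limb_events=events,
            )
            for event in events:
                movement_rows.append(compute_movement_features(event, ctx))

    combined = attribute_limbs(events_by_placement, params.sync_window_s)
    night = night_level_features(
        combined,
        {a: events_by_placement.get(a, []) for a in ANKLES},
        sleep_period,
        fs,
    )
    if movement_rows:
        night.update(aggregate_night(movement_rows))
    else:
        logger.warning(
            "night %s/%s: no ankle movements; movement features missing",
            record.participant_id,
            record.night_index,
        )
        for col in feature_columns():
            if not col.startswith("night."):
                night[col] = float("nan")
    return night


def extract_participant_features(
    records: list, params: DetectionParams | None = None
) -> dict | None:
    """Median-across-typical-nights feature vector; None if no typical night."""
    typical, _ = filter_typical_nights(records)
    if not typical:
        return None
    return aggregate_participant([extract_night_features(r, params) for r in typical])


def extract_cohort(config: CohortConfig, params: DetectionParams | None = None):
    """Generate a synthetic cohort and extract its feature table (streaming).

    Returns ``(features, outcomes_df, covariates_df, excluded)`` where
    ``features`` is the unscaled participant x 133 table.
    """
    vectors, outcome_rows, cov_rows, excluded = {}, [], [], []
    for phen, outcome, cov, night_iter in iter_participants(config):
        records = [record for record, _, _ in night_iter]
        vec = extract_participant_features(records, params)
        if vec is None:
            excluded.append(phen.participant_id)
            logger.warning("participant %s excluded: no typical nights", phen.participant_id)
            continue
        vectors[phen.participant_id] = vec
        outcome_rows.append(
            {
                "participant_id": phen.participant_id,
                "lems": outcome.lems,
                "light_touch": outcome.light_touch,
                "mas_category": outcome.mas_category,
            }
        )
        cov_rows.append({"participant_id": phen.participant_id, **cov})
    features = feature_frame(vectors)
    outcomes_df = pd.DataFrame(outcome_rows).set_index("participant_id")
    covariates_df = pd.DataFrame(cov_rows).set_index("participant_id")
    return features, outcomes_df, covariates_df, excluded


def _loglik_multinomial(result, X, y) -> float:
    scores = np.asarray(X, dtype=float) @ result.coefficients.T + result.intercept
    scores -= scores.max(axis=1, keepdims=True)
    log_probs = scores - np.log(np.exp(scores).sum(axis=1, keepdims=True))
    class_index = {c: i for i, c in enumerate(result.classes)}
    rows = np.arange(len(y))
    return float(log_probs[rows, [class_index[v] for v in y]].sum())


@dataclass
class StudyReport:
    """All models and metrics from one end-to-end run."""

    selection: dict = field(default_factory=dict)  # (outcome, feature_set) -> SelectionResult
    regression: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)
    n_participants: int = 0

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "excluded": list(self.excluded),
            "selection": {f"{k[0]}:{k[1]}": v.to_dict() for k, v in self.selection.items()},
            "regression": {
                f"{k[0]}:{k[1]}": v.to_dict() for k, v in self.regression.items()
            },
            "classification": {
                f"{k[0]}:{k[1]}": v.to_dict() for k, v in self.classification.items()
            },
            "comparisons": self.comparisons,
        }


REGRESSION_OUTCOMES = ("lems", "light_touch")


def fit_study_models(
    features_scaled: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates_scaled: pd.DataFrame | None = None,
    seed: int = 0,
    k_folds: int = 10,
    feature_sets: tuple = ("la_only",),
) -> StudyReport:
    """Fit and evaluate every outcome x feature-set model.

    ``features_scaled`` and ``covariates_scaled`` must be on the common 0-1
    scale; missing values are mean-imputed here with a logged warning.
    """
    if not features_scaled.index.equals(outcomes.index):
        raise ValidationError("feature and outcome tables index different participants")
    la = impute_missing(features_scaled, warn=logger.warning)
    sets = compose_feature_sets(la, covariates_scaled)
    n = len(la)
    folds = block_cv_folds(n, k=k_folds, seed=seed)
    report = StudyReport(n_participants=n)

    for label in feature_sets:
        X = sets[label]
        if X is None:
            continue
        for outcome in REGRESSION_OUTCOMES:
            y = outcomes[outcome].to_numpy(dtype=float)
            sel = select_features_lasso_lars(X, y, folds, outcome=outcome, feature_set=label)
            report.selection[(outcome, label)] = sel
            p = max(len(sel.selected), 1)
            if n > p + 1:
                y_hat = sel.predict(X)
                report.regression[(outcome, label)] = regression_metrics(y, y_hat, p)
        y_cat = outcomes["mas_category"].to_numpy()
        sel = select_features_l1_logistic(
            X, y_cat, folds, outcome="mas_category", feature_set=label
        )
        report.selection[("mas_category", label)] = sel
        y_pred = sel.predict(X)
        m = confusion_matrix(y_cat, y_pred, SPASTICITY_CATEGORIES)
        report.classification[("mas_category", label)] = classification_report(
            m, SPASTICITY_CATEGORIES
        )

    if "covariates_only" in feature_sets and "covariates_plus_la" in feature_sets:
        _add_comparisons(report, sets, outcomes, n)
    return report


def _add_comparisons(report: StudyReport, sets: dict, outcomes: pd.DataFrame, n: int):
    for outcome in REGRESSION_OUTCOMES:
        red = report.regression.get((outcome, "covariates_only"))
        full = report.regression.get((outcome, "covariates_plus_la"))
        if red is None or full is None:
            continue
        comp = compare_regression_models(red.adj_r2, full.adj_r2)
        if full.p > red.p and full.r2 >= red.r2:
            f, p_val = f_change_test(red.r2, full.r2, n, red.p, full.p)
            comp["f_change"] = f
            comp["p_value"] = p_val
        report.comparisons[outcome] = comp

    red_sel = report.selection.get(("mas_category", "covariates_only"))
    full_sel = report.selection.get(("mas_category", "covariates_plus_la"))
    red_rep = report.classification.get(("mas_category", "covariates_only"))
    full_rep = report.classification.get(("mas_category", "covariates_plus_la"))
    if red_sel and full_sel and red_rep and full_rep:
        comp = compare_classification_models(red_rep, full_rep)
        y = outcomes["mas_category"].to_numpy()
        ll_red = _loglik_multinomial(red_sel, sets["covariates_only"], y)
        ll_full = _loglik_multinomial(full_sel, sets["covariates_plus_la"], y)
        df_diff = max(
            1,
            sum(len(v) for v in full_sel.selected.values())
            - sum(len(v) for v in red_sel.selected.values()),
        )
        stat, p_val = likelihood_ratio_test(ll_red, ll_full, df_diff)
        comp["lr_statistic"] = stat
        comp["p_value"] = p_val
        report.comparisons["mas_category"] = comp


def selected_categories(selection) -> set:
    """LA feature categories among a model's selected features."""
    names = (
        selection.selected
        if not isinstance(selection.selected, dict)
        else [f for v in selection.selected.values() for f in v]
    )
    cats = set()
    for name in names:
        if name.startswith("la."):
            cats.add(column_category(name[3:]))
    return cats


def run_study(
    config: CohortConfig,
    params: DetectionParams | None = None,
    seed: int | None = None,
    feature_sets: tuple = ("la_only",),
):
    """Full synthetic-study run: generate, extract, scale, fit, evaluate."""
    features, outcomes, covariates, excluded = extract_cohort(config, params)
    scaled, _ = min_max_scale(features)
    cov_scaled, _ = min_max_scale(covariates) if covariates.shape[1] else (None, None)
    report = fit_study_models(
        scaled,
        outcomes,
        covariates_scaled=cov_scaled,
        seed=config.seed if seed is None else seed,
        feature_sets=feature_sets,
    )
    report.excluded = excluded
    return report, features, outcomes
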