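"""Model evaluation: regression fit metrics, effect sizes, classification
metrics from a confusion matrix, and nested-model comparison tests.

Regression models are summarised by :math:`R^2`, the adjusted
:math:`R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)` which penalises the number of
predictors ``p``, Cohen's effect size :math:`f^2 = R^2_{adj}/(1 - R^2_{adj})`
(0.02 / 0.15 / 0.35 read as small / medium / large), and MAE / MSE / RMSE.
Classifiers are summarised from the confusion matrix (rows = actual,
columns = predicted): per-class precision, recall and F1, their macro and
support-weighted averages, and the overall classification accuracy
(OCA = trace / total). Nested linear models are compared with the F-change
test; nested likelihood models with the likelihood-ratio chi-square test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError

EFFECT_SIZE_THRESHOLDS = ((0.35, "large"), (0.15, "medium"), (0.02, "small"))


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R-squared for a model with ``p`` predictors fit on ``n`` samples."""
    if n <= p + 1:
        raise ValidationError(f"adjusted R2 requires n > p + 1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def cohens_f2(adj_r2: float) -> float:
    """Cohen's f-squared effect size computed from an adjusted R-squared."""
    if adj_r2 >= 1.0:
        raise ValidationError("Cohen's f2 undefined for adjusted R2 >= 1")
    return adj_r2 / (1.0 - adj_r2)


def effect_size_label(f2: float) -> str:
    for threshold, label in EFFECT_SIZE_THRESHOLDS:
        if f2 >= threshold:
            return label
    return "negligible"


@dataclass
class RegressionReport:
    n: int
    p: int
    r2: float
    adj_r2: float
    f2: float
    effect_size: str
    mae: float
    mse: float
    rmse: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def regression_metrics(y, y_hat, p: int) -> RegressionReport:
    """Full regression metric suite for predictions ``y_hat`` of ``y``.

    ``p`` is the number of (selected) predictors in the model, used for the
    adjusted R-squared correction.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValidationError("y and y_hat must have equal length")
    n = len(y)
    if n <= p + 1:
        raise ValidationError(f"need n > p + 1 (n={n}, p={p})")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValidationError("R2 undefined: outcome has zero variance")
    sse = float(np.sum((y - y_hat) ** 2))
    r2 = 1.0 - sse / sst
    adj = adjusted_r2(r2, n, p)
    f2 = cohens_f2(adj) if adj < 1.0 else float("inf")
    resid = y - y_hat
    mse = float(np.mean(resid**2))
    return RegressionReport(
        n=n,
        p=p,
        r2=r2,
        adj_r2=adj,
        f2=f2,
        effect_size=effect_size_label(f2),
        mae=float(np.mean(np.abs(resid))),
        mse=mse,
        rmse=float(np.sqrt(mse)),
    )


@dataclass
class ClassificationReport:
    classes: tuple
    confusion: np.ndarray  # rows = actual, cols = predicted
    oca: float
    precision: dict
    recall: dict
    f1: dict
    macro: dict = field(default_factory=dict)
    weighted: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "oca": self.oca,
            "precision": dict(self.precision),
            "recall": dict(self.recall),
            "f1": dict(self.f1),
            "macro": dict(self.macro),
            "weighted": dict(self.weighted),
        }


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """Confusion matrix with rows = actual, columns = predicted."""
    index = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred, strict=True):
        m[index[t], index[p]] += 1
    return m


def classification_report(matrix, classes=None) -> ClassificationReport:
    """Per-class and averaged classification metrics from a confusion matrix.

    precision_c = M[c,c] / column sum; recall_c = M[c,c] / row sum;
    F1_c = harmonic mean; macro = unweighted mean over classes; weighted =
    mean weighted by actual class counts (row sums). A class never predicted
    (empty column) has undefined precision: it is reported as NaN and dropped
    from the macro average with a warning.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if np.any(m < 0) or not np.issubdtype(m.dtype, np.integer):
        if not np.all(m == np.floor(m)) or np.any(m < 0):
            raise ValidationError("confusion matrix entries must be non-negative integers")
        m = m.astype(int)
    k = m.shape[0]
    if classes is None:
        classes = tuple(range(k))
    classes = tuple(classes)
    if len(classes) != k:
        raise ValidationError("class labels must match matrix dimension")

    total = int(m.sum())
    if total == 0:
        raise ValidationError("empty confusion matrix")
    diag = np.diag(m).astype(float)
    col = m.sum(axis=0).astype(float)
    row = m.sum(axis=1).astype(float)

    precision, recall, f1 = {}, {}, {}
    for i, c in enumerate(classes):
        if col[i] == 0:
            warnings.warn(
                f"class {c!r} never predicted; precision undefined and "
                "excluded from the macro average",
                stacklevel=2,
            )
            precision[c] = float("nan")
        else:
            precision[c] = diag[i] / col[i]
        recall[c] = diag[i] / row[i] if row[i] > 0 else float("nan")
        pr, rc = precision[c], recall[c]
        if np.isnan(pr) or np.isnan(rc) or pr + rc == 0:
            f1[c] = float("nan")
        else:
            f1[c] = 2 * pr * rc / (pr + rc)

    def _macro(d):
        vals = [v for v in d.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def _weighted(d):
        num = sum(row[i] * d[c] for i, c in enumerate(classes) if not np.isnan(d[c]))
        den = sum(row[i] for i, c in enumerate(classes) if not np.isnan(d[c]))
        return float(num / den) if den else float("nan")

    return ClassificationReport(
        classes=classes,
        confusion=m,
        oca=float(diag.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro={"precision": _macro(precision), "recall": _macro(recall), "f1": _macro(f1)},
        weighted={
            "precision": _weighted(precision),
            "recall": _weighted(recall),
            "f1": _weighted(f1),
        },
    )


def f_change_test(r2_reduced, r2_full, n, p_reduced, p_full):
    """F test for the R-squared change between nested linear models.

    Returns ``(F, p_value)`` with numerator df = p_full - p_reduced and
    denominator df = n - p_full - 1.
    """
    if p_full <= p_reduced:
        raise ValidationError("p_full must exceed p_reduced")
    if n <= p_full + 1:
        raise ValidationError("need n > p_full + 1")
    if r2_full < r2_reduced:
        raise ValidationError("nested full model cannot have lower R2 than reduced")
    df1 = p_full - p_reduced
    df2 = n - p_full - 1
    f = ((r2_full - r2_reduced) / df1) / ((1.0 - r2_full) / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


def likelihood_ratio_test(loglik_reduced, loglik_full, df_diff):
    """Likelihood-ratio chi-square test between nested likelihood models."""
    if df_diff < 1:
        raise ValidationError("df_diff must be >= 1")
    if loglik_full < loglik_reduced:
        warnings.warn(
            "full model has lower log-likelihood than reduced; statistic clipped at 0",
            stacklevel=2,
        )
    stat = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    return float(stat), float(stats.chi2.sf(stat, df_diff))


def compare_regression_models(adj_r2_reduced: float, adj_r2_full: float) -> dict:
    """Delta summary for a covariates-only vs covariates+LA comparison."""
    delta = adj_r2_full - adj_r2_reduced
    pct = 100.0 * delta / adj_r2_reduced if adj_r2_reduced != 0 else float("inf")
    return {
        "adj_r2_reduced": adj_r2_reduced,
        "adj_r2_full": adj_r2_full,
        "delta_adj_r2": delta,
        "pct_increase": pct,
    }


def compare_classification_models(report_reduced, report_full) -> dict:
    """Delta summary (OCA and weighted F1) between two classifiers."""
    d_oca = report_full.oca - report_reduced.oca
    f1_r = report_reduced.weighted["f1"]
    f1_f = report_full.weighted["f1"]
    return {
        "oca_reduced": report_reduced.oca,
        "oca_full": report_full.oca,
        "delta_oca": d_oca,
        "pct_increase_oca": 100.0 * d_oca / report_reduced.oca if report_reduced.oca else float("inf"),
        "weighted_f1_reduced": f1_r,
        "weighted_f1_full": f1_f,
        "delta_weighted_f1": f1_f - f1_r,
        "pct_increase_weighted_f1": 100.0 * (f1_f - f1_r) / f1_r if f1_r else float("inf"),
    }


def render_model_table(reg_reports: dict, cls_report=None) -> str:
    """Human-readable summary table (3 dp proportions, 2 dp f2, 1 dp percents)."""
    lines = []
    header = (
        f"{'Model':<12}{'p':>4}{'R2':>8}{'adj R2':>9}{'f2':>7}"
        f"{'MAE':>8}{'MSE':>9}{'RMSE':>8}"
    )
    lines.append(header)
    for name, r in reg_reports.items():
        lines.append(
            f"{name:<12}{r.p:>4}{r.r2:>8.3f}{r.adj_r2:>9.3f}{r.f2:>7.2f}"
            f"{r.mae:>8.2f}{r.mse:>9.2f}{r.rmse:>8.2f}"
        )
    if cls_report is not None:
        lines.append("")
        lines.append(f"OCA: {100 * cls_report.oca:.1f}%")
        lines.append(f"{'Class':<12}{'F1':>8}{'Precision':>11}{'Recall':>8}")
        for c in cls_report.classes:
            lines.append(
                f"{str(c):<12}{cls_report.f1[c]:>8.3f}"
                f"{cls_report.precision[c]:>11.3f}{cls_report.recall[c]:>8.3f}"
            )
        for label in ("macro", "weighted"):
            d = getattr(cls_report, label)
            lines.append(
                f"{label:<12}{d['f1']:>8.3f}{d['precision']:>11.3f}{d['recall']:>8.3f}"
            )
    return "\n".join(lines)
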