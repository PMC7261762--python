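"""Evaluation statistics: confusion matrices, one-vs-rest ROC and
precision-recall analysis, F1, optimal cutoffs, bootstrap and exact binomial
confidence intervals.

Curve construction and AUCs are delegated to scikit-learn; this module fixes
the conventions (row = reference class, column = predicted; PR AUC by the
step-interpolation rule, which avoids the optimism of trapezoidal PR
interpolation; "optimal" cutoff = Youden's J with ties broken toward higher
sensitivity) and adds the resampling machinery. No multiple-testing
correction is applied anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn import metrics as skm

from .contrasts import CLASSES
from .errors import DomainError, ValidationError


def confusion_matrix(reference, predicted, classes=CLASSES) -> pd.DataFrame:
    """Count matrix with rows = reference class, columns = predicted class."""
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.shape != predicted.shape:
        raise ValidationError("reference and predicted label arrays must align")
    unknown = (set(reference) | set(predicted)) - set(classes)
    if unknown:
        raise ValidationError(f"unknown label(s) {sorted(unknown)}")
    counts = skm.confusion_matrix(reference, predicted, labels=list(classes))
    return pd.DataFrame(counts, index=list(classes), columns=list(classes))


def _positive_scores(reference, probabilities, positive_class, classes):
    reference = np.asarray(reference)
    probabilities = np.asarray(probabilities, dtype=float)
    if positive_class not in classes:
        raise ValidationError(f"unknown positive class {positive_class!r}")
    if probabilities.ndim == 1:
        scores = probabilities
    else:
        if probabilities.shape != (len(reference), len(classes)):
            raise ValidationError(
                f"probability rows {probabilities.shape} do not match "
                f"{len(reference)} samples x {len(classes)} classes"
            )
        scores = probabilities[:, list(classes).index(positive_class)]
    y = (reference == positive_class).astype(int)
    return y, scores


def roc_one_vs_rest(reference, probabilities, positive_class, classes=CLASSES):
    """One-vs-rest ROC curve and trapezoidal AUC for one class.

    Returns ``(fpr, tpr, thresholds, auc)``.
    """
    y, scores = _positive_scores(reference, probabilities, positive_class, classes)
    if y.sum() == 0 or y.sum() == len(y):
        raise DomainError(
            f"ROC for {positive_class!r} needs at least one positive and one negative sample"
        )
    fpr, tpr, thr = skm.roc_curve(y, scores)
    return fpr, tpr, thr, float(skm.auc(fpr, tpr))


def precision_recall_one_vs_rest(reference, probabilities, positive_class, classes=CLASSES):
    """One-vs-rest precision-recall curve and step-interpolated AUC
    (average precision). Returns ``(precision, recall, thresholds, auc)``."""
    y, scores = _positive_scores(reference, probabilities, positive_class, classes)
    if y.sum() == 0:
        raise DomainError(f"PR curve for {positive_class!r} needs at least one positive sample")
    precision, recall, thr = skm.precision_recall_curve(y, scores)
    return precision, recall, thr, float(skm.average_precision_score(y, scores))


def f1_score(reference, predicted, positive_class, classes=CLASSES) -> float:
    """F1 = 2 P R / (P + R) for one class against the rest; 0 when both
    precision and recall are 0."""
    reference = np.asarray(reference)
    if positive_class not in set(reference):
        raise ValidationError(f"class {positive_class!r} absent from reference labels")
    y_true = (reference == positive_class).astype(int)
    y_pred = (np.asarray(predicted) == positive_class).astype(int)
    return float(skm.f1_score(y_true, y_pred, zero_division=0))


def optimal_cutoff(fpr, tpr, thresholds):
    """Threshold maximizing Youden's J = sensitivity + specificity - 1; ties
    go to the point with higher sensitivity. Returns
    ``(threshold, sensitivity, specificity)``."""
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    j = tpr - fpr
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    idx = candidates[np.argmax(tpr[candidates])]
    return float(thresholds[idx]), float(tpr[idx]), float(1.0 - fpr[idx])


class DegenerateResample(Exception):
    """Raised by a bootstrap statistic when undefined on a resample."""


def bootstrap_ci(statistic, records, n_iter: int = 1000, seed: int = 0, level: float = 0.95):
    """Percentile bootstrap interval of ``statistic(records[idx])``.

    ``records`` is indexable by an integer array (ndarray or DataFrame).
    Resamples on which the statistic is undefined (raises
    ``DegenerateResample`` or ``DomainError``/``ValidationError``, or returns
    NaN) are redrawn; the redraw count is reported via the third return
    value ``(lower, upper, n_redrawn)``.
    """
    n = len(records)
    if n < 2:
        raise ValidationError("bootstrap needs at least 2 records")
    rng = np.random.default_rng(seed)
    is_frame = isinstance(records, pd.DataFrame)
    values = np.empty(n_iter)
    redrawn = 0
    max_attempts = 20 * n_iter
    i = attempts = 0
    while i < n_iter:
        attempts += 1
        if attempts > max_attempts:
            raise DomainError("bootstrap statistic undefined on too many resamples")
        idx = rng.integers(0, n, size=n)
        sample = records.iloc[idx] if is_frame else records[idx]
        try:
            v = statistic(sample)
        except (DegenerateResample, DomainError, ValidationError):
            redrawn += 1
            continue
        if not np.isfinite(v):
            redrawn += 1
            continue
        values[i] = v
        i += 1
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return float(lower), float(upper), redrawn


def binomial_error_ci(n: int, x: int, level: float = 0.95):
    """Exact (Clopper-Pearson) two-sided confidence interval for a
    proportion of x events in n trials."""
    if n <= 0:
        raise DomainError("binomial interval needs n > 0 trials")
    if not 0 <= x <= n:
        raise ValidationError(f"x = {x} outside [0, {n}]")
    ci = binomtest(x, n).proportion_ci(confidence_level=level, method="exact")
    return float(ci.low), float(ci.high)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-class and overall test statistics of one classifier."""

    confusion: pd.DataFrame
    per_class: dict            # class -> dict of statistics (and optional CIs)
    error_rate: float
    error_ci: tuple
    n_test: int
    footer: str = "No multiple-testing correction applied."

    def __post_init__(self):
        total = int(self.confusion.to_numpy().sum())
        if total != self.n_test:
            raise ValidationError(
                f"confusion entries sum to {total}, expected n_test = {self.n_test}"
            )
        trace = float(np.trace(self.confusion.to_numpy()))
        recomputed = 1.0 - trace / total if total else float("nan")
        if abs(recomputed - self.error_rate) > 1e-12:
            raise ValidationError("stored error_rate disagrees with the confusion matrix")

    @property
    def accuracy(self) -> float:
        return 1.0 - self.error_rate

    def to_dict(self) -> dict:
        return {
            "n_test": self.n_test,
            "error_rate": self.error_rate,
            "error_ci": list(self.error_ci),
            "accuracy": self.accuracy,
            "confusion": {
                "classes": list(self.confusion.index),
                "counts": self.confusion.to_numpy().tolist(),
            },
            "per_class": self.per_class,
            "footer": self.footer,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [
            f"n_test = {self.n_test}   error rate = {100 * self.error_rate:.1f}% "
            f"(95% CI {100 * self.error_ci[0]:.1f}-{100 * self.error_ci[1]:.1f}%)",
            "",
            "Confusion matrix (rows = reference, columns = predicted):",
            self.confusion.to_string(),
            "",
            f"{'class':>6} {'ROC AUC':>8} {'PR AUC':>8} {'sens':>6} {'spec':>6} {'F1':>6}",
        ]
        for cls_name, stats in self.per_class.items():
            lines.append(
                f"{cls_name:>6} {stats['roc_auc']:>8.3f} {stats['pr_auc']:>8.3f} "
                f"{stats['sensitivity']:>6.3f} {stats['specificity']:>6.3f} {stats['f1']:>6.3f}"
            )
        lines += ["", self.footer]
        return "\n".join(lines)


def evaluate_predictions(
    reference,
    probabilities,
    classes=CLASSES,
    n_bootstrap: int | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Full report for one model's test-set probability rows.

    Per class: one-vs-rest ROC AUC, PR AUC, sensitivity and specificity at the
    Youden-optimal cutoff, and F1 of the argmax prediction. When
    ``n_bootstrap`` is given, 95% percentile-bootstrap CIs (resampling test
    voxels) are attached to ROC AUC, sensitivity, and specificity.
    """
    reference = np.asarray(reference)
    probabilities = np.asarray(probabilities, dtype=float)
    predicted = np.array(classes)[np.argmax(probabilities, axis=1)]
    confusion = confusion_matrix(reference, predicted, classes)
    n_test = len(reference)
    errors = int(np.sum(reference != predicted))
    error_rate = errors / n_test
    error_ci = binomial_error_ci(n_test, errors)

    per_class = {}
    for ci_cls, cls_name in enumerate(classes):
        fpr, tpr, thr, auc = roc_one_vs_rest(reference, probabilities, cls_name, classes)
        _, _, _, pr_auc = precision_recall_one_vs_rest(reference, probabilities, cls_name, classes)
        _, sens, spec = optimal_cutoff(fpr, tpr, thr)
        stats = {
            "roc_auc": auc,
            "pr_auc": pr_auc,
            "sensitivity": sens,
            "specificity": spec,
            "f1": f1_score(reference, predicted, cls_name, classes),
        }
        if n_bootstrap:
            frame = pd.DataFrame({"ref": reference, "score": probabilities[:, ci_cls]})

            def stat_factory(fn):
                def stat(sample):
                    y = (sample["ref"].to_numpy() == cls_name).astype(int)
                    if y.sum() == 0 or y.sum() == len(y):
                        raise DegenerateResample
                    f, t, th = skm.roc_curve(y, sample["score"].to_numpy())
                    return fn(f, t, th)
                return stat

            lo, hi, _ = bootstrap_ci(
                stat_factory(lambda f, t, th: skm.auc(f, t)), frame, n_bootstrap, seed
            )
            stats["roc_auc_ci"] = [lo, hi]
            lo, hi, _ = bootstrap_ci(
                stat_factory(lambda f, t, th: optimal_cutoff(f, t, th)[1]), frame, n_bootstrap, seed
            )
            stats["sensitivity_ci"] = [lo, hi]
            lo, hi, _ = bootstrap_ci(
                stat_factory(lambda f, t, th: optimal_cutoff(f, t, th)[2]), frame, n_bootstrap, seed
            )
            stats["specificity_ci"] = [lo, hi]
        per_class[cls_name] = stats

    return EvaluationReport(
        confusion=confusion,
        per_class=per_class,
        error_rate=error_rate,
        error_ci=error_ci,
        n_test=n_test,
    )
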