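"""Single-marker expression thresholds for hypermethylator prediction.

For each miR the classifier finds the relative-expression cutoff that
best separates hypermethylator (positive) from non-hypermethylator
(negative) cell lines, scoring every candidate threshold by the
fraction of correct assignments (CA). A sample is called "diminished"
— and thereby predicted hypermethylator — when its expression lies
strictly below the threshold.

The search is exhaustive over midpoints between consecutive distinct
observed values (plus one sentinel below the minimum and one above the
maximum), so the fitted threshold is provably the global optimum of the
chosen objective on the training data. Ties in the objective are broken
by maximal Youden's J (sensitivity + specificity - 1), then by the
lowest threshold, which keeps fits deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "ThresholdModel",
    "candidate_thresholds",
    "classify",
    "confusion_at",
    "diagnostics",
    "fit_threshold",
    "percent",
]

OBJECTIVES = ("max_ca", "max_youden", "prevalence_weighted")


def percent(proportion: float | None) -> int | None:
    """Render a proportion as a whole percent, rounding half-up (0.875 -> 88).

    None (undefined ratio) stays None rather than collapsing to 0.
    """
    if proportion is None:
        return None
    return int(math.floor(proportion * 100.0 + 0.5))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for the diminished-expression call vs hypermethylator status.

    A positive call (value below threshold) predicts hypermethylator
    status, so tp counts hypermethylators called diminished and fp
    counts non-hypermethylators called diminished.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


@dataclass(frozen=True)
class DiagnosticMetrics:
    """CA, sensitivity, specificity, PPV and NPV as exact proportions.

    Undefined ratios (zero denominator) are None, never 0. ``as_percent``
    gives the whole-percent rendering used in reports.
    """

    ca: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def as_percent(self) -> dict[str, int | None]:
        return {
            "ca": percent(self.ca),
            "sensitivity": percent(self.sensitivity),
            "specificity": percent(self.specificity),
            "ppv": percent(self.ppv),
            "npv": percent(self.npv),
        }


def diagnostics(confusion: ConfusionMatrix) -> DiagnosticMetrics:
    """Diagnostic metrics of a confusion matrix (proportions, None if undefined)."""
    if confusion.total == 0:
        raise InsufficientDataError("empty confusion matrix")
    return DiagnosticMetrics(
        ca=_ratio(confusion.tp + confusion.tn, confusion.total),
        sensitivity=_ratio(confusion.tp, confusion.tp + confusion.fn),
        specificity=_ratio(confusion.tn, confusion.tn + confusion.fp),
        ppv=_ratio(confusion.tp, confusion.tp + confusion.fp),
        npv=_ratio(confusion.tn, confusion.tn + confusion.fn),
    )


@dataclass(frozen=True)
class ThresholdModel:
    """A fitted per-marker cutoff with its training confusion and metrics."""

    marker_id: str
    threshold: float
    confusion: ConfusionMatrix
    metrics: DiagnosticMetrics
    objective: str


def candidate_thresholds(values: Sequence[float]) -> np.ndarray:
    """Ordered candidate cutoffs for a set of observed expression values.

    Midpoints between consecutive distinct sorted values, flanked by one
    sentinel below the minimum and one above the maximum (offset by half
    the observed range, or 0.5 when all values coincide). Scanning these
    candidates visits every achievable confusion matrix exactly once.
    """
    v = np.unique(np.asarray(values, dtype=float))
    if v.size == 0:
        raise InsufficientDataError("no values supplied")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    span = v[-1] - v[0]
    pad = span / 2.0 if span > 0 else 0.5
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate(([v[0] - pad], mids, [v[-1] + pad]))


def classify(values: Sequence[float], threshold: float) -> np.ndarray:
    """Boolean diminished-expression calls: strictly below the threshold.

    At-threshold values are *not* diminished.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(values, dtype=float) < threshold


def confusion_at(
    values: Sequence[float], labels: Sequence[bool], threshold: float
) -> ConfusionMatrix:
    """Confusion matrix of the diminished call at a fixed threshold."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    calls = classify(values, threshold)
    return ConfusionMatrix(
        tp=int(np.sum(calls & labels)),
        fp=int(np.sum(calls & ~labels)),
        tn=int(np.sum(~calls & ~labels)),
        fn=int(np.sum(~calls & labels)),
    )


def _objective_value(
    m: DiagnosticMetrics, objective: str, prevalence: float
) -> float:
    sens = m.sensitivity if m.sensitivity is not None else 0.0
    spec = m.specificity if m.specificity is not None else 0.0
    if objective == "max_ca":
        return m.ca if m.ca is not None else 0.0
    if objective == "max_youden":
        return sens + spec - 1.0
    if objective == "prevalence_weighted":
        return prevalence * sens + (1.0 - prevalence) * spec
    raise ValueError(f"unknown objective {objective!r}; expected one of {OBJECTIVES}")


def fit_threshold(
    values: Sequence[float],
    labels: Sequence[bool],
    marker_id: str = "",
    objective: str = "max_ca",
    prevalence: float | None = None,
) -> ThresholdModel:
    """Exhaustively fit the objective-maximising diminished-expression cutoff.

    Parameters
    ----------
    values, labels:
        Relative expression per sample and its binary hypermethylator
        status (True = hypermethylator). Both classes must be present.
    objective:
        ``max_ca`` (default, correct-assignments fraction), ``max_youden``,
        or ``prevalence_weighted`` (prev*sens + (1-prev)*spec, the expected
        posterior correctness at the supplied prevalence).
    prevalence:
        Class prior for ``prevalence_weighted``; defaults to the observed
        positive fraction (in which case the objective coincides with CA).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise DegenerateDataError(
            "threshold fitting requires at least one sample of each class"
        )
    if prevalence is None:
        prevalence = n_pos / labels.size

    best: tuple[float, float, float] | None = None  # (objective, youden, -threshold)
    best_model: ThresholdModel | None = None
    for t in candidate_thresholds(values):
        confusion = confusion_at(values, labels, t)
        metrics = diagnostics(confusion)
        obj = _objective_value(metrics, objective, prevalence)
        sens = metrics.sensitivity or 0.0
        spec = metrics.specificity or 0.0
        key = (obj, sens + spec - 1.0, -t)
        if best is None or key > best:
            best = key
            best_model = ThresholdModel(
                marker_id=marker_id,
                threshold=float(t),
                confusion=confusion,
                metrics=metrics,
                objective=objective,
            )
    assert best_model is not None
    return best_model
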