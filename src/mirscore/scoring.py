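"""Panel calls, composite miR scores and group comparisons.

A marker panel (default: miR-29c, miR-148a, miR-148b, miR-26a, miR-26b,
miR-203) is reduced to a binary samples x markers call matrix —
True where relative expression falls strictly below that marker's
fitted threshold — and each sample's miR score is the row sum, i.e. the
number of panel miRs it expresses at diminished levels (0..panel size).
Group means are compared with an unpaired two-tailed t-test (pooled
variance by default, Welch on request) and reported as mean +/- SEM,
where SEM uses the n-1 sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError
from .thresholds import ThresholdModel

__all__ = [
    "DEFAULT_PANEL",
    "GroupComparison",
    "make_calls",
    "mir_scores",
    "compare_groups",
    "differential_expression",
]

DEFAULT_PANEL = ("miR-29c", "miR-148a", "miR-148b", "miR-26a", "miR-26b", "miR-203")


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary: per-group mean/SEM/n and an unpaired two-tailed t-test.

    ``degenerate`` is set (and ``t``/``p_value`` are None) when both groups
    have zero variance around unequal means, where the t statistic is
    undefined; two *identical* groups yield t = 0, p = 1.
    """

    mean_pos: float
    sem_pos: float
    n_pos: int
    mean_neg: float
    sem_neg: float
    n_neg: int
    t: float | None
    p_value: float | None
    test_variant: str
    degenerate: bool = False


def _as_bool_labels(labels: Sequence[bool] | pd.Series, index: pd.Index) -> pd.Series:
    s = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    if isinstance(labels, pd.Series):
        s = s.reindex(index)
        if s.isna().any():
            missing = list(s.index[s.isna()])
            raise ConfigurationError(f"labels missing for samples {missing}")
    else:
        if len(s) != len(index):
            raise ConfigurationError("labels length does not match number of samples")
        s.index = index
    return s.astype(bool)


def make_calls(
    rq: pd.DataFrame,
    thresholds: Sequence[ThresholdModel] | Mapping[str, float],
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary diminished-expression calls over a marker panel.

    ``rq`` is a samples x targets relative-expression frame;
    ``thresholds`` either fitted models or a marker -> cutoff mapping.
    A cell is True iff RQ is strictly below the marker's threshold.
    """
    if isinstance(thresholds, Mapping):
        cutoff = dict(thresholds)
    else:
        cutoff = {m.marker_id: m.threshold for m in thresholds}
    markers = list(markers) if markers is not None else list(cutoff)
    missing_t = [m for m in markers if m not in cutoff]
    if missing_t:
        raise ConfigurationError(f"no threshold for markers {missing_t}")
    missing_c = [m for m in markers if m not in rq.columns]
    if missing_c:
        raise ConfigurationError(f"markers absent from expression matrix: {missing_c}")
    calls = pd.DataFrame(
        {m: rq[m] < cutoff[m] for m in markers}, index=rq.index, columns=markers
    )
    return calls.astype(bool)


def mir_scores(calls: pd.DataFrame) -> pd.Series:
    """Per-sample miR score: the number of panel miRs called diminished."""
    return calls.astype(bool).sum(axis=1).astype(int).rename("mir_score")


def compare_groups(
    values: Sequence[float] | pd.Series,
    labels: Sequence[bool] | pd.Series,
    test_variant: str = "pooled",
) -> GroupComparison:
    """Mean +/- SEM per group and an unpaired two-tailed t-test.

    ``pooled`` (default) is the classic Student t-test with pooled
    variance; ``welch`` drops the equal-variance assumption.
    """
    if test_variant not in {"pooled", "welch"}:
        raise ConfigurationError(f"unknown test_variant {test_variant!r}")
    values = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    labels = _as_bool_labels(labels, values.index)
    pos = values[labels].to_numpy()
    neg = values[~labels].to_numpy()
    if len(pos) < 2 or len(neg) < 2:
        raise InsufficientDataError(
            "each group needs n >= 2 for SEM and the t-test "
            f"(got {len(pos)} positive, {len(neg)} negative)"
        )
    summary = dict(
        mean_pos=float(pos.mean()),
        sem_pos=float(pos.std(ddof=1) / np.sqrt(len(pos))),
        n_pos=len(pos),
        mean_neg=float(neg.mean()),
        sem_neg=float(neg.std(ddof=1) / np.sqrt(len(neg))),
        n_neg=len(neg),
        test_variant=test_variant,
    )
    if pos.std(ddof=1) == 0.0 and neg.std(ddof=1) == 0.0:
        if pos.mean() == neg.mean():
            return GroupComparison(t=0.0, p_value=1.0, **summary)
        return GroupComparison(t=None, p_value=None, degenerate=True, **summary)
    t, p = stats.ttest_ind(pos, neg, equal_var=(test_variant == "pooled"))
    return GroupComparison(t=float(t), p_value=float(p), **summary)


def differential_expression(
    rq: pd.DataFrame,
    labels: Sequence[bool] | pd.Series,
    test_variant: str = "pooled",
) -> dict[str, GroupComparison]:
    """Per-marker group comparison of relative expression.

    One unpaired two-tailed t-test per marker column, with no
    multiple-testing adjustment; downstream reports flag the p-values as
    nominal. Constant markers come back with ``degenerate=True``.
    """
    out: dict[str, GroupComparison] = {}
    for marker in rq.columns:
        col = rq[marker].astype(float)
        result = compare_groups(col, labels, test_variant)
        if col.std(ddof=0) == 0.0:
            # A flat marker carries no between-group information; flag it
            # rather than reporting the vacuous t = 0.
            result = GroupComparison(
                mean_pos=result.mean_pos,
                sem_pos=result.sem_pos,
                n_pos=result.n_pos,
                mean_neg=result.mean_neg,
                sem_neg=result.sem_neg,
                n_neg=result.n_neg,
                t=None,
                p_value=None,
                test_variant=test_variant,
                degenerate=True,
            )
        out[marker] = result
    return out
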