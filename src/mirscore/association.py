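"""Pearson correlation analyses.

Two uses: (i) associating the composite miR score with the promoter
methylation score and the methylation-sensitive gene expression score
(each an integer 0-9 over the nine biomarker genes, imported from prior
methylation profiling, never recomputed here); and (ii) the full
pairwise co-regulation matrix over the miR panel's expression values.

p-values are the standard two-tailed t transform of r,
t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom. Significance
is flagged at a nominal, unadjusted alpha (0.05 by default) to mirror
how such small-panel screens are usually reported; the flag is
descriptive, not a corrected inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "CorrelationResult",
    "pearson",
    "score_associations",
    "coregulation_matrix",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r between two named variables, with its two-tailed p-value."""

    x_name: str
    y_name: str
    n: int
    r: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
    alpha: float = 0.05,
    log2_transform: bool = False,
) -> CorrelationResult:
    """Pearson correlation with two-tailed significance.

    ``log2_transform`` applies log2 to both vectors first — an option for
    relative-quantity data, which is multiplicative by construction; the
    default correlates raw values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError(f"Pearson correlation needs n >= 3, got n = {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if log2_transform:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log2 transform requires strictly positive values")
        x, y = np.log2(x), np.log2(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError(
            "correlation undefined for a zero-variance vector"
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        n=int(x.size),
        r=float(r),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def score_associations(
    scores: pd.DataFrame, alpha: float = 0.05
) -> list[CorrelationResult]:
    """Correlate the miR score with the expression and methylation scores.

    ``scores`` needs columns ``mir_score``, ``expression_score`` and
    ``methylation_score`` (one row per cell line). Returns the two
    correlations in that order.
    """
    required = ["mir_score", "expression_score", "methylation_score"]
    missing = [c for c in required if c not in scores.columns]
    if missing:
        raise ValueError(f"scores table is missing columns {missing}")
    complete = scores[required].dropna()
    if len(complete) < 3:
        raise InsufficientDataError(
            f"need >= 3 cell lines with all three scores, got {len(complete)}"
        )
    mir = complete["mir_score"].to_numpy(dtype=float)
    return [
        pearson(mir, complete["expression_score"].to_numpy(dtype=float),
                "mir_score", "expression_score", alpha=alpha),
        pearson(mir, complete["methylation_score"].to_numpy(dtype=float),
                "mir_score", "methylation_score", alpha=alpha),
    ]


def coregulation_matrix(
    rq: pd.DataFrame,
    markers: Sequence[str] | None = None,
    alpha: float = 0.05,
    log2_transform: bool = False,
) -> list[CorrelationResult]:
    """All unordered marker-pair correlations of expression across samples.

    Returns C(k, 2) results for a k-marker panel, each flagged
    significant at the nominal (unadjusted) alpha.
    """
    markers = list(markers) if markers is not None else list(rq.columns)
    missing = [m for m in markers if m not in rq.columns]
    if missing:
        raise ValueError(f"markers absent from expression matrix: {missing}")
    return [
        pearson(
            rq[a].to_numpy(dtype=float),
            rq[b].to_numpy(dtype=float),
            a,
            b,
            alpha=alpha,
            log2_transform=log2_transform,
        )
        for a, b in combinations(markers, 2)
    ]
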