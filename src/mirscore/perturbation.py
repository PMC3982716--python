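"""Summaries of pre-miR and antagomir transfection experiments.

Each experiment measures a readout (a miR or DNMT3b mRNA, as relative
quantities) in several arms of one cell line: untransfected control,
non-target control oligomer, and one or more active perturbations
(pre-miR mimics that restore a miR, antagomirs that knock one down).
Every non-control arm is summarised against the untransfected arm as

    fold_change       = mean(treated RQ) / mean(control RQ)
    percent_reduction = (1 - fold_change) * 100

(negative percent reduction = induction), plus an unpaired two-tailed
t-test against the untransfected replicates with star annotations at
p < 0.05 / 0.005 / 0.0005. Fold change is the ratio of arm means, not
the mean of per-replicate ratios, matching how grouped ddCt assays are
reported. A readout whose baseline was censored at the qPCR stage keeps
its ``baseline_censored`` flag: its fold induction is limited by the
assay's cycle ceiling, not a measured quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputValidationError

__all__ = [
    "UNTRANSFECTED",
    "PerturbationSummary",
    "significance_stars",
    "summarize_perturbation",
    "summarize_all",
]

UNTRANSFECTED = "untransfected"
PERTURBATION_KINDS = ("pre_mir", "antagomir", "nontarget_control", UNTRANSFECTED)

_STAR_THRESHOLDS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


def significance_stars(p_value: float | None) -> str:
    """Star annotation for a p-value: * <0.05, ** <0.005, *** <0.0005."""
    if p_value is None or not np.isfinite(p_value):
        return ""
    for cutoff, stars in _STAR_THRESHOLDS:
        if p_value < cutoff:
            return stars
    return ""


@dataclass(frozen=True)
class PerturbationSummary:
    """One treated arm vs the untransfected control for a single readout."""

    cell_line: str
    readout: str
    perturbation: str
    target_mir: str
    fold_change: float
    percent_reduction: float
    p_value: float | None
    stars: str
    n_treated: int
    n_control: int
    degenerate: bool = False
    baseline_censored: bool = False


def _check_replicates(rq: np.ndarray, arm: str) -> None:
    if (rq <= 0).any() or not np.isfinite(rq).all():
        raise InputValidationError(f"relative quantities in arm {arm!r} must be finite and > 0")


def summarize_perturbation(
    records: pd.DataFrame,
    baseline_censored: bool | None = None,
) -> list[PerturbationSummary]:
    """Summarise every non-control arm of one (cell line, readout) experiment.

    ``records`` is a long frame with columns ``cell_line``, ``perturbation``
    (one of pre_mir / antagomir / nontarget_control / untransfected),
    ``target_mir``, ``readout`` and ``rq`` (one row per replicate). Exactly
    one cell line and readout must be present, including an untransfected
    arm with >= 2 replicates.
    """
    required = ["cell_line", "perturbation", "target_mir", "readout", "rq"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise InputValidationError(f"perturbation records missing columns {missing}")
    unknown = set(records["perturbation"]) - set(PERTURBATION_KINDS)
    if unknown:
        raise InputValidationError(f"unknown perturbation kinds {sorted(unknown)}")
    cell_lines = records["cell_line"].unique()
    readouts = records["readout"].unique()
    if len(cell_lines) != 1 or len(readouts) != 1:
        raise ConfigurationError(
            "summarize_perturbation expects one (cell_line, readout) experiment; "
            f"got cell lines {list(cell_lines)}, readouts {list(readouts)}"
        )
    cell_line, readout = cell_lines[0], readouts[0]

    control = records.loc[records["perturbation"] == UNTRANSFECTED, "rq"].to_numpy(dtype=float)
    if control.size == 0:
        raise ConfigurationError(
            f"no untransfected control arm for {cell_line!r} / {readout!r}"
        )
    if control.size < 2:
        raise ConfigurationError(
            f"untransfected control for {cell_line!r} / {readout!r} needs >= 2 replicates"
        )
    _check_replicates(control, UNTRANSFECTED)
    control_mean = control.mean()

    summaries: list[PerturbationSummary] = []
    arms = records.loc[records["perturbation"] != UNTRANSFECTED]
    for (perturbation, target_mir), arm in arms.groupby(
        ["perturbation", "target_mir"], sort=False
    ):
        treated = arm["rq"].to_numpy(dtype=float)
        _check_replicates(treated, str(perturbation))
        fold = treated.mean() / control_mean
        degenerate = treated.std(ddof=1) == 0.0 and control.std(ddof=1) == 0.0
        if degenerate:
            p = 1.0 if treated.mean() == control_mean else None
        else:
            _, p = stats.ttest_ind(treated, control, equal_var=True)
            p = float(p)
        summaries.append(
            PerturbationSummary(
                cell_line=str(cell_line),
                readout=str(readout),
                perturbation=str(perturbation),
                target_mir=str(target_mir),
                fold_change=float(fold),
                percent_reduction=float((1.0 - fold) * 100.0),
                p_value=p,
                stars=significance_stars(p),
                n_treated=int(treated.size),
                n_control=int(control.size),
                degenerate=degenerate,
                baseline_censored=bool(baseline_censored) if baseline_censored is not None else False,
            )
        )
    return summaries


def summarize_all(records: pd.DataFrame) -> list[PerturbationSummary]:
    """Summarise every (cell line, readout) experiment in a combined table."""
    out: list[PerturbationSummary] = []
    for _, group in records.groupby(["cell_line", "readout"], sort=False):
        out.extend(summarize_perturbation(group))
    return out
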