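"""The 16-cell-line breast-cancer reference cohort.

Ten of the sixteen lines carry the hypermethylator defect (DNMT
hyperactivity with DNMT3b overexpression); six do not. The published
study of this cohort reports, for each panel miR, exactly which lines
fall below the fitted expression threshold, and those per-line
exception lists fully determine the 16 x 6 diminished-call matrix, the
per-miR confusion counts and the per-line miR scores. This module
encodes that call matrix so classification-metric and score arithmetic
can be checked end to end without any expression data.

Two variants are shipped because the source is internally inconsistent
about one cell line: the per-miR lists imply BT20 is diminished for
both miR-148b and miR-26b (non-hypermethylator scores {2,2,1,0,0,0},
mean 0.83), while the printed group mean 0.67 +/- 0.33 requires one
fewer call ({1,2,1,0,0,0}). ``prose`` follows the lists; ``printed_mean``
drops BT20's miR-26b call (its miR-148b call is pinned by the
10 TP / 1 FP confusion the same source states). Neither variant is
"corrected" toward the other; the discrepancy is preserved as data.

The cohort's promoter methylation and gene expression scores (integer
0-9 over nine methylation-sensitive biomarker genes) exist only in the
authors' prior profiling work and are not reproduced here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .qpcr import CtTable
from .scoring import DEFAULT_PANEL
from .thresholds import ConfusionMatrix

__all__ = [
    "HYPERMETHYLATOR_LINES",
    "NONHYPERMETHYLATOR_LINES",
    "CALIBRATOR_LINE",
    "VARIANTS",
    "ReferenceCohort",
    "reference_cohort",
    "reference_ct_table",
    "hypermethylator_scores",
    "nonhypermethylator_scores",
]

HYPERMETHYLATOR_LINES = (
    "BT549",
    "Hs578T",
    "HCC1937",
    "MDA-MB-231",
    "MDA-MB-435s",
    "MDA-MB-436",
    "MDA-MB-453",
    "SUM102",
    "SUM149",
    "SUM185",
)
NONHYPERMETHYLATOR_LINES = (
    "BT20",
    "MCF7",
    "MDA-MB-415",
    "MDA-MB-468",
    "SKBR3",
    "ZR-75-1",
)
CALIBRATOR_LINE = "MCF12A"  # normal mammary epithelial reference

VARIANTS = ("prose", "printed_mean")

# Hypermethylator lines NOT below the threshold, per marker.
_HYPER_EXCEPTIONS: dict[str, frozenset[str]] = {
    "miR-29c": frozenset({"MDA-MB-231", "MDA-MB-436", "MDA-MB-453", "BT549"}),
    "miR-148a": frozenset({"MDA-MB-453"}),
    "miR-148b": frozenset(),
    "miR-26a": frozenset({"Hs578T", "MDA-MB-453"}),
    "miR-26b": frozenset({"MDA-MB-453"}),
    "miR-203": frozenset({"MDA-MB-453", "SUM149", "HCC1937"}),
}

# Non-hypermethylator lines that ARE below the threshold, per marker.
_NONHYPER_LOW: dict[str, frozenset[str]] = {
    "miR-29c": frozenset({"MCF7"}),
    "miR-148a": frozenset({"MCF7"}),
    "miR-148b": frozenset({"BT20"}),
    "miR-26a": frozenset(),
    "miR-26b": frozenset({"BT20"}),
    "miR-203": frozenset({"SKBR3"}),
}


@dataclass(frozen=True)
class ReferenceCohort:
    """Call matrix, labels and per-miR confusion counts for the 16-line cohort."""

    variant: str
    calls: pd.DataFrame  # 16 x 6 boolean, True = diminished
    labels: pd.Series  # True = hypermethylator
    confusions: dict[str, ConfusionMatrix]


def _call_matrix(variant: str) -> pd.DataFrame:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    samples = list(HYPERMETHYLATOR_LINES) + list(NONHYPERMETHYLATOR_LINES)
    calls = pd.DataFrame(False, index=samples, columns=list(DEFAULT_PANEL))
    for marker in DEFAULT_PANEL:
        for line in HYPERMETHYLATOR_LINES:
            calls.loc[line, marker] = line not in _HYPER_EXCEPTIONS[marker]
        for line in _NONHYPER_LOW[marker]:
            calls.loc[line, marker] = True
    if variant == "printed_mean":
        calls.loc["BT20", "miR-26b"] = False
    return calls


def reference_cohort(variant: str = "prose") -> ReferenceCohort:
    """Build the reference cohort call matrix in the requested variant."""
    calls = _call_matrix(variant)
    labels = pd.Series(
        [s in HYPERMETHYLATOR_LINES for s in calls.index],
        index=calls.index,
        name="hypermethylator",
    )
    confusions = {}
    for marker in calls.columns:
        col = calls[marker]
        confusions[marker] = ConfusionMatrix(
            tp=int((col & labels).sum()),
            fp=int((col & ~labels).sum()),
            tn=int((~col & ~labels).sum()),
            fn=int((~col & labels).sum()),
        )
    return ReferenceCohort(
        variant=variant, calls=calls, labels=labels, confusions=confusions
    )


def reference_ct_table(
    variant: str = "prose",
    normalizer_ct: float = 22.0,
    base_delta_ct: float = 3.0,
    diminished_shift: float = 3.5,
    n_replicates: int = 3,
) -> CtTable:
    """A noise-free triplicate Ct table consistent with the cohort call matrix.

    Diminished cells sit ``diminished_shift`` cycles above the
    calibrator's target-minus-normalizer dCt (RQ = 2**-shift, about 0.09
    by default); non-diminished cells sit at the calibrator level
    (RQ = 1). Feeding this table through comparative-Ct quantification
    and CA-maximising threshold fitting reproduces the cohort's
    confusion counts exactly, so it serves as a deterministic end-to-end
    input for the full pipeline.
    """
    calls = _call_matrix(variant)
    rows: list[tuple] = []

    def add(sample: str, assay: str, assay_class: str, ct: float) -> None:
        for rep in range(1, n_replicates + 1):
            rows.append((sample, assay, assay_class, rep, ct))

    for sample in [CALIBRATOR_LINE, *calls.index]:
        add(sample, "RNU66", "mir_normalizer", normalizer_ct)
        for marker in calls.columns:
            shift = 0.0
            if sample != CALIBRATOR_LINE and bool(calls.loc[sample, marker]):
                shift = diminished_shift
            add(sample, marker, "mir_target", normalizer_ct + base_delta_ct + shift)
    return CtTable(pd.DataFrame(rows, columns=["sample_id", "assay_id", "assay_class", "replicate", "ct"]))


def hypermethylator_scores(variant: str = "prose") -> pd.Series:
    """miR scores of the ten hypermethylator lines (identical across variants)."""
    cohort = reference_cohort(variant)
    return cohort.calls.loc[list(HYPERMETHYLATOR_LINES)].sum(axis=1).astype(int)


def nonhypermethylator_scores(variant: str = "prose") -> pd.Series:
    """miR scores of the six non-hypermethylator lines (variant-dependent)."""
    cohort = reference_cohort(variant)
    return cohort.calls.loc[list(NONHYPERMETHYLATOR_LINES)].sum(axis=1).astype(int)
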