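"""Readers and writers for the pipeline's tab-separated interchange formats.

The canonical Ct input is a long-format TSV/CSV with header
``sample_id  assay_id  assay_class  replicate  ct`` where ``ct`` is a
cycle number or the censored tokens ``NA`` / ``Undetermined`` (vendor
exports differ; a column-mapping option covers renamed headers).
Annotations map ``sample_id`` to ``group`` (hypermethylator /
non_hypermethylator). All writers produce plain TSV that round-trips
through the matching reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputValidationError
from .qpcr import CtTable
from .thresholds import ConfusionMatrix, DiagnosticMetrics, ThresholdModel

__all__ = [
    "read_ct_table",
    "read_annotations",
    "read_rq",
    "write_rq",
    "read_thresholds",
    "write_thresholds",
    "read_sample_scores",
    "write_scores",
    "read_perturbation_records",
]

CENSORED_TOKENS = {"na", "undetermined", "undet", ""}

GROUP_LEVELS = {"hypermethylator": True, "non_hypermethylator": False}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_ct_table(
    path: str | Path,
    max_cycles: float = 40.0,
    column_map: Mapping[str, str] | None = None,
) -> CtTable:
    """Parse a long-format Ct file into a validated :class:`CtTable`.

    ``column_map`` renames vendor headers onto the canonical ones, e.g.
    ``{"Sample Name": "sample_id"}``. Malformed rows are reported with
    their 1-based line number (header = line 1).
    """
    df = _read_table(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["sample_id", "assay_id", "assay_class", "replicate", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw_ct = str(getattr(row, "ct")).strip()
        if raw_ct.lower() in CENSORED_TOKENS:
            ct = np.nan
        else:
            try:
                ct = float(raw_ct)
            except ValueError:
                raise InputValidationError(
                    f"{path}:{i}: non-numeric ct value {raw_ct!r}"
                ) from None
        try:
            replicate = int(str(getattr(row, "replicate")).strip())
        except ValueError:
            raise InputValidationError(
                f"{path}:{i}: non-integer replicate {getattr(row, 'replicate')!r}"
            ) from None
        records.append(
            (
                str(getattr(row, "sample_id")).strip(),
                str(getattr(row, "assay_id")).strip(),
                str(getattr(row, "assay_class")).strip(),
                replicate,
                ct,
            )
        )
    frame = pd.DataFrame(
        records, columns=["sample_id", "assay_id", "assay_class", "replicate", "ct"]
    )
    return CtTable(frame, max_cycles=max_cycles)


def read_annotations(path: str | Path) -> pd.Series:
    """Read sample annotations; returns a boolean Series (True = hypermethylator)."""
    df = _read_table(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise InputValidationError(f"{path}: missing column {col!r}")
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise InputValidationError(
            f"{path}: duplicate sample_id {df.loc[dup, 'sample_id'].iloc[0]!r}"
        )
    unknown = set(df["group"]) - set(GROUP_LEVELS)
    if unknown:
        raise InputValidationError(
            f"{path}: unknown group values {sorted(unknown)}; "
            f"expected {sorted(GROUP_LEVELS)}"
        )
    return pd.Series(
        [GROUP_LEVELS[g] for g in df["group"]],
        index=df["sample_id"].tolist(),
        name="hypermethylator",
    )


def write_rq(rq: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x targets relative-expression matrix as wide TSV."""
    rq.to_csv(path, sep="\t", index_label="sample_id")


def read_rq(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", float_precision="round_trip")
    return df.astype(float)


def write_thresholds(models: Sequence[ThresholdModel], path: str | Path) -> None:
    """One row per marker: threshold, confusion counts and diagnostic metrics."""
    rows = []
    for m in models:
        row = {
            "marker_id": m.marker_id,
            "threshold": m.threshold,
            "objective": m.objective,
            "tp": m.confusion.tp,
            "fp": m.confusion.fp,
            "tn": m.confusion.tn,
            "fn": m.confusion.fn,
        }
        for name in ("ca", "sensitivity", "specificity", "ppv", "npv"):
            value = getattr(m.metrics, name)
            row[name] = value if value is not None else "NA"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_thresholds(path: str | Path) -> list[ThresholdModel]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    models = []
    for row in df.itertuples(index=False):
        confusion = ConfusionMatrix(tp=int(row.tp), fp=int(row.fp), tn=int(row.tn), fn=int(row.fn))
        metrics = DiagnosticMetrics(
            ca=None if pd.isna(row.ca) else float(row.ca),
            sensitivity=None if pd.isna(row.sensitivity) else float(row.sensitivity),
            specificity=None if pd.isna(row.specificity) else float(row.specificity),
            ppv=None if pd.isna(row.ppv) else float(row.ppv),
            npv=None if pd.isna(row.npv) else float(row.npv),
        )
        models.append(
            ThresholdModel(
                marker_id=str(row.marker_id),
                threshold=float(row.threshold),
                confusion=confusion,
                metrics=metrics,
                objective=str(row.objective),
            )
        )
    return models


def read_sample_scores(path: str | Path) -> pd.DataFrame:
    """Per-sample integer scores (mir_score and/or methylation/expression scores)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id", float_precision="round_trip")
    return df.apply(pd.to_numeric)


def write_scores(scores: pd.DataFrame | pd.Series, path: str | Path) -> None:
    frame = scores.to_frame() if isinstance(scores, pd.Series) else scores
    frame.to_csv(path, sep="\t", index_label="sample_id")


def read_perturbation_records(path: str | Path) -> pd.DataFrame:
    """Long-format perturbation replicates: cell_line, perturbation, target_mir, readout, rq."""
    df = _read_table(path)
    required = ["cell_line", "perturbation", "target_mir", "readout", "rq"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing columns {missing}")
    df = df.copy()
    try:
        df["rq"] = df["rq"].astype(float)
    except ValueError as exc:
        raise InputValidationError(f"{path}: non-numeric rq value ({exc})") from None
    return df
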