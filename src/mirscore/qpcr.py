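"""Comparative-Ct (2^-ddCt) relative quantification.

Turns replicate-level threshold-cycle (Ct) measurements into relative
expression values against a small-RNA or mRNA normalizer assay and a
calibrator sample, the standard comparative-Ct workflow for TaqMan
qPCR panels:

    dCt(s, g)  = mean Ct(s, g) - mean Ct(s, normalizer)
    ddCt(s, g) = dCt(s, g) - dCt(calibrator, g)
    RQ(s, g)   = 2 ** -ddCt(s, g)

Amplification efficiency is assumed to be 2 for every assay; replicate
Ct values are combined by arithmetic mean before any exponentiation.
"Undetermined" wells (no amplification within ``max_cycles`` cycles) are
carried as censored observations and, under the default policy, imputed
at ``max_cycles`` so that undetectable targets appear as near-zero RQ
with an explicit censored flag rather than as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputValidationError, MissingDataError

__all__ = [
    "ASSAY_CLASSES",
    "CtTable",
    "QuantConfig",
    "ExpressionMatrix",
    "aggregate_replicates",
    "relative_expression",
]

#: Recognised assay classes. ``*_target`` assays are quantified; each is
#: normalised against the ``*_normalizer`` assay of the same nucleic-acid kind.
ASSAY_CLASSES = ("mir_target", "mir_normalizer", "mrna_target", "mrna_normalizer")

_TARGET_TO_NORMALIZER_CLASS = {
    "mir_target": "mir_normalizer",
    "mrna_target": "mrna_normalizer",
}

_CT_COLUMNS = ["sample_id", "assay_id", "assay_class", "replicate", "ct"]


@dataclass(frozen=True)
class CtTable:
    """Long-format table of replicate-level Ct measurements.

    ``data`` holds one row per well with columns ``sample_id``, ``assay_id``,
    ``assay_class``, ``replicate`` (1-based integer, unique within a
    (sample, assay) group) and ``ct`` (cycles; NaN encodes a censored /
    "Undetermined" well). Validation happens at construction.
    """

    data: pd.DataFrame
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _CT_COLUMNS if c not in df.columns]
        if missing:
            raise InputValidationError(f"Ct table is missing columns: {missing}")
        df = df.loc[:, _CT_COLUMNS].copy()
        df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
        bad_class = set(df["assay_class"]) - set(ASSAY_CLASSES)
        if bad_class:
            raise InputValidationError(
                f"Unknown assay_class values {sorted(bad_class)}; expected one of {ASSAY_CLASSES}"
            )
        if (df["replicate"] < 1).any() or (df["replicate"] != df["replicate"].astype(int)).any():
            raise InputValidationError("replicate indices must be positive integers")
        dup = df.duplicated(subset=["sample_id", "assay_id", "replicate"], keep=False)
        if dup.any():
            first = df.loc[dup, ["sample_id", "assay_id", "replicate"]].iloc[0]
            raise InputValidationError(
                "duplicate replicate: sample "
                f"{first['sample_id']!r}, assay {first['assay_id']!r}, replicate {int(first['replicate'])}"
            )
        finite = df["ct"].dropna()
        if ((finite < 0) | (finite > self.max_cycles)).any():
            bad = finite[(finite < 0) | (finite > self.max_cycles)].iloc[0]
            raise InputValidationError(
                f"Ct value {bad} outside [0, {self.max_cycles}] — negative or overflow cycle counts are invalid"
            )
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        max_cycles: float = 40.0,
    ) -> "CtTable":
        """Build from an iterable of (sample_id, assay_id, assay_class, replicate, ct).

        ``ct`` may be a float, None, or the strings "NA"/"Undetermined"
        (case-insensitive) for censored wells.
        """
        rows = []
        for rec in records:
            sample_id, assay_id, assay_class, replicate, ct = rec
            if isinstance(ct, str):
                if ct.strip().lower() in {"na", "undetermined", ""}:
                    ct = np.nan
                else:
                    try:
                        ct = float(ct)
                    except ValueError as exc:
                        raise InputValidationError(f"non-numeric ct value {ct!r}") from exc
            rows.append((sample_id, assay_id, assay_class, int(replicate), ct))
        df = pd.DataFrame(rows, columns=_CT_COLUMNS)
        return cls(df, max_cycles=max_cycles)

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample_id"]))

    @property
    def assays(self) -> list[str]:
        return list(pd.unique(self.data["assay_id"]))

    def assay_class_of(self) -> pd.Series:
        """assay_id -> assay_class mapping (must be consistent across rows)."""
        classes = self.data.groupby("assay_id")["assay_class"].unique()
        conflict = classes[classes.map(len) > 1]
        if len(conflict):
            raise InputValidationError(
                f"assay {conflict.index[0]!r} appears with multiple assay_class values"
            )
        return classes.map(lambda a: a[0])


@dataclass(frozen=True)
class QuantConfig:
    """Configuration for comparative-Ct quantification.

    Parameters
    ----------
    normalizer_assays:
        Maps each target assay class to the assay id used for
        normalization. Defaults: small nucleolar RNA RNU66 for miRs,
        beta-actin for mRNAs.
    calibrator_sample:
        Sample against which ddCt is referenced (RQ = 1 by construction).
        Defaults to the normal mammary epithelial line MCF12A.
    censored_policy:
        ``impute_max`` (default) replaces censored Ct with ``max_cycles``
        and flags the group; ``drop`` discards censored replicates;
        ``error`` refuses censored input.
    """

    normalizer_assays: Mapping[str, str] = field(
        default_factory=lambda: {"mir_target": "RNU66", "mrna_target": "ACTB"}
    )
    calibrator_sample: str = "MCF12A"
    max_cycles: float = 40.0
    censored_policy: str = "impute_max"

    def __post_init__(self) -> None:
        if self.censored_policy not in {"impute_max", "drop", "error"}:
            raise ConfigurationError(
                f"unknown censored_policy {self.censored_policy!r}"
            )
        unknown = set(self.normalizer_assays) - set(_TARGET_TO_NORMALIZER_CLASS)
        if unknown:
            raise ConfigurationError(
                f"normalizer_assays keys must be target classes, got {sorted(unknown)}"
            )
        if self.max_cycles <= 0:
            raise ConfigurationError("max_cycles must be positive")

    def to_dict(self) -> dict:
        return {
            "normalizer_assays": dict(self.normalizer_assays),
            "calibrator_sample": self.calibrator_sample,
            "max_cycles": self.max_cycles,
            "censored_policy": self.censored_policy,
        }


@dataclass(frozen=True)
class ExpressionMatrix:
    """Relative expression (RQ) with its dCt / ddCt provenance.

    ``rq``, ``delta_ct``, ``delta_delta_ct`` and ``censored`` are
    samples x targets DataFrames sharing index and columns; ``censored``
    marks cells whose target group was fully censored (RQ is then a
    lower bound on suppression, limited by the assay's cycle ceiling).
    """

    rq: pd.DataFrame
    delta_ct: pd.DataFrame
    delta_delta_ct: pd.DataFrame
    censored: pd.DataFrame
    config: QuantConfig

    @property
    def samples(self) -> list[str]:
        return list(self.rq.index)

    @property
    def targets(self) -> list[str]:
        return list(self.rq.columns)


def _apply_censoring(table: CtTable, config: QuantConfig) -> pd.DataFrame:
    df = table.data.copy()
    censored = df["ct"].isna()
    if config.censored_policy == "error":
        if censored.any():
            row = df.loc[censored].iloc[0]
            raise MissingDataError(
                f"censored Ct for sample {row['sample_id']!r}, assay {row['assay_id']!r} "
                "under censored_policy='error'"
            )
    elif config.censored_policy == "impute_max":
        df.loc[censored, "ct"] = config.max_cycles
    df["censored"] = censored
    return df


def aggregate_replicates(table: CtTable, config: QuantConfig | None = None) -> pd.DataFrame:
    """Collapse replicates to one mean Ct per (sample, assay) group.

    Returns a DataFrame with columns ``sample_id``, ``assay_id``,
    ``assay_class``, ``mean_ct``, ``sd_ct``, ``sem_ct``, ``n_replicates``
    and ``censored`` (True when every replicate in the group was
    censored, only possible under ``impute_max``).
    """
    config = config or QuantConfig()
    df = _apply_censoring(table, config)
    if config.censored_policy == "drop":
        kept = df.loc[~df["censored"]]
        empty = (
            df.groupby(["sample_id", "assay_id"], sort=False)["censored"].all()
        )
        if empty.any():
            sample_id, assay_id = empty.index[np.argmax(empty.values)]
            raise MissingDataError(
                f"no usable replicates for sample {sample_id!r}, assay {assay_id!r} "
                "after dropping censored wells"
            )
        df = kept
    grouped = df.groupby(["sample_id", "assay_id", "assay_class"], sort=False)
    out = grouped.agg(
        mean_ct=("ct", "mean"),
        sd_ct=("ct", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        n_replicates=("ct", "size"),
        censored=("censored", "all"),
    ).reset_index()
    out["sem_ct"] = out["sd_ct"] / np.sqrt(out["n_replicates"])
    return out


def relative_expression(table: CtTable, config: QuantConfig | None = None) -> ExpressionMatrix:
    """Comparative-Ct quantification of every target assay in the table.

    Each ``mir_target`` assay is normalised against the configured miR
    normalizer, each ``mrna_target`` against the mRNA normalizer, and
    all ddCt values are referenced to the calibrator sample's dCt.
    """
    config = config or QuantConfig()
    agg = aggregate_replicates(table, config)
    mean_ct = agg.pivot(index="sample_id", columns="assay_id", values="mean_ct")
    # preserve first-appearance order of samples and assays rather than
    # the lexicographic order pivot imposes
    mean_ct = mean_ct.reindex(
        index=pd.unique(agg["sample_id"]), columns=pd.unique(agg["assay_id"])
    )
    cens = (
        agg.pivot(index="sample_id", columns="assay_id", values="censored")
        .reindex(index=mean_ct.index)
        .fillna(False)
    )
    if config.calibrator_sample not in mean_ct.index:
        raise ConfigurationError(
            f"calibrator sample {config.calibrator_sample!r} not present in the Ct table"
        )
    assay_class = table.assay_class_of()
    targets = [a for a in mean_ct.columns if assay_class[a] in _TARGET_TO_NORMALIZER_CLASS]
    if not targets:
        raise ConfigurationError("Ct table contains no target assays")

    delta_ct = pd.DataFrame(index=mean_ct.index, columns=targets, dtype=float)
    for target in targets:
        norm_assay = config.normalizer_assays.get(assay_class[target])
        if norm_assay is None:
            raise ConfigurationError(
                f"no normalizer configured for assay class {assay_class[target]!r}"
            )
        if norm_assay not in mean_ct.columns:
            raise ConfigurationError(
                f"normalizer assay {norm_assay!r} missing from the Ct table"
            )
        norm_ct = mean_ct[norm_assay]
        missing = norm_ct.isna() | mean_ct[target].isna()
        if missing.any():
            sample = missing.index[np.argmax(missing.values)]
            raise MissingDataError(
                f"sample {sample!r} lacks a measurement for {target!r} or its normalizer {norm_assay!r}"
            )
        delta_ct[target] = mean_ct[target] - norm_ct

    ddct = delta_ct - delta_ct.loc[config.calibrator_sample]
    rq = np.exp2(-ddct)
    return ExpressionMatrix(
        rq=rq,
        delta_ct=delta_ct,
        delta_delta_ct=ddct,
        censored=cens.loc[:, targets].astype(bool),
        config=config,
    )
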