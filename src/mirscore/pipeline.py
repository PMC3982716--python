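"""End-to-end report: quantify -> differential expression -> thresholds ->
calls/scores -> group comparison -> correlations (-> perturbations).

``run_report`` orchestrates the library stages in the order the
underlying study presents them, writes every intermediate as TSV plus a
versioned JSON summary, and echoes its configuration so a run is
reproducible from its own output directory. Any stage failure is
re-raised annotated with the stage name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from . import io as mio
from .association import coregulation_matrix, score_associations
from .errors import MirscoreError
from .perturbation import summarize_all
from .qpcr import QuantConfig, relative_expression
from .scoring import DEFAULT_PANEL, compare_groups, differential_expression, make_calls, mir_scores
from .thresholds import fit_threshold

__all__ = ["RunConfig", "run_report", "SUMMARY_SCHEMA_VERSION"]

SUMMARY_SCHEMA_VERSION = 1

logger = logging.getLogger("mirscore")


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for a full pipeline run; fully JSON-serialisable."""

    ct_path: str
    annotations_path: str
    out_dir: str
    scores_path: str | None = None  # methylation/expression scores, optional
    perturbation_path: str | None = None
    panel: tuple[str, ...] = DEFAULT_PANEL
    quant: QuantConfig = field(default_factory=QuantConfig)
    objective: str = "max_ca"
    test_variant: str = "pooled"
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "ct_path": self.ct_path,
            "annotations_path": self.annotations_path,
            "out_dir": self.out_dir,
            "scores_path": self.scores_path,
            "perturbation_path": self.perturbation_path,
            "panel": list(self.panel),
            "quant": self.quant.to_dict(),
            "objective": self.objective,
            "test_variant": self.test_variant,
            "alpha": self.alpha,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        quant = d.pop("quant", None)
        panel = d.pop("panel", DEFAULT_PANEL)
        cfg = cls(
            **d,
            panel=tuple(panel),
            quant=QuantConfig(**quant) if isinstance(quant, Mapping) else QuantConfig(),
        )
        return cfg


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise MirscoreError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _comparison_dict(c) -> dict:
    return {
        "mean_hyper": c.mean_pos,
        "sem_hyper": c.sem_pos,
        "n_hyper": c.n_pos,
        "mean_nonhyper": c.mean_neg,
        "sem_nonhyper": c.sem_neg,
        "n_nonhyper": c.n_neg,
        "t": c.t,
        "p_value": c.p_value,
        "test_variant": c.test_variant,
        "degenerate": c.degenerate,
    }


def run_report(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``config.out_dir``.

    Returns the JSON-serialisable summary dict that is also written to
    ``summary.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read_inputs"):
        table = mio.read_ct_table(config.ct_path, max_cycles=config.quant.max_cycles)
        labels = mio.read_annotations(config.annotations_path)

    with _stage("quantify"):
        expr = relative_expression(table, config.quant)
        mio.write_rq(expr.rq, out / "rq.tsv")
        cohort_samples = [s for s in expr.samples if s in labels.index]
        rq = expr.rq.loc[cohort_samples]
        rq_labels = labels.loc[cohort_samples]

    with _stage("differential_expression"):
        de = differential_expression(rq, rq_labels, config.test_variant)
        de_frame = pd.DataFrame({m: _comparison_dict(c) for m, c in de.items()}).T
        de_frame.to_csv(out / "differential_expression.tsv", sep="\t", index_label="marker")

    with _stage("thresholds"):
        panel = [m for m in config.panel if m in rq.columns]
        missing = [m for m in config.panel if m not in rq.columns]
        if missing:
            raise MirscoreError(f"panel markers missing from expression data: {missing}")
        models = [
            fit_threshold(
                rq[m].to_numpy(), rq_labels.to_numpy(), marker_id=m, objective=config.objective
            )
            for m in panel
        ]
        mio.write_thresholds(models, out / "thresholds.tsv")

    with _stage("scores"):
        calls = make_calls(rq, models, markers=panel)
        scores = mir_scores(calls)
        calls.astype(int).to_csv(out / "calls.tsv", sep="\t", index_label="sample_id")
        mio.write_scores(scores, out / "scores.tsv")
        group_cmp = compare_groups(scores, rq_labels, config.test_variant)

    with _stage("correlations"):
        coreg = coregulation_matrix(rq, panel, alpha=config.alpha)
        coreg_frame = pd.DataFrame(
            [
                {
                    "marker_a": c.x_name,
                    "marker_b": c.y_name,
                    "n": c.n,
                    "r": c.r,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in coreg
            ]
        )
        coreg_frame.to_csv(out / "coregulation.tsv", sep="\t", index=False)
        associations = None
        if config.scores_path is not None:
            ext = mio.read_sample_scores(config.scores_path)
            merged = ext.join(scores, how="inner")
            associations = score_associations(merged, alpha=config.alpha)

    perturb_rows = None
    if config.perturbation_path is not None:
        with _stage("perturbation"):
            records = mio.read_perturbation_records(config.perturbation_path)
            perturb = summarize_all(records)
            perturb_rows = [
                {
                    "cell_line": s.cell_line,
                    "readout": s.readout,
                    "perturbation": s.perturbation,
                    "target_mir": s.target_mir,
                    "fold_change": s.fold_change,
                    "percent_reduction": s.percent_reduction,
                    "p_value": s.p_value,
                    "stars": s.stars,
                }
                for s in perturb
            ]
            pd.DataFrame(perturb_rows).to_csv(
                out / "perturbation_summary.tsv", sep="\t", index=False
            )

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "software_version": __version__,
        "config": config.to_dict(),
        "n_samples": len(cohort_samples),
        "thresholds": {
            m.marker_id: {
                "threshold": m.threshold,
                "confusion": {"tp": m.confusion.tp, "fp": m.confusion.fp,
                              "tn": m.confusion.tn, "fn": m.confusion.fn},
                "metrics_percent": m.metrics.as_percent(),
            }
            for m in models
        },
        "differential_expression": {m: _comparison_dict(c) for m, c in de.items()},
        "mir_scores": {str(k): int(v) for k, v in scores.items()},
        "group_comparison": _comparison_dict(group_cmp),
        "score_associations": None
        if associations is None
        else [
            {"pair": [c.x_name, c.y_name], "n": c.n, "r": c.r,
             "p_value": c.p_value, "significant": c.significant}
            for c in associations
        ],
        "coregulation_significant_pairs": int(sum(c.significant for c in coreg)),
        "perturbation": perturb_rows,
        "notes": [
            "p-values are nominal (no multiple-testing correction applied)",
        ],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
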