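"""Synthetic qPCR cohorts with the statistical structure the analysis assumes.

The generator emulates the study design the pipeline targets: two
groups of breast-cancer cell lines (10 hypermethylator, 6 non-
hypermethylator) plus a normal-epithelial calibrator line, assayed in
triplicate for a panel of miRs and a small-RNA normalizer. Simulation
happens at the Ct level — per-well threshold cycles drawn from normal
distributions — so the whole pipeline, including normalisation and
calibration, is exercised rather than just downstream arithmetic.

Per marker, hypermethylator samples are shifted by a configurable
number of cycles above the non-hypermethylator mean dCt (default 4
cycles, a 16-fold expression drop — the order of magnitude separating
the groups for the informative panel miRs). Promoter methylation and
biomarker-gene expression scores are generated on the 0-9 integer
scale of the nine-gene biomarker panel as monotone functions of each
sample's true diminished-marker count plus bounded integer jitter, so
score-association analyses have a recoverable signed signal.

Everything is driven by one seeded NumPy generator: a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .qpcr import CtTable
from .scoring import DEFAULT_PANEL

__all__ = ["SyntheticConfig", "SyntheticCohort", "simulate_cohort"]

N_BIOMARKER_GENES = 9  # methylation/expression scores live on 0..9


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a two-group qPCR cohort.

    ``hyper_shift_ct`` maps each marker to the extra cycles a
    hypermethylator sample's target Ct carries (0 = marker uninformative);
    markers absent from the mapping default to ``default_shift_ct``.
    ``between_sample_sd`` is biological spread of per-sample mean dCt,
    ``replicate_sd`` the technical well-to-well spread, both in cycles.
    """

    n_hyper: int = 10
    n_nonhyper: int = 6
    markers: tuple[str, ...] = DEFAULT_PANEL
    default_shift_ct: float = 4.0
    hyper_shift_ct: Mapping[str, float] = field(default_factory=dict)
    base_delta_ct: float = 3.0
    between_sample_sd: float = 0.5
    replicate_sd: float = 0.3
    normalizer_assay: str = "RNU66"
    normalizer_mean_ct: float = 22.0
    normalizer_sd: float = 0.25
    n_replicates: int = 3
    score_noise: int = 1
    max_cycles: float = 40.0
    calibrator_sample: str = "MCF12A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hyper < 1 or self.n_nonhyper < 1:
            raise ConfigurationError("group sizes must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for name in ("between_sample_sd", "replicate_sd", "normalizer_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.score_noise < 0:
            raise ConfigurationError("score_noise must be >= 0")
        unknown = set(self.hyper_shift_ct) - set(self.markers)
        if unknown:
            raise ConfigurationError(f"hyper_shift_ct names unknown markers {sorted(unknown)}")

    def shift_for(self, marker: str) -> float:
        return float(self.hyper_shift_ct.get(marker, self.default_shift_ct))


@dataclass(frozen=True)
class SyntheticCohort:
    """A simulated cohort: raw Ct table, group labels and integer scores."""

    ct_table: CtTable
    labels: pd.Series  # True = hypermethylator; calibrator not included
    sample_scores: pd.DataFrame  # mir-related truth + methylation/expression scores
    config: SyntheticConfig


def _draw_ct(rng: np.random.Generator, mean: float, sd: float, n: int, max_cycles: float) -> np.ndarray:
    ct = rng.normal(mean, sd, size=n)
    return np.clip(ct, 0.0, max_cycles)


def simulate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Simulate replicate-level Ct data for a two-group cohort.

    Returns the Ct table (including the calibrator sample), boolean
    hypermethylator labels for the 16 (by default) cohort samples, and a
    per-sample score frame with columns ``true_diminished``,
    ``methylation_score`` and ``expression_score``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    hyper = [f"HYPER-{i + 1:02d}" for i in range(config.n_hyper)]
    nonhyper = [f"NONHYPER-{i + 1:02d}" for i in range(config.n_nonhyper)]
    samples = hyper + nonhyper
    labels = pd.Series(
        [True] * len(hyper) + [False] * len(nonhyper), index=samples, name="hypermethylator"
    )

    rows: list[tuple] = []

    def emit(sample: str, assay: str, assay_class: str, mean: float) -> None:
        cts = _draw_ct(rng, mean, config.replicate_sd, config.n_replicates, config.max_cycles)
        for rep, ct in enumerate(cts, start=1):
            rows.append((sample, assay, assay_class, rep, float(ct)))

    # Calibrator: baseline dCt for every marker, no group shift.
    all_samples = [config.calibrator_sample, *samples]
    for sample in all_samples:
        norm_mean = rng.normal(config.normalizer_mean_ct, config.normalizer_sd)
        emit(sample, config.normalizer_assay, "mir_normalizer", norm_mean)
        for marker in config.markers:
            shift = config.shift_for(marker) if (sample in hyper) else 0.0
            sample_effect = (
                rng.normal(0.0, config.between_sample_sd)
                if sample != config.calibrator_sample
                else 0.0
            )
            target_mean = norm_mean + config.base_delta_ct + shift + sample_effect
            emit(sample, marker, "mir_target", target_mean)

    table = CtTable(
        pd.DataFrame(rows, columns=["sample_id", "assay_id", "assay_class", "replicate", "ct"]),
        max_cycles=config.max_cycles,
    )

    # True diminished count per sample: markers whose group shift is > 0.
    shifted = sum(1 for m in config.markers if config.shift_for(m) > 0)
    true_dim = np.where(labels.to_numpy(), shifted, 0)
    scale = N_BIOMARKER_GENES / max(len(config.markers), 1)
    jitter = rng.integers(-config.score_noise, config.score_noise + 1, size=len(samples))
    meth = np.clip(np.rint(true_dim * scale) + jitter, 0, N_BIOMARKER_GENES).astype(int)
    jitter2 = rng.integers(-config.score_noise, config.score_noise + 1, size=len(samples))
    expr = np.clip(
        N_BIOMARKER_GENES - np.rint(true_dim * scale) + jitter2, 0, N_BIOMARKER_GENES
    ).astype(int)
    scores = pd.DataFrame(
        {
            "true_diminished": true_dim,
            "methylation_score": meth,
            "expression_score": expr,
        },
        index=samples,
    )
    return SyntheticCohort(ct_table=table, labels=labels, sample_scores=scores, config=config)
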