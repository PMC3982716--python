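"""Threshold search, diagnostic metrics and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mirscore as ms
from mirscore.thresholds import (
    candidate_thresholds,
    classify,
    confusion_at,
    diagnostics,
    fit_threshold,
    percent,
)

from conftest import brute_force_best_ca


class TestCandidateThresholds:
    def test_midpoints_plus_sentinels(self):
        cands = candidate_thresholds([0.1, 0.2, 0.8])
        assert cands[0] < 0.1 and cands[-1] > 0.8
        assert list(cands[1:-1]) == pytest.approx([0.15, 0.5])

    def test_degenerate_all_identical(self):
        cands = candidate_thresholds([0.3, 0.3, 0.3])
        assert len(cands) == 2
        assert cands[0] < 0.3 < cands[1]

    def test_count_is_distinct_minus_one_plus_two(self):
        assert len(candidate_thresholds([1, 2, 3, 4])) == 5


class TestClassify:
    def test_at_threshold_is_not_diminished(self):
        assert classify([0.5], 0.5).tolist() == [False]

    def test_strictly_below_is_diminished(self):
        assert classify([0.49], 0.5).tolist() == [True]

    def test_empty_input(self):
        assert classify([], 0.5).tolist() == []


class TestDiagnostics:
    def test_mir29c_style_counts(self):
        # 6 true positives of 10 hypermethylators, 5 of 6 negatives above cut
        m = diagnostics(ms.ConfusionMatrix(tp=6, fn=4, tn=5, fp=1))
        assert m.as_percent() == {
            "ca": 69, "sensitivity": 60, "specificity": 83, "ppv": 86, "npv": 56,
        }

    def test_mir148b_style_counts(self):
        m = diagnostics(ms.ConfusionMatrix(tp=10, fn=0, tn=5, fp=1))
        assert percent(m.ca) == 94

    def test_perfect_classifier(self):
        m = diagnostics(ms.ConfusionMatrix(tp=7, fn=0, tn=4, fp=0))
        assert m.as_percent() == {
            "ca": 100, "sensitivity": 100, "specificity": 100, "ppv": 100, "npv": 100,
        }

    def test_zero_denominator_is_none_not_zero(self):
        m = diagnostics(ms.ConfusionMatrix(tp=0, fn=0, tn=3, fp=1))
        assert m.sensitivity is None
        assert m.as_percent()["sensitivity"] is None

    def test_percent_rounds_half_up(self):
        assert percent(0.875) == 88
        assert percent(14 / 16) == 88
        assert percent(0.684) == 68


class TestFitThreshold:
    def test_perfectly_separable(self):
        model = fit_threshold([0.1, 0.2, 0.8, 0.9], [True, True, False, False])
        assert model.metrics.ca == 1.0
        assert 0.2 < model.threshold < 0.8

    def test_mir29c_reference_ca(self):
        # 6/10 positives low (0.1), 4 high (1.0); 5/6 negatives high, 1 low
        values = [0.1] * 6 + [1.0] * 4 + [0.1] + [1.0] * 5
        labels = [True] * 10 + [False] * 6
        model = fit_threshold(values, labels)
        assert model.metrics.ca == pytest.approx(11 / 16)
        assert percent(model.metrics.ca) == 69

    def test_single_class_rejected(self):
        with pytest.raises(ms.DegenerateDataError):
            fit_threshold([0.1, 0.2], [True, True])

    def test_stored_confusion_reproducible_from_threshold(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 1, 20)
        labels = rng.uniform(0, 1, 20) < 0.5
        labels[0], labels[1] = True, False
        model = fit_threshold(values, labels)
        assert confusion_at(values, labels, model.threshold) == model.confusion

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 64))
        values = np.round(rng.uniform(0, 1, n), 2)  # ties likely
        labels = rng.uniform(0, 1, n) < rng.uniform(0.2, 0.8)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        model = fit_threshold(values, labels)
        assert model.metrics.ca == pytest.approx(brute_force_best_ca(values, labels))

    @pytest.mark.parametrize("seed", range(25))
    def test_fitted_ca_never_below_prevalence(self, seed):
        rng = np.random.default_rng(1000 + seed)
        values = rng.uniform(0, 1, 16)
        labels = rng.permutation([True] * 10 + [False] * 6)
        model = fit_threshold(values, labels)
        assert model.metrics.ca >= max(np.mean(labels), 1 - np.mean(labels)) - 1e-12

    def test_metrics_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0.01, 1, 16)
        labels = rng.permutation([True] * 10 + [False] * 6)
        base = fit_threshold(values, labels)
        transformed = fit_threshold(np.log(values) * 3 + 5, labels)
        assert base.confusion == transformed.confusion

    def test_tie_break_prefers_higher_youden_then_lower_threshold(self):
        # values below give the same CA at several cuts; result must be
        # deterministic and equal on repeated fits
        values = [0.1, 0.2, 0.3, 0.4]
        labels = [True, False, True, False]
        a = fit_threshold(values, labels)
        b = fit_threshold(values, labels)
        assert a == b

    def test_well_separated_groups_yield_perfect_ca(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            values = np.concatenate(
                [rng.normal(0.1, 0.1, 10), rng.normal(1.0, 0.1, 6)]
            )
            labels = np.array([True] * 10 + [False] * 6)
            model = fit_threshold(values, labels)
            hits += model.metrics.ca == 1.0
        assert hits >= 95

    def test_objectives_agree_on_separable_data(self):
        values = [0.1, 0.15, 0.9, 0.95]
        labels = [True, True, False, False]
        for objective in ("max_ca", "max_youden", "prevalence_weighted"):
            model = fit_threshold(values, labels, objective=objective)
            assert model.metrics.ca == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_property_fit_equals_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        values = np.round(rng.normal(0, 1, n), 1)
        labels = rng.uniform(0, 1, n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        model = fit_threshold(values, labels)
        assert model.metrics.ca == pytest.approx(brute_force_best_ca(values, labels))
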