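"""Comparative-Ct quantification: replicate aggregation, RQ arithmetic, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mirscore as ms
from mirscore.qpcr import aggregate_replicates, relative_expression


def _table(rows):
    return ms.CtTable(
        pd.DataFrame(rows, columns=["sample_id", "assay_id", "assay_class", "replicate", "ct"])
    )


class TestAggregateReplicates:
    @pytest.mark.parametrize(
        "cts, expected",
        [((24.0, 24.1, 23.9), 24.0), ((28.1, 28.3, 28.2), 28.2)],
    )
    def test_mean_of_triplicates(self, cts, expected):
        table = _table([("S", "A", "mir_target", i + 1, ct) for i, ct in enumerate(cts)])
        agg = aggregate_replicates(table)
        assert agg.loc[0, "mean_ct"] == pytest.approx(expected)
        assert agg.loc[0, "n_replicates"] == 3
        assert not agg.loc[0, "censored"]

    def test_fully_censored_group_imputed_at_max_and_flagged(self):
        table = _table([("S", "A", "mir_target", i, None) for i in (1, 2, 3)])
        agg = aggregate_replicates(table, ms.QuantConfig(censored_policy="impute_max"))
        assert agg.loc[0, "mean_ct"] == 40.0
        assert bool(agg.loc[0, "censored"])

    def test_drop_policy_discards_censored_wells(self):
        table = _table(
            [("S", "A", "mir_target", 1, 20.0), ("S", "A", "mir_target", 2, None)]
        )
        agg = aggregate_replicates(table, ms.QuantConfig(censored_policy="drop"))
        assert agg.loc[0, "mean_ct"] == 20.0
        assert agg.loc[0, "n_replicates"] == 1

    def test_drop_policy_errors_on_empty_group_naming_it(self):
        table = _table([("S9", "miR-203", "mir_target", i, None) for i in (1, 2, 3)])
        with pytest.raises(ms.MissingDataError, match="S9.*miR-203"):
            aggregate_replicates(table, ms.QuantConfig(censored_policy="drop"))

    def test_error_policy_refuses_censored_input(self):
        table = _table([("S", "A", "mir_target", 1, None)])
        with pytest.raises(ms.MissingDataError):
            aggregate_replicates(table, ms.QuantConfig(censored_policy="error"))


class TestCtTableValidation:
    def test_duplicate_replicate_rejected(self):
        with pytest.raises(ms.InputValidationError, match="duplicate"):
            _table([("S", "A", "mir_target", 1, 20.0), ("S", "A", "mir_target", 1, 21.0)])

    def test_ct_outside_cycle_range_rejected(self):
        with pytest.raises(ms.InputValidationError):
            _table([("S", "A", "mir_target", 1, -1.0)])
        with pytest.raises(ms.InputValidationError):
            _table([("S", "A", "mir_target", 1, 41.0)])

    def test_unknown_assay_class_rejected(self):
        with pytest.raises(ms.InputValidationError, match="assay_class"):
            _table([("S", "A", "protein", 1, 20.0)])

    def test_from_records_parses_censored_tokens(self):
        table = ms.CtTable.from_records(
            [("S", "A", "mir_target", 1, "Undetermined"), ("S", "A", "mir_target", 2, "24.5")]
        )
        assert table.data["ct"].isna().sum() == 1
        assert table.data["ct"].iloc[1] == 24.5


class TestRelativeExpression:
    def test_calibrator_row_is_identity(self, simple_ct_table):
        expr = relative_expression(simple_ct_table)
        assert expr.delta_delta_ct.loc["MCF12A"].eq(0).all()
        assert expr.rq.loc["MCF12A"].eq(1.0).all()

    def test_known_ddct_gives_half_rq(self):
        # tumor dCt exceeds calibrator dCt by exactly 1 cycle -> RQ 0.5
        rows = []
        for sample, tct in [("MCF12A", 25.0), ("T", 26.0)]:
            rows += [
                (sample, "RNU66", "mir_normalizer", 1, 22.0),
                (sample, "miR-29c", "mir_target", 1, tct),
            ]
        expr = relative_expression(_table(rows))
        assert expr.rq.loc["T", "miR-29c"] == pytest.approx(0.5)

    def test_fractional_ddct(self, simple_ct_table):
        # sample dCt 7.2, calibrator dCt 3.0 -> ddCt 4.2... use the spec-style
        # hand value: dCt 4.2 vs 3.0 -> ddCt 1.2 -> RQ 2^-1.2
        rows = []
        for sample, tct in [("MCF12A", 25.0), ("T", 26.2)]:
            rows += [
                (sample, "RNU66", "mir_normalizer", 1, 22.0),
                (sample, "miR-29c", "mir_target", 1, tct),
            ]
        expr = relative_expression(_table(rows))
        assert expr.rq.loc["T", "miR-29c"] == pytest.approx(2.0 ** -1.2)
        assert expr.rq.loc["T", "miR-29c"] == pytest.approx(0.4353, abs=5e-5)

    def test_missing_calibrator_is_configuration_error(self, simple_ct_table):
        config = ms.QuantConfig(calibrator_sample="NOPE")
        with pytest.raises(ms.ConfigurationError, match="NOPE"):
            relative_expression(simple_ct_table, config)

    def test_missing_normalizer_is_configuration_error(self):
        table = _table([("MCF12A", "miR-29c", "mir_target", 1, 25.0)])
        with pytest.raises(ms.ConfigurationError, match="RNU66"):
            relative_expression(table)

    def test_censored_flag_propagates_to_matrix(self):
        rows = [
            ("MCF12A", "RNU66", "mir_normalizer", 1, 22.0),
            ("MCF12A", "miR-203", "mir_target", 1, 25.0),
            ("T", "RNU66", "mir_normalizer", 1, 22.0),
            ("T", "miR-203", "mir_target", 1, None),
        ]
        expr = relative_expression(_table(rows))
        assert bool(expr.censored.loc["T", "miR-203"])
        assert expr.rq.loc["T", "miR-203"] == pytest.approx(2.0 ** -(40.0 - 25.0))


class TestInvariants:
    @given(shift=st.floats(-3.0, 3.0), target_ct=st.floats(24.0, 34.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_constant_sample_shift_cancels(self, shift, target_ct):
        """Adding a constant to every Ct of a sample leaves its RQ unchanged."""
        def build(offset):
            rows = [
                ("MCF12A", "RNU66", "mir_normalizer", 1, 22.0),
                ("MCF12A", "miR-29c", "mir_target", 1, 25.0),
                ("T", "RNU66", "mir_normalizer", 1, 22.0 + offset),
                ("T", "miR-29c", "mir_target", 1, target_ct + offset),
            ]
            return relative_expression(_table(rows)).rq.loc["T", "miR-29c"]

        assert build(shift) == pytest.approx(build(0.0), rel=1e-12)

    @given(ct_lo=st.floats(24.0, 30.0), delta=st.floats(0.1, 6.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_rq_strictly_decreasing_in_target_ct(self, ct_lo, delta):
        def rq_at(ct):
            rows = [
                ("MCF12A", "RNU66", "mir_normalizer", 1, 22.0),
                ("MCF12A", "miR-29c", "mir_target", 1, 25.0),
                ("T", "RNU66", "mir_normalizer", 1, 22.0),
                ("T", "miR-29c", "mir_target", 1, ct),
            ]
            return relative_expression(_table(rows)).rq.loc["T", "miR-29c"]

        assert rq_at(ct_lo + delta) < rq_at(ct_lo)

    def test_round_trip_ddct_from_rq(self, reference_expression):
        expr = reference_expression
        recon = -np.log2(expr.rq)
        assert np.allclose(recon.to_numpy(), expr.delta_delta_ct.to_numpy(), atol=1e-12)

    def test_rq_positive_everywhere(self, reference_expression):
        assert (reference_expression.rq.to_numpy() > 0).all()
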