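import numpy as np
import pandas as pd
import pytest

import mirscore as ms


@pytest.fixture(scope="session")
def prose_cohort() -> ms.ReferenceCohort:
    return ms.reference_cohort("prose")


@pytest.fixture(scope="session")
def printed_cohort() -> ms.ReferenceCohort:
    return ms.reference_cohort("printed_mean")


@pytest.fixture(scope="session")
def reference_expression():
    """RQ matrix quantified from the noise-free reference Ct table."""
    table = ms.reference_ct_table("prose")
    return ms.relative_expression(table)


@pytest.fixture()
def simple_ct_table() -> ms.CtTable:
    """Two samples (calibrator + one), one miR target, triplicates."""
    rows = []
    for sample, target_ct, norm_ct in [("MCF12A", 25.0, 22.0), ("TUMOR", 29.2, 22.0)]:
        for rep in (1, 2, 3):
            rows.append((sample, "RNU66", "mir_normalizer", rep, norm_ct))
            rows.append((sample, "miR-29c", "mir_target", rep, target_ct))
    return ms.CtTable(
        pd.DataFrame(rows, columns=["sample_id", "assay_id", "assay_class", "replicate", "ct"])
    )


def brute_force_best_ca(values, labels):
    """Independent exhaustive oracle: best CA over every possible cut.

    Scans one cut strictly below each observed value, plus one above the
    maximum, computing accuracy directly; independent of the package's
    candidate-midpoint construction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cuts = np.concatenate([np.unique(values), [values.max() + 1.0]])
    best = 0.0
    for cut in cuts:
        calls = values < cut
        acc = np.mean(calls == labels)
        best = max(best, acc)
    return best
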