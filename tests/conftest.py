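import numpy as np
import pandas as pd
import pytest

import thyromet as tm


@pytest.fixture
def cohort():
    """Five controls + five cases with fixed creatinine."""
    return [
        tm.SampleInfo(f"C{i}", 0, 100.0) for i in range(5)
    ] + [tm.SampleInfo(f"H{i}", 1, 50.0) for i in range(5)]


@pytest.fixture
def study_cohort():
    """The default study-sized cohort: 19 controls, 16 cases."""
    return tm.generate_cohort(19, 16, seed=11)


def make_table(values, stage="raw", sample_ids=None, feature_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    feature_ids = feature_ids or [f"F{j}" for j in range(p)]
    return tm.FeatureTable(
        values=pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        stage=stage,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
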