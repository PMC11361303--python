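import numpy as np
import pandas as pd
import pytest

import commstate as cs


@pytest.fixture
def tiny_taxa_table() -> cs.FeatureTable:
    data = pd.DataFrame(
        [[5, 0, 12], [3, 7, 1], [2, 2, 4]],
        index=["Bacteroides", "Prevotella", "Blautia"],
        columns=["s1", "s2", "s3"],
    )
    return cs.FeatureTable(data=data, layer="taxa")


@pytest.fixture(scope="session")
def small_cohort() -> cs.Cohort:
    """20-subject default-parameter cohort reused by fast tests."""
    return cs.generate_cohort(cs.CohortConfig(n_subjects=20, seed=11))


@pytest.fixture(scope="session")
def default_cohort() -> cs.Cohort:
    """Full 93-subject, 3-timepoint cohort at default parameters."""
    return cs.generate_cohort(cs.CohortConfig(seed=7))


def truth_sample_labels(cohort: cs.Cohort) -> pd.Series:
    """sample_id -> true generating state (1-based)."""
    traj = cohort.truth.trajectories
    out = {}
    for i, (subject, row) in enumerate(traj.iterrows()):
        for t, state in row.items():
            out[f"S{i:03d}T{t}"] = int(state)
    return pd.Series(out)
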