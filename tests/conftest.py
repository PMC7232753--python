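import numpy as np
import pandas as pd
import pytest

from probene import ExperimentRecord

# master seed for every Monte-Carlo test in the suite (date stamp; fixed)
MC_SEED = 20260925


def make_records(strain_points, host_type="h", outcome_kind="continuous"):
    """Records from {strain: [(density, outcome), ...]} (raw-scale density)."""
    recs = []
    for strain, pts in strain_points.items():
        for d, h in pts:
            recs.append(
                ExperimentRecord(
                    host_type=host_type,
                    strain=strain,
                    density=float(d),
                    outcome=float(h),
                    outcome_kind=outcome_kind,
                )
            )
    return recs


@pytest.fixture
def exact_two_strain():
    """Zero-residual two-strain fixture: strain A lies exactly on the line
    health = 10 - density (b = -1), strain B on health = 10 (b = 0)."""
    return make_records(
        {
            "A": [(1, 9), (2, 8), (3, 7), (4, 6)],
            "B": [(1, 10), (2, 10), (3, 10), (4, 10)],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(MC_SEED)
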