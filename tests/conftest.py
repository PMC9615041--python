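import numpy as np
import pandas as pd
import pytest

from atacdyn import CountMatrix


@pytest.fixture
def two_day_samples() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["d0_r1", "d0_r2", "d3_r1", "d3_r2"],
            "day": [0.0, 0.0, 3.0, 3.0],
            "replicate": [1, 2, 1, 2],
        }
    )


@pytest.fixture
def full_course_times() -> np.ndarray:
    """Five sampling days, two replicates each (replicates repeat the day)."""
    return np.repeat([0.0, 3.0, 7.0, 10.0, 28.0], 2)


def make_count_matrix(counts: np.ndarray, samples: pd.DataFrame) -> CountMatrix:
    df = pd.DataFrame(
        counts,
        index=[f"peak_{i}" for i in range(len(counts))],
        columns=samples["sample_id"].tolist(),
    )
    return CountMatrix(df, samples)


@pytest.fixture
def make_cm():
    return make_count_matrix
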