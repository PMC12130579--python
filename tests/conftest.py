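import numpy as np
import pandas as pd
import pytest

from agingatlas import AnalysisConfig, FeatureMatrix, SimConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One default-condition synthetic study shared across tests."""
    return generate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(5)
    vals = pd.DataFrame(rng.normal(10, 1, (50, 8)),
                        index=[f"F{i:03d}" for i in range(50)],
                        columns=[f"s{j}" for j in range(8)])
    return FeatureMatrix(vals)


def two_group_meta(samples, tissue="liver"):
    """Metadata helper: first half young, second half aged."""
    from agingatlas import make_sample_meta
    half = len(samples) // 2
    rows = [dict(sample_id=s, tissue=tissue,
                 age_group="young" if i < half else "aged",
                 subject_id=f"m{i}", role="biological")
            for i, s in enumerate(samples)]
    return make_sample_meta(rows)
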