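import numpy as np
import pandas as pd
import pytest

from abundex import Experiment


@pytest.fixture
def pond_exp() -> Experiment:
    """6 samples x 4 features with origin/plate metadata (3 Pond, 3 Stream)."""
    data = np.array(
        [
            [5.0, 0, 2, 1],
            [3.0, 1, 0, 0],
            [0.0, 4, 1, 2],
            [1.0, 2, 3, 0],
            [2.0, 0, 0, 5],
            [0.0, 1, 4, 3],
        ]
    )
    smd = pd.DataFrame(
        {
            "origin": ["Pond", "Pond", "Pond", "Stream", "Stream", "Stream"],
            "plate": ["pa", "pb", "pa", "pb", "pa", "pb"],
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )
    fmd = pd.DataFrame(
        {"taxon": ["a", "b", "c", "d"]},
        index=pd.Index([f"f{i}" for i in range(4)], name="feature_id"),
    )
    return Experiment(data, smd, fmd)


@pytest.fixture
def random_exp() -> Experiment:
    """Seeded random sparse-ish count experiment, 20 samples x 30 features."""
    rng = np.random.default_rng(42)
    data = rng.poisson(2.0, size=(20, 30)) * (rng.random((20, 30)) > 0.5)
    data = data.astype(float)
    data[data.sum(axis=1) == 0, 0] = 1.0  # no all-zero samples
    smd = pd.DataFrame(
        {"group": ["g1"] * 10 + ["g2"] * 10, "depth": data.sum(axis=1)},
        index=pd.Index([f"s{i:02d}" for i in range(20)], name="sample_id"),
    )
    fmd = pd.DataFrame(
        index=pd.Index([f"feat{j:02d}" for j in range(30)], name="feature_id")
    )
    return Experiment(data, smd, fmd)


def assert_axis_sync(exp: Experiment):
    """Shared post-condition: metadata order matches the matrix on both axes."""
    assert len(exp.sample_metadata) == exp.shape[0]
    assert len(exp.feature_metadata) == exp.shape[1]
    exp.validate()
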