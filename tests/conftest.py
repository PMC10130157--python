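import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import culturebench as cb
from culturebench.io_tables import FeatureTable, SampleMetadata

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down culture design: 3 donors x 3 media x 2 times x 2 reps."""
    return cb.CommunitySimSpec(
        n_donors=3,
        n_media=3,
        time_points_h=(6, 24),
        n_replicates=2,
        n_taxa=60,
        n_families=10,
        depth=2000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_spec):
    return cb.simulate_experiment(small_spec)


@pytest.fixture()
def toy_table():
    return FeatureTable(
        pd.DataFrame(
            [[5.0, 0.0, 5.0], [0.0, 10.0, 0.0]],
            index=["S1", "S2"],
            columns=["T1", "T2", "T3"],
        )
    )


@pytest.fixture()
def toy_metadata():
    return SampleMetadata(
        pd.DataFrame(
            {
                "donor": ["D1", "D1"],
                "medium": ["M1", "M1"],
                "time_h": [6, 24],
                "replicate": ["r1", "r1"],
                "role": ["culture", "culture"],
            },
            index=["S1", "S2"],
        )
    )


def one_factor_metadata(labels):
    ids = [f"S{i}" for i in range(len(labels))]
    return SampleMetadata(
        pd.DataFrame(
            {
                "donor": labels,
                "medium": "m",
                "time_h": 0,
                "replicate": "r",
                "role": "culture",
            },
            index=ids,
        )
    )


def random_distance(n, seed, dim=5):
    from scipy.spatial.distance import pdist, squareform

    from culturebench.io_tables import DistanceMatrix

    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, dim))
    ids = [f"S{i}" for i in range(n)]
    return DistanceMatrix(ids, squareform(pdist(x)), metric="euclidean")
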