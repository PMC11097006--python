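import numpy as np
import pandas as pd
import pytest

import ginkgosdm as g


@pytest.fixture(scope="session")
def small_spec():
    return g.SyntheticClimateSpec(
        n_rows=40, n_cols=40, origin_lon=100.0, origin_lat=40.0,
        cell_size=0.05,
        variables=[("bio6", -1.7, 4.0), ("bio12", 1113.2, 369.4)],
        correlation=np.array([[1.0, 0.45], [0.45, 1.0]]),
        smoothness=1, seed=42,
    )


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return g.make_climate_stack(small_spec)


@pytest.fixture(scope="session")
def study_stack():
    """Default six-variable scenario at a reduced 80x80 desk scale."""
    return g.make_climate_stack(g.default_spec(n_rows=80, n_cols=80))


@pytest.fixture(scope="session")
def study_occ(study_stack):
    return g.sample_occurrences(study_stack, g.default_envelope(), n=400,
                                seed=11)


@pytest.fixture(scope="session")
def study_env(study_stack, study_occ):
    return g.extract_at_points(study_stack, study_occ)


@pytest.fixture()
def occ_frame():
    return pd.DataFrame({
        "id": ["a", "b", "c", "d"],
        "lon": [110.0, 110.5, 111.0, 112.0],
        "lat": [30.0, 30.5, 31.0, 32.0],
        "elevation": [100.0, 900.0, 1700.0, 2500.0],
    })


@pytest.fixture()
def occ_table(occ_frame):
    return g.OccurrenceTable(frame=occ_frame)
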