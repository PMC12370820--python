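import numpy as np
import pandas as pd
import pytest

from iceegnorm import (
    SimulationParams,
    simulate_cohort,
    simulate_parcellation,
)


@pytest.fixture(scope="session")
def default_cohort():
    """A ~500-subject, 15-hospital cohort at the default study conditions."""
    table, truth = simulate_cohort(SimulationParams(seed=11))
    return table, truth


@pytest.fixture(scope="session")
def small_parcellation():
    return simulate_parcellation(n_region_pairs=4, seed=5)


@pytest.fixture(scope="session")
def standard_parcellation():
    return simulate_parcellation(n_region_pairs=41, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_roi_vectors(subjects, rois, rng):
    """Unit-sum RBP vectors for every subject x ROI combination."""
    rows = []
    for s in subjects:
        for roi in rois:
            v = rng.dirichlet(np.ones(5) * 20)
            rows.append({"subject": s, "roi": roi,
                         "delta": v[0], "theta": v[1], "alpha": v[2],
                         "beta": v[3], "gamma": v[4]})
    return pd.DataFrame(rows)


def make_metadata(subjects, rng, n_hospitals=3):
    return pd.DataFrame({
        "subject": list(subjects),
        "hospital": [f"h{int(i)}" for i in
                     rng.integers(0, n_hospitals, len(subjects))],
        "age": rng.uniform(6, 60, len(subjects)),
        "sex": rng.choice(["female", "male"], len(subjects)),
    })
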