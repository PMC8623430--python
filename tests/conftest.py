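import numpy as np
import pytest

import epikin as ek


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic training cohort: 12 patients, 43 + 43 videos."""
    return ek.simulate_cohort(ek.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def feature_table(cohort):
    return ek.build_feature_table(cohort)


@pytest.fixture(scope="session")
def cohort_Xyg(feature_table):
    X = feature_table.loc[:, list(ek.FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = feature_table["label"].to_numpy(dtype=object)
    groups = feature_table["patient_id"].to_numpy()
    return X, y, groups


def tone(freq, fs=200.0, n=1000, amplitude=1.0, phase=0.0):
    t = np.arange(n) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture
def make_tone():
    return tone
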