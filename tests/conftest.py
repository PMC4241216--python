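import numpy as np
import pandas as pd
import pytest

import costvar as cv


def make_standardized(arr) -> cv.StandardizedMatrix:
    """Standardize a raw array (population s.d.) into the package type."""
    frame = pd.DataFrame(np.asarray(arr, dtype=float))
    frame.index = [f"o{i + 1}" for i in range(frame.shape[0])]
    frame.columns = [f"a{j + 1}" for j in range(frame.shape[1])]
    return cv.standardize(frame)


@pytest.fixture(scope="session")
def sarcoma():
    return cv.load_sarcoma_matrix()


@pytest.fixture(scope="session")
def sarcoma_X(sarcoma):
    return cv.standardize(sarcoma)


@pytest.fixture(scope="session")
def sarcoma_scan(sarcoma_X):
    return cv.scan_combinations(sarcoma_X)


@pytest.fixture(scope="session")
def sarcoma_pca(sarcoma_X):
    return cv.fit_pca(sarcoma_X)


@pytest.fixture
def toy_records():
    """Two French diagnosis patients with biopsy-factor sums 1 and 3."""
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2"],
            "country": ["France"] * 3,
            "phase": ["diagnosis"] * 3,
            "factor": ["surgical biopsy", "micro-biopsy", "surgical biopsy"],
            "quantity": [1.0, 0.0, 3.0],
            "year_offset": [0, 0, 0],
        }
    )
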