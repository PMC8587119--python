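import numpy as np
import pytest

import myoadapt as ma


@pytest.fixture(scope="session")
def default_spec():
    return ma.GeneratorSpec()


@pytest.fixture(scope="session")
def calib_features(default_spec):
    """One fused calibration session (expensive; shared read-only)."""
    records = ma.gen_calibration_session(default_spec, seed=424242)
    return ma.fuse_records(records)


@pytest.fixture(scope="session")
def reference(calib_features):
    """Reference selector fitted on the shared calibration session."""
    X = ma.feature_matrix(calib_features)
    y = calib_features["motion"].astype(str).to_numpy()
    return ma.ReferenceSelector(seed=7).fit(
        X, y, heldout={"pose": calib_features["pose"].to_numpy()}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
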