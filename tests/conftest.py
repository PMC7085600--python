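import pytest

from throwsense import (
    RecognizerConfig,
    SensorConfig,
    builtin_db,
    encode_pair,
    preprocess_trace,
    recognize_throw,
)

#: Published identification counts of the three-user evaluation (steps 0-6).
TABLE4_COUNTS = {
    "User 1": [(50, 50), (49, 50), (47, 50), (46, 50), (44, 50), (49, 50), (48, 50)],
    "User 2": [(49, 50), (49, 50), (45, 50), (42, 50), (41, 50), (47, 50), (47, 50)],
    "User 3": [(50, 50), (49, 50), (48, 50), (45, 50), (43, 50), (49, 50), (49, 50)],
}


@pytest.fixture(scope="session")
def db():
    return builtin_db()


@pytest.fixture(scope="session")
def sensor_cfg():
    return SensorConfig()


@pytest.fixture(scope="session")
def rec_cfg():
    return RecognizerConfig()


@pytest.fixture(scope="session")
def run_throw(db, sensor_cfg):
    """Full pipeline on a generated throw: traces -> ThrowResult."""

    def _run(forearm, upper, handedness="right", config=None):
        cfg = config or RecognizerConfig(mode="left" if handedness == "left" else "right")
        pair = encode_pair(
            preprocess_trace(forearm, sensor_cfg, cfg.mirror_axes),
            preprocess_trace(upper, sensor_cfg, cfg.mirror_axes),
        )
        return recognize_throw(pair, db, cfg)

    return _run
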