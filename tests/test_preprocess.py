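"""Kalman smoothing, normalization and ternary leveling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from throwsense import SensorConfig, Trace, kalman_smooth, levelize, normalize, preprocess_trace
from throwsense.encode import compress_runs, encode_levels
from throwsense.preprocess import FOREARM


def kalman_by_hand(series, q, r, x0, p0):
    """Independent straight-line transcription of the predict/update recursion."""
    x, p = x0, p0
    out = []
    for z in series:
        x_minus = x
        p_minus = p + q
        k = p_minus / (p_minus + r)
        x = x_minus + k * (z - x_minus)
        p = (1.0 - k) * p_minus
        out.append(x)
    return out


class TestKalman:
    def test_constant_series_is_fixed_point(self):
        out = kalman_smooth([3.0] * 20, q=0.01, r=0.1, x0=3.0)
        assert np.allclose(out, 3.0)

    def test_vanishing_measurement_noise_tracks_measurements(self):
        z = np.array([0.0, 1.0, -2.0, 5.0, 3.0])
        out = kalman_smooth(z, q=1.0, r=1e-12)
        assert np.allclose(out[1:], z[1:], atol=1e-6)

    def test_matches_hand_unrolled_recursion(self):
        z = [0.0, 1.0]
        got = kalman_smooth(z, q=1.0, r=1.0, x0=0.0, p0=1.0)
        want = kalman_by_hand(z, q=1.0, r=1.0, x0=0.0, p0=1.0)
        # two-step recursion by hand: first update leaves 0, second gives 5/8
        assert want == pytest.approx([0.0, 5.0 / 8.0])
        assert got == pytest.approx(want)

    @pytest.mark.parametrize("q,r,p0", [(0.0, 0.1, 1.0), (0.01, -1.0, 1.0), (0.01, 0.1, 0.0)])
    def test_rejects_nonpositive_variances(self, q, r, p0):
        with pytest.raises(ValueError):
            kalman_smooth([1.0, 2.0], q=q, r=r, p0=p0)

    def test_rejects_empty_series(self):
        with pytest.raises(ValueError):
            kalman_smooth([], q=0.01, r=0.1)

    def test_reduces_white_noise_variance(self):
        rng = np.random.default_rng(42)
        z = rng.normal(0.0, 1.0, 10_000)
        out = kalman_smooth(z, q=0.01, r=0.1)
        assert np.var(out) < np.var(z)


class TestNormalizeAndLevel:
    @pytest.mark.parametrize(
        "raw,expected", [(32768, 1.0), (0, 0.0), (-16384, -0.5), (-32768, -1.0)]
    )
    def test_fixed_full_scale_division(self, raw, expected):
        tr = Trace(t=[0.0], counts=[[raw, 0, 0]], channel=FOREARM)
        assert normalize(tr)[0, 0] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "value,level",
        [(0.5, 1), (0.35, 0), (0.351, 1), (-0.35, 0), (-0.36, -1), (0.0, 0), (1.0, 1)],
    )
    def test_leveling_thresholds_are_strict(self, value, level):
        assert levelize(value) == level

    @given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_levelize_is_odd_and_bounded(self, v):
        assert levelize(v) in (-1, 0, 1)
        assert levelize(-v) == -levelize(v)

    @given(
        st.floats(min_value=-1.0, max_value=1.0, allow_nan=False),
        st.floats(min_value=-1.0, max_value=1.0, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_levelize_is_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert levelize(lo) <= levelize(hi)

    def test_levelize_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            levelize(0.5, threshold=0.0)


class TestPreprocessTrace:
    def test_gravity_rest_trace_levels_to_z_up(self, sensor_cfg):
        n = 50
        counts = np.tile([0, 0, int(0.9 * 32768)], (n, 1))
        tr = Trace(t=np.arange(n) / 100.0, counts=counts, channel=FOREARM)
        out = preprocess_trace(tr, sensor_cfg)
        assert out.shape == (n, 3)
        assert (out == (0, 0, 1)).all()

    def test_all_zero_trace_levels_to_rest(self, sensor_cfg):
        tr = Trace(t=np.arange(10) / 100.0, counts=np.zeros((10, 3), int), channel=FOREARM)
        assert (preprocess_trace(tr, sensor_cfg) == 0).all()

    def test_is_causal(self, sensor_cfg):
        """The estimate at i must not change when later samples change."""
        rng = np.random.default_rng(0)
        counts = rng.integers(-20000, 20000, (40, 3))
        t = np.arange(40) / 100.0
        full = preprocess_trace(Trace(t, counts, FOREARM), sensor_cfg)
        head = preprocess_trace(Trace(t[:25], counts[:25], FOREARM), sensor_cfg)
        assert (full[:25] == head).all()

    def test_step1_profile_levels_to_p_then_e_runs(self, sensor_cfg):
        """The wind-up profile quantizes to the (1,-1,0) then (0,-1,0) classes."""
        from throwsense import ThrowProfile, generate_throw

        f, _u, gt = generate_throw(ThrowProfile(seed=5))
        lv = preprocess_trace(f, sensor_cfg)
        lo, hi = gt.step_bounds[1]
        seq = encode_levels(lv[lo + 3 : hi - 3], FOREARM)  # clip filter lag at the edges
        majors = [s for s, n in zip(*vars(compress_runs(seq)).values()) if n >= 3]
        assert majors == ["P", "E"]

    def test_rejects_nonmonotone_timestamps(self):
        with pytest.raises(ValueError):
            Trace(t=[0.0, 0.2, 0.1], counts=np.zeros((3, 3), int), channel=FOREARM)

    def test_rejects_out_of_range_counts(self):
        with pytest.raises(ValueError, match="out of range"):
            Trace(t=[0.0], counts=[[40000, 0, 0]], channel=FOREARM)


def test_sensor_config_validation():
    with pytest.raises(ValueError):
        SensorConfig(level_threshold=1.5)
    with pytest.raises(ValueError):
        SensorConfig(kalman_q=-1.0)
    with pytest.raises(ValueError):
        SensorConfig(sensitivity_forearm=0)
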