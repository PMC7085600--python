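"""Raw accelerometer preprocessing: Kalman smoothing, normalization, leveling.

The wearable measures two tri-axial accelerometer channels (forearm and
upper arm) as signed 16-bit counts.  Each axis is independently smoothed
with a scalar constant-state Kalman filter, scaled to the dimensionless
[-1, 1] range by the fixed full-scale count, and finally quantized into a
ternary level {-1, 0, +1} with a symmetric +/-0.35 dead band.  The leveled
triples are what the symbolic encoder consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Full-scale magnitude of the 16-bit ADC output used for normalization.
FULL_SCALE_COUNTS = 32768

FOREARM = "forearm"
UPPERARM = "upperarm"
CHANNELS = (FOREARM, UPPERARM)


@dataclass(frozen=True)
class SensorConfig:
    """Sensor scaling and preprocessing parameters.

    Parameters
    ----------
    sensitivity_forearm, sensitivity_upperarm
        Accelerometer sensitivity in counts per g for each placement
        (2048 and 4096 LSB/g by default).
    full_scale_g
        Nominal measurement range in g.
    level_threshold
        Half-width of the dead band used by :func:`levelize`; values with
        magnitude at or below the threshold quantize to 0.
    kalman_q, kalman_r
        Process- and measurement-noise variances of the per-axis scalar
        Kalman filter (constant-state model).
    """

    sensitivity_forearm: float = 2048.0
    sensitivity_upperarm: float = 4096.0
    full_scale_g: float = 16.0
    level_threshold: float = 0.35
    kalman_q: float = 0.01
    kalman_r: float = 0.1

    def __post_init__(self) -> None:
        if self.sensitivity_forearm <= 0 or self.sensitivity_upperarm <= 0:
            raise ValueError("sensitivities must be positive")
        if not 0.0 < self.level_threshold < 1.0:
            raise ValueError("level_threshold must lie in (0, 1)")
        if self.kalman_q <= 0 or self.kalman_r <= 0:
            raise ValueError("kalman_q and kalman_r must be positive")


@dataclass
class Trace:
    """One channel of timestamped raw accelerometer counts.

    ``t`` is a monotone non-decreasing time vector in seconds and
    ``counts`` an (n, 3) integer array of raw axis readings in
    [-32768, +32768].
    """

    t: np.ndarray
    counts: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.t.ndim != 1 or self.counts.shape != (self.t.size, 3):
            raise ValueError("trace requires t of shape (n,) and counts of shape (n, 3)")
        if self.t.size == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")
        if np.any(np.abs(self.counts) > FULL_SCALE_COUNTS):
            bad = int(np.argmax(np.any(np.abs(self.counts) > FULL_SCALE_COUNTS, axis=1)))
            raise ValueError(
                f"count out of range [-32768, +32768] at sample {bad}"
            )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def sample_rate(self) -> float:
        """Median sampling rate inferred from the timestamps."""
        if len(self) < 2:
            return float("nan")
        dt = float(np.median(np.diff(self.t)))
        return 1.0 / dt if dt > 0 else float("nan")


def kalman_smooth(
    series,
    q: float,
    r: float,
    x0: float | None = None,
    p0: float = 1.0,
) -> np.ndarray:
    """Scalar constant-state Kalman filter over an ordered series.

    The state model is a random walk: predict ``x- = x``, ``p- = p + q``;
    update ``k = p-/(p- + r)``, ``x = x- + k (z - x-)``, ``p = (1 - k) p-``.
    One estimate is returned per input measurement.  ``x0`` defaults to the
    first measurement so a constant series is a fixed point.
    """
    z = np.asarray(series, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    if q <= 0 or r <= 0 or p0 <= 0:
        raise ValueError("q, r and p0 must be positive")
    x = float(z[0]) if x0 is None else float(x0)
    p = float(p0)
    out = np.empty_like(z)
    for i in range(z.size):
        # predict (constant state: x unchanged)
        p += q
        # update
        k = p / (p + r)
        x += k * (z[i] - x)
        p *= 1.0 - k
        out[i] = x
    return out


def normalize(trace: Trace, config: SensorConfig | None = None) -> np.ndarray:
    """Map raw counts to the dimensionless [-1, 1] scale.

    Uses the fixed full-scale division (counts / 32768) so the +/-0.35
    leveling thresholds mean the same thing in every recording; the result
    is clipped to [-1, 1].
    """
    del config  # scale is fixed by the 16-bit range, kept for signature symmetry
    return np.clip(trace.counts / FULL_SCALE_COUNTS, -1.0, 1.0)


def levelize(value, threshold: float = 0.35):
    """Quantize normalized values into ternary levels {-1, 0, +1}.

    Values strictly greater than ``+threshold`` map to +1, strictly below
    ``-threshold`` to -1, and everything else (including the boundaries)
    to 0.  Works element-wise on arrays; a Python scalar input returns an int.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = np.asarray(value)
    levels = np.where(v > threshold, 1, np.where(v < -threshold, -1, 0))
    if np.isscalar(value) or getattr(value, "ndim", 1) == 0:
        return int(levels)
    return levels.astype(np.int8)


def preprocess_trace(
    trace: Trace,
    config: SensorConfig | None = None,
    mirror_axes: tuple[str, ...] = (),
) -> np.ndarray:
    """Full per-channel pipeline: Kalman smooth, normalize, level.

    Returns an (n, 3) int8 array of leveled triples, one per input sample.
    ``mirror_axes`` names axes ('x', 'y', 'z') whose sign is inverted before
    leveling; this is how left-handed recordings are folded onto the
    right-handed template frame.
    """
    cfg = config or SensorConfig()
    smoothed = np.column_stack(
        [kalman_smooth(trace.counts[:, i], cfg.kalman_q, cfg.kalman_r) for i in range(3)]
    )
    norm = np.clip(smoothed / FULL_SCALE_COUNTS, -1.0, 1.0)
    for ax in mirror_axes:
        idx = {"x": 0, "y": 1, "z": 2}[ax]
        norm[:, idx] = -norm[:, idx]
    return levelize(norm, cfg.level_threshold)


def counts_to_g(trace: Trace, config: SensorConfig | None = None) -> np.ndarray:
    """Convert raw counts to physical acceleration in g via the channel sensitivity."""
    cfg = config or SensorConfig()
    sens = cfg.sensitivity_forearm if trace.channel == FOREARM else cfg.sensitivity_upperarm
    return trace.counts / sens
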