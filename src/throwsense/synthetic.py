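"""Synthetic two-channel throw generator with ground-truth labels.

Every stage of the pipeline is testable without hardware: the generator
renders the six-step class choreography of the template database as
piecewise-constant normalized accelerations (plateaus at +/-0.6, inside
the leveling bands but away from the +/-0.35 thresholds) joined by short
linear ramps, adds Gaussian noise, and scales to raw 16-bit counts.  The
upper-arm class changes are aligned with forearm class boundaries — each
upper-arm class covers a contiguous block of forearm classes — which is
exactly the simultaneity the dual-channel matcher verifies.

The signal is a choreography model, not physics: plateau fidelity is all
the symbolic pipeline consumes, so no kinematic simulation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .encode import ThrowSequencePair, encode_pair
from .preprocess import FOREARM, FULL_SCALE_COUNTS, UPPERARM, SensorConfig, Trace, preprocess_trace
from .recognizer import ERROR, OK, RecognizerConfig

#: Canonical choreography: per step, (forearm triple, upper-arm triple) per
#: forearm class slot, in temporal order.  Symbols (forearm/upper):
#: step 1 P,E / p; step 2 Y,M,A / k,a; step 3 G,B,H / m,y,r;
#: step 4 D,L,F,M / r,y; step 5 A / a; step 6 K / k.
STEP_PLAN: dict[int, list[tuple[tuple[int, int, int], tuple[int, int, int]]]] = {
    1: [((1, -1, 0), (1, -1, 0)), ((0, -1, 0), (1, -1, 0))],
    2: [((-1, -1, 1), (1, 0, 1)), ((-1, 0, 1), (1, 0, 1)), ((0, 0, 1), (0, 0, 1))],
    3: [((0, 1, 1), (-1, 0, 1)), ((0, 1, 0), (-1, -1, 1)), ((0, 1, -1), (-1, -1, 0))],
    4: [((0, 0, -1), (-1, -1, 0)), ((1, 0, -1), (-1, -1, 0)),
        ((-1, 0, 0), (-1, -1, 1)), ((-1, 0, 1), (-1, -1, 1))],
    5: [((0, 0, 1), (0, 0, 1))],
    6: [((1, 0, 1), (1, 0, 1))],
}

#: Standing posture (Step 0): arm hanging, gravity on -y, both channels.
STANDING: tuple[tuple[int, int, int], tuple[int, int, int]] = ((0, -1, 0), (0, -1, 0))

REST = (0, 0, 0)


@dataclass(frozen=True)
class ThrowProfile:
    """Study conditions for one synthetic throw.

    ``step_durations`` — seconds per throwing step (speed model: a slow
    throw stretches every run).  ``amplitude`` — plateau magnitude on the
    normalized scale (0.6 sits comfortably outside the 0.35 band).
    ``noise_sigma`` — Gaussian noise std on the normalized scale.
    ``ramp_frac`` — fraction of each class slot spent ramping between
    plateaus.  ``lead_in_s``/``lead_out_s`` — standing rest around the
    throw so the readiness gate has something to hold on to.
    """

    step_durations: tuple[float, ...] = (0.4, 0.4, 0.4, 0.4, 0.4, 0.4)
    amplitude: float = 0.6
    noise_sigma: float = 0.0
    sample_rate: float = 100.0
    handedness: str = "right"
    seed: int = 0
    ramp_frac: float = 0.1
    lead_in_s: float = 1.0
    lead_out_s: float = 0.8

    def __post_init__(self) -> None:
        if len(self.step_durations) != 6 or any(d <= 0 for d in self.step_durations):
            raise ValueError("six positive step durations required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")
        if not 0.0 < self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in (0, 1]")
        if not 0.0 <= self.ramp_frac < 0.5:
            raise ValueError("ramp_frac must lie in [0, 0.5)")


@dataclass
class ThrowGroundTruth:
    """What the generator intended, for oracle-style checks.

    Levels are in the canonical right-handed frame (a left-handed raw trace
    mirrors x; the pipeline's left mode folds it back).
    """

    levels_forearm: np.ndarray
    levels_upper: np.ndarray
    step_bounds: dict[int, tuple[int, int]]  # 0..6 -> sample span
    intended: dict[int, tuple[str, str]]  # step -> (status, message), step 0 included
    onset: int
    end: int
    error_id: str | None
    profile: ThrowProfile

    @property
    def pair(self) -> ThrowSequencePair:
        return encode_pair(self.levels_forearm, self.levels_upper)

    @property
    def all_ok(self) -> bool:
        return all(s == OK for s, _ in self.intended.values())


# Registered erroneous-action generators: error id -> (step, mutation tag).
# "rest" silences both channels for the step; "rest_forearm" silences only
# the forearm (the upper arm proceeds); "invert" flips every plateau sign
# (a wrong, non-rest posture); "worn" rotates the standing posture.
ERROR_GENERATORS: dict[str, tuple[int, str]] = {
    "Error-1": (1, "rest"),
    "Error-2": (2, "rest"),
    "Error-3": (3, "rest"),
    "Error-4": (4, "rest"),
    "Error-5": (5, "rest"),
    "Error-6": (6, "invert"),
    "Elbow is not high enough": (4, "rest_forearm"),
    "No follow-through": (6, "rest"),
    "Worn too inside or outside": (0, "worn"),
}

#: Standing triple used by the "worn" error: device rotated so gravity
#: lands on the x axis instead of -y.
WORN_STANDING = ((1, 0, 0), (1, 0, 0))


def _segments(profile: ThrowProfile, plan: dict[int, list], standing) -> tuple[list, dict]:
    """Flat list of (n_samples, f_triple, u_triple, step) slots plus step bounds."""
    rate = profile.sample_rate
    slots: list[tuple[int, tuple, tuple, int]] = []
    slots.append((max(1, int(round(profile.lead_in_s * rate))), standing[0], standing[1], 0))
    for step in range(1, 7):
        step_slots = plan[step]
        per = profile.step_durations[step - 1] / len(step_slots)
        n = max(1, int(round(per * rate)))
        for f_t, u_t in step_slots:
            slots.append((n, f_t, u_t, step))
    slots.append((max(1, int(round(profile.lead_out_s * rate))), standing[0], standing[1], 0))
    bounds: dict[int, tuple[int, int]] = {}
    pos = 0
    for n, _f, _u, step in slots:
        lo, hi = bounds.get(step, (pos, pos))
        bounds[step] = (min(lo, pos), pos + n)
        pos += n
    bounds[0] = (0, slots[0][0])  # step 0 = the lead-in only
    return slots, bounds


def _render(slots, amplitude: float, ramp_frac: float, channel_idx: int) -> np.ndarray:
    """Piecewise-constant target with linear ramps at slot boundaries."""
    total = sum(s[0] for s in slots)
    out = np.empty((total, 3), dtype=float)
    pos = 0
    starts = []
    for n, f_t, u_t, _step in slots:
        t = f_t if channel_idx == 0 else u_t
        out[pos : pos + n] = np.asarray(t, dtype=float) * amplitude
        starts.append(pos)
        pos += n
    if ramp_frac > 0:
        for b in range(1, len(slots)):
            i = starts[b]
            prev_n = slots[b - 1][0]
            next_n = slots[b][0]
            r = int(round(ramp_frac * min(prev_n, next_n)))
            if r < 2:
                continue
            lo = max(0, i - r // 2)
            hi = min(total, i + (r - r // 2))
            a = out[lo - 1] if lo > 0 else out[lo]
            c = out[hi] if hi < total else out[hi - 1]
            w = np.linspace(0.0, 1.0, hi - lo + 2)[1:-1, None]
            out[lo:hi] = a * (1 - w) + c * w
    return out


def _mutate_plan(error_id: str | None):
    plan = {k: list(v) for k, v in STEP_PLAN.items()}
    standing = STANDING
    intended: dict[int, tuple[str, str]] = {0: (OK, "ready")}
    for k in range(1, 7):
        intended[k] = (OK, "OK!!")
    if error_id is None:
        return plan, standing, intended
    if error_id not in ERROR_GENERATORS:
        raise ValueError(f"unregistered error id {error_id!r}")
    step, tag = ERROR_GENERATORS[error_id]
    if tag == "worn":
        standing = WORN_STANDING
        intended[0] = (ERROR, error_id)
        return plan, standing, intended
    if tag == "rest":
        plan[step] = [(REST, REST)]
    elif tag == "rest_forearm":
        plan[step] = [(REST, u) for _f, u in plan[step]]
    elif tag == "invert":
        plan[step] = [
            (tuple(-v for v in f), tuple(-v for v in u)) for f, u in plan[step]
        ]
    intended[step] = (ERROR, error_id)
    return plan, standing, intended


def _to_counts(target: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    noisy = target if sigma == 0 else target + rng.normal(0.0, sigma, target.shape)
    noisy = np.clip(noisy, -1.0, 1.0)
    return np.rint(noisy * FULL_SCALE_COUNTS).astype(np.int32)


def generate_throw(
    profile: ThrowProfile,
    error_id: str | None = None,
) -> tuple[Trace, Trace, ThrowGroundTruth]:
    """Generate one throw (raw forearm and upper-arm traces + ground truth).

    Reproducible from ``profile.seed``; at ``noise_sigma=0`` the pipeline's
    leveled output matches the ground-truth levels up to the filter's short
    boundary lag.
    """
    plan, standing, intended = _mutate_plan(error_id)
    slots, bounds = _segments(profile, plan, standing)
    rng = np.random.default_rng(profile.seed)
    thr = 0.35  # leveling band, for the ground-truth quantization only

    traces = []
    gt_levels = []
    for idx, channel in enumerate((FOREARM, UPPERARM)):
        target = _render(slots, profile.amplitude, profile.ramp_frac, idx)
        gt = np.where(target > thr, 1, np.where(target < -thr, -1, 0)).astype(np.int8)
        gt_levels.append(gt)
        if profile.handedness == "left":
            target = target.copy()
            target[:, 0] = -target[:, 0]
        counts = _to_counts(target, profile.noise_sigma, rng)
        t = np.arange(target.shape[0]) / profile.sample_rate
        traces.append(Trace(t=t, counts=counts, channel=channel))

    onset = bounds[1][0]
    end = bounds[6][1]
    truth = ThrowGroundTruth(
        levels_forearm=gt_levels[0],
        levels_upper=gt_levels[1],
        step_bounds=bounds,
        intended=intended,
        onset=onset,
        end=end,
        error_id=error_id,
        profile=profile,
    )
    return traces[0], traces[1], truth


def generate_error_throw(
    profile: ThrowProfile, error_id: str
) -> tuple[Trace, Trace, ThrowGroundTruth]:
    """A throw whose ``error_id`` step is replaced by its registered deviant."""
    if error_id not in ERROR_GENERATORS:
        raise ValueError(f"unregistered error id {error_id!r}")
    return generate_throw(profile, error_id=error_id)


@dataclass
class SessionGroundTruth:
    """Ground truth for a multi-throw session."""

    throws: list[ThrowGroundTruth]
    offsets: list[int]

    @property
    def n_throws(self) -> int:
        return len(self.throws)


def generate_session(
    n_throws: int,
    profile: ThrowProfile | None = None,
    profiles: list[ThrowProfile] | None = None,
    error_ids: list[str | None] | None = None,
) -> tuple[Trace, Trace, SessionGroundTruth]:
    """Concatenate throws (each with its standing lead-in/out) into a session.

    Per-throw profiles may be given explicitly; otherwise the base profile
    is reused with per-throw seeds derived from it.
    """
    if n_throws < 1:
        raise ValueError("n_throws must be >= 1")
    if profiles is None:
        base = profile or ThrowProfile()
        profiles = [replace(base, seed=base.seed + 1000 * i) for i in range(n_throws)]
    if len(profiles) != n_throws:
        raise ValueError("one profile per throw required")
    errs = error_ids or [None] * n_throws
    f_parts, u_parts, truths, offsets = [], [], [], []
    pos = 0
    t_off = 0.0
    f_all_t, u_all_t = [], []
    for p, e in zip(profiles, errs):
        f, u, gt = generate_throw(p, error_id=e)
        offsets.append(pos)
        truths.append(gt)
        f_parts.append(f.counts)
        u_parts.append(u.counts)
        f_all_t.append(f.t + t_off)
        u_all_t.append(u.t + t_off)
        pos += len(f)
        t_off += len(f) / p.sample_rate
    f_trace = Trace(np.concatenate(f_all_t), np.concatenate(f_parts), FOREARM)
    u_trace = Trace(np.concatenate(u_all_t), np.concatenate(u_parts), UPPERARM)
    return f_trace, u_trace, SessionGroundTruth(throws=truths, offsets=offsets)


def symbol_error_rate(
    forearm_trace: Trace,
    upper_trace: Trace,
    truth: ThrowGroundTruth,
    sensor_config: SensorConfig | None = None,
    config: RecognizerConfig | None = None,
    guard_s: float = 0.1,
) -> float:
    """Fraction of plateau-interior samples whose symbol differs from intent.

    Samples within ``guard_s`` of an intended level change are excluded:
    the Kalman filter delays threshold crossings by a couple of samples, so
    boundary lag is not a quantization error.
    """
    cfg = config or RecognizerConfig()
    mirror = ("x",) if truth.profile.handedness == "left" else ()
    f_lv = preprocess_trace(forearm_trace, sensor_config, mirror)
    u_lv = preprocess_trace(upper_trace, sensor_config, mirror)
    guard = int(round(guard_s * truth.profile.sample_rate))
    n = f_lv.shape[0]
    keep = np.ones(n, dtype=bool)
    for gt in (truth.levels_forearm, truth.levels_upper):
        change = np.flatnonzero(np.any(np.diff(gt, axis=0) != 0, axis=1)) + 1
        for c in change:
            keep[max(0, c - guard) : min(n, c + guard)] = False
    if not keep.any():
        return 0.0
    err = (
        np.any(f_lv[keep] != truth.levels_forearm[keep], axis=1)
        | np.any(u_lv[keep] != truth.levels_upper[keep], axis=1)
    )
    return float(np.mean(err))
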