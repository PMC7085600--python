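"""Throw recognition: readiness gating, phase matching, error diagnosis, scoring.

A throw is recognized by scanning its two-channel symbol stream left to
right against the thirteen ordered sub-templates of the database.  Each
numbered step (1-6) passes only when all of its sub-templates match — on
both channels simultaneously — at the LCS similarity threshold; transition
templates (Steps 1-2, 2-3, 3-4) are scored as continuity checks but do not
affect the verdict.  A failed step receives a message from the erroneous
action catalogue: a registered deviant pattern when one matches, the
step's generic message otherwise.  A throw that simply stops (only rest
and standing symbols remain) is marked incomplete from the failed step on
rather than misclassified — except at Step 6, where stopping *is* the
registered "No follow-through" error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .encode import (
    FOREARM,
    UPPERARM,
    ThrowSequencePair,
    encode_pair,
    triple_to_symbol,
)
from .lcs import class_similarity
from .preprocess import SensorConfig, Trace, preprocess_trace
from .templates import TemplateDB, builtin_db

OK = "ok"
ERROR = "error"
INCOMPLETE = "incomplete"

#: Wording used on the glove-end display for specific errors (the report
#: channel keeps the catalogue wording).
DISPLAY_DIALECT = {"Elbow is not high enough": "Elbow is not enough high!!"}


@dataclass(frozen=True)
class RecognizerConfig:
    """Tunable recognition parameters.

    ``theta`` is the per-channel LCS similarity threshold; ``min_run`` the
    shortest symbol run treated as signal (shorter runs are noise
    glitches); ``min_hold`` the number of consecutive standing samples the
    readiness gate requires.  In a continuous stream a throw window closes
    once rest/standing persists for ``rest_hold_s`` — long enough to bridge
    a silent (erroneous) phase inside a throw, short enough to split
    consecutive throws at their idle gaps — or at the ``throw_timeout_s``
    safety cap.  ``mode`` selects right- or left-handed operation (left
    mirrors the x axis before leveling).
    """

    theta: float = 0.7
    min_run: int = 3
    min_hold: int = 30
    onset_hold: int = 3
    rest_hold_s: float = 1.0
    throw_timeout_s: float = 12.0
    mode: str = "right"
    standing_forearm: tuple[int, int, int] = (0, -1, 0)
    standing_upperarm: tuple[int, int, int] = (0, -1, 0)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must lie in (0, 1]")
        if self.mode not in ("right", "left"):
            raise ValueError("mode must be 'right' or 'left'")

    @property
    def mirror_axes(self) -> tuple[str, ...]:
        return ("x",) if self.mode == "left" else ()

    @property
    def standing_symbols(self) -> tuple[str, str]:
        return (
            triple_to_symbol(self.standing_forearm, FOREARM),
            triple_to_symbol(self.standing_upperarm, UPPERARM),
        )


@dataclass(frozen=True)
class ReadyStatus:
    """Outcome of the getting-ready (Step 0) balance judgment."""

    ok: bool
    reason: str  # "ready" | "Worn too inside or outside" | "unstable"


@dataclass(frozen=True)
class StepVerdict:
    step: int
    status: str  # OK | ERROR | INCOMPLETE
    message: str

    @property
    def ok(self) -> bool:
        return self.status == OK


@dataclass
class ThrowResult:
    """Per-step verdicts for one throw, plus matched windows for inspection."""

    steps: dict[int, StepVerdict]
    windows: dict[str, tuple[int, int]] = field(default_factory=dict)
    transitions: dict[str, bool] = field(default_factory=dict)

    @property
    def all_ok(self) -> bool:
        return all(v.ok for v in self.steps.values())

    def display_lines(self) -> list[str]:
        lines = []
        for k in sorted(self.steps):
            v = self.steps[k]
            if v.ok:
                lines.append(f"S{k}: OK!!")
            elif v.status == INCOMPLETE:
                lines.append(f"S{k}: --")
            else:
                lines.append(f"S{k}: {DISPLAY_DIALECT.get(v.message, v.message)}")
        return lines

    def report_lines(self) -> list[str]:
        lines = []
        for k in sorted(self.steps):
            v = self.steps[k]
            text = "OK!!" if v.ok else ("Incomplete" if v.status == INCOMPLETE else v.message)
            lines.append(f"STEP{k}: {text}")
        return lines

    def to_dict(self) -> dict:
        return {
            "all_ok": self.all_ok,
            "steps": {
                str(k): {"status": v.status, "message": v.message}
                for k, v in sorted(self.steps.items())
            },
        }


# ---------------------------------------------------------------------------
# run helpers


@dataclass(frozen=True)
class _Run:
    sym: str
    start: int
    end: int  # exclusive


def _runs(seq: str, min_len: int = 1) -> list[_Run]:
    out: list[_Run] = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            out.append(_Run(seq[i], i, j))
        i = j
    return out


def _find_ordered(runs: list[_Run], classes: Sequence[str], start: int) -> list[int] | None:
    """Indices of runs realizing the class sequence in order, greedily."""
    idx = start
    found: list[int] = []
    for c in classes:
        j = next((k for k in range(idx, len(runs)) if runs[k].sym == c), None)
        if j is None:
            return None
        found.append(j)
        idx = j
    return found


# ---------------------------------------------------------------------------
# Step 0: action balance judgment


def _stable_run(levels: np.ndarray, min_hold: int) -> tuple[int, int, int] | None:
    """Triple of the last constant run of length >= min_hold, else None."""
    lv = np.asarray(levels)
    n = lv.shape[0]
    best = None
    i = 0
    while i < n:
        j = i + 1
        while j < n and np.array_equal(lv[j], lv[i]):
            j += 1
        if j - i >= min_hold:
            best = tuple(int(v) for v in lv[i])
        i = j
    return best


def check_ready(
    forearm_levels: np.ndarray,
    upper_levels: np.ndarray,
    min_hold: int = 30,
    config: RecognizerConfig | None = None,
) -> ReadyStatus:
    """Getting-ready (Step 0) judgment over a window of leveled triples.

    Ready requires both channels to hold their expected standing-posture
    triple for ``min_hold`` consecutive samples.  A stable but wrong triple
    means the device is worn incorrectly; no stable run at all is reported
    as unstable.
    """
    cfg = config or RecognizerConfig()
    f = np.asarray(forearm_levels)
    u = np.asarray(upper_levels)
    if f.shape[0] < min_hold or u.shape[0] < min_hold:
        raise ValueError(f"window must cover at least min_hold={min_hold} samples")
    fr = _stable_run(f, min_hold)
    ur = _stable_run(u, min_hold)
    if fr is None or ur is None:
        return ReadyStatus(False, "unstable")
    if fr != cfg.standing_forearm or ur != cfg.standing_upperarm:
        return ReadyStatus(False, "Worn too inside or outside")
    return ReadyStatus(True, "ready")


# ---------------------------------------------------------------------------
# throw recognition


def _strip_overlap(classes: Sequence[str], own: set[str]) -> list[str]:
    kept = [c for c in classes if c in own]
    return kept or list(classes)


def recognize_throw(
    pair: ThrowSequencePair,
    db: TemplateDB | None = None,
    config: RecognizerConfig | None = None,
) -> ThrowResult:
    """Recognize one delimited throw (Step 0 assumed already passed).

    Scans the pair left to right over the thirteen ordered sub-templates.
    The forearm channel drives window search (its class runs are located in
    order); the window is then verified with the dual-channel LCS match.
    Numbered-step templates overlap the previous step's final class, so
    when the previous step failed the overlap classes are dropped (using
    phase-template membership) before searching — a broken arm-acceleration
    phase must not take the deceleration phase down with it.
    """
    if len(pair) == 0:
        raise ValueError("empty sequence pair")
    database = db or builtin_db()
    cfg = config or RecognizerConfig()

    f_runs = _runs(pair.forearm, cfg.min_run)
    cursor = 0
    windows: dict[str, tuple[int, int]] = {}
    transitions: dict[str, bool] = {}
    step_failed: dict[int, bool] = {}
    fail_pos: dict[int, int] = {}

    def attempt(fcl: Sequence[str], ucl: Sequence[str]):
        found = _find_ordered(f_runs, fcl, cursor)
        if found is None:
            return None
        s, e = f_runs[found[0]].start, f_runs[found[-1]].end
        seg = pair.segment(s, e)
        if class_similarity(seg.forearm, fcl).ratio < cfg.theta:
            return None
        if class_similarity(seg.upper, ucl).ratio < cfg.theta:
            return None
        return found[-1], s, e

    for tmpl in database.sub_templates:
        step = tmpl.step
        if step is not None and step_failed.get(step):
            continue
        fcl = list(tmpl.temporal_forearm)
        ucl = list(tmpl.temporal_upper)
        if step is not None and step_failed.get(step - 1):
            fcl = _strip_overlap(fcl, set(database.phase_templates[step].forearm_classes))
            ucl = _strip_overlap(ucl, set(database.phase_templates[step].upper_classes))
        hit = attempt(fcl, ucl)
        if tmpl.is_transition:
            transitions[tmpl.id] = hit is not None
            if hit is not None:
                cursor = hit[0]
            continue
        if hit is None:
            step_failed[step] = True
            # suffix starts where scanning stood when the step went missing
            fail_pos[step] = f_runs[cursor].end if cursor < len(f_runs) else len(pair)
            if not windows and cursor == 0:
                fail_pos[step] = 0
        else:
            cursor = hit[0]
            step_failed.setdefault(step, False)
            s, e = hit[1], hit[2]
            lo, hi = windows.get(f"Step {step}", (s, e))
            windows[f"Step {step}"] = (min(lo, s), max(hi, e))

    verdicts: dict[int, StepVerdict | None] = {}
    for k in range(1, 7):
        if step_failed.get(k):
            verdicts[k] = None  # diagnosed below
        else:
            verdicts[k] = StepVerdict(k, OK, "OK!!")

    _diagnose_failures(pair, database, cfg, step_failed, fail_pos, verdicts)
    return ThrowResult(steps=verdicts, windows=windows, transitions=transitions)


def _restish_sets(cfg: RecognizerConfig) -> tuple[set[str], set[str]]:
    sf, su = cfg.standing_symbols
    return {"1", sf}, {"2", su}


def _diagnose_failures(
    pair: ThrowSequencePair,
    db: TemplateDB,
    cfg: RecognizerConfig,
    step_failed: dict[int, bool],
    fail_pos: dict[int, int],
    verdicts: dict[int, StepVerdict | None],
) -> None:
    rest_f, rest_u = _restish_sets(cfg)
    incomplete_from: int | None = None
    for k in range(1, 7):
        if not step_failed.get(k):
            continue
        if incomplete_from is not None:
            verdicts[k] = StepVerdict(k, INCOMPLETE, "Incomplete")
            continue
        pos = fail_pos.get(k, 0)
        suf_f = _runs(pair.forearm[pos:], cfg.min_run)
        suf_u = _runs(pair.upper[pos:], cfg.min_run)
        all_rest = all(r.sym in rest_f for r in suf_f) and all(r.sym in rest_u for r in suf_u)
        message = None
        for dev in db.deviants:
            if dev.step != k:
                continue
            if dev.all_rest:
                if all_rest:
                    message = dev.message
                    break
                continue
            absent_ok = all(
                all(r.sym != c for r in suf_f) for c in dev.forearm_absent
            )
            present_ok = all(
                any(r.sym == c for r in suf_u) for c in dev.upper_present
            )
            if absent_ok and present_ok and (dev.forearm_absent or dev.upper_present):
                message = dev.message
                break
        if message is not None:
            verdicts[k] = StepVerdict(k, ERROR, message)
        elif all_rest and k < 6:
            incomplete_from = k
            verdicts[k] = StepVerdict(k, INCOMPLETE, "Incomplete")
        else:
            verdicts[k] = StepVerdict(k, ERROR, db.generic_error(k))


# ---------------------------------------------------------------------------
# continuous stream processing


@dataclass
class SessionReport:
    """Recognition outcome of a continuous two-channel recording."""

    throws: list[ThrowResult]
    ready_checks: list[ReadyStatus]
    throw_spans: list[tuple[int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "meta": dict(self.meta),
            "ready_checks": [
                {"ok": r.ok, "reason": r.reason} for r in self.ready_checks
            ],
            "throws": [t.to_dict() for t in self.throws],
            "throw_spans": [list(s) for s in self.throw_spans],
        }


def _first_hold(mask: np.ndarray, hold: int, start: int) -> int | None:
    """First index i >= start with mask[i : i + hold] all True."""
    n = mask.size
    run = 0
    for i in range(start, n):
        run = run + 1 if mask[i] else 0
        if run >= hold:
            return i - hold + 1
    return None


def process_stream(
    forearm_trace: Trace,
    upper_trace: Trace,
    db: TemplateDB | None = None,
    sensor_config: SensorConfig | None = None,
    config: RecognizerConfig | None = None,
) -> SessionReport:
    """Recognize every throw in a continuous recording.

    Repeatedly: wait for the readiness gate (both channels standing for
    ``min_hold`` samples), detect motion onset (the forearm leaves the
    standing class for ``onset_hold`` consecutive samples), delimit one
    throw window (closed by a rest hold, the timeout, or the stream end),
    recognize it, and resume.  No throw is emitted for a stream whose
    readiness gate never passes; a throw cut short is recorded with
    incomplete verdicts rather than misclassified.
    """
    database = db or builtin_db()
    scfg = sensor_config or SensorConfig()
    cfg = config or RecognizerConfig()

    f_lv = preprocess_trace(forearm_trace, scfg, cfg.mirror_axes)
    u_lv = preprocess_trace(upper_trace, scfg, cfg.mirror_axes)
    pair = encode_pair(f_lv, u_lv)
    n = len(pair)

    sf, su = cfg.standing_symbols
    fs = np.frombuffer(pair.forearm.encode(), dtype=np.uint8)
    us = np.frombuffer(pair.upper.encode(), dtype=np.uint8)
    standing = (fs == ord(sf)) & (us == ord(su))
    moving = fs != ord(sf)
    resting = (fs == ord(sf)) | (fs == ord("1"))

    rate = forearm_trace.sample_rate
    if not np.isfinite(rate) or rate <= 0:
        rate = 100.0
    rest_hold = max(1, int(round(cfg.rest_hold_s * rate)))
    timeout = max(rest_hold, int(round(cfg.throw_timeout_s * rate)))

    throws: list[ThrowResult] = []
    spans: list[tuple[int, int]] = []
    ready_log: list[ReadyStatus] = []

    i = 0
    while i < n:
        ready_at = _first_hold(standing, cfg.min_hold, i)
        if ready_at is None:
            # gate never passes; diagnose why on the remaining window
            if n - i >= cfg.min_hold:
                ready_log.append(check_ready(f_lv[i:], u_lv[i:], cfg.min_hold, cfg))
            break
        ready_log.append(ReadyStatus(True, "ready"))
        onset = _first_hold(moving, cfg.onset_hold, ready_at + cfg.min_hold)
        if onset is None:
            break
        end = _first_hold(resting, rest_hold, onset + 1)
        end = n if end is None else end
        end = min(end, onset + timeout, n)
        throws.append(recognize_throw(pair.segment(onset, end), database, cfg))
        spans.append((onset, end))
        i = end
    return SessionReport(
        throws=throws,
        ready_checks=ready_log,
        throw_spans=spans,
        meta={"n_samples": n, "sample_rate": rate, "mode": cfg.mode, "theta": cfg.theta},
    )


# ---------------------------------------------------------------------------
# identification-rate aggregation


def _trunc2(x: Fraction) -> float:
    """Truncate an exact fraction toward zero at two decimals."""
    return int(x * 100) / 100.0


@dataclass
class AccuracyReport:
    """Per-step identification rates and their averages, in percent.

    All percentages are reported to two decimals, truncated toward zero
    (640/7 -> 91.42).
    """

    users: list[str]
    steps: list[int]
    counts: dict[str, list[tuple[int, int]]]
    per_step_pct: dict[str, list[float]]
    user_average: dict[str, float]
    step_average: list[float]
    overall: float

    def to_dict(self) -> dict:
        return {
            "users": self.users,
            "steps": self.steps,
            "counts": {u: [list(c) for c in self.counts[u]] for u in self.users},
            "per_step_pct": self.per_step_pct,
            "user_average": self.user_average,
            "step_average": self.step_average,
            "overall": self.overall,
        }

    def to_text(self) -> str:
        head = ["Stage"] + [f"{u} k/n" for u in self.users] + [f"{u} %" for u in self.users] + ["Avg %"]
        rows = []
        for idx, s in enumerate(self.steps):
            row = [f"Step {s}"]
            row += [f"{self.counts[u][idx][0]}/{self.counts[u][idx][1]}" for u in self.users]
            row += [f"{self.per_step_pct[u][idx]:.2f}" for u in self.users]
            row += [f"{self.step_average[idx]:.2f}"]
            rows.append(row)
        rows.append(
            ["Average"]
            + ["" for _ in self.users]
            + [f"{self.user_average[u]:.2f}" for u in self.users]
            + [f"{self.overall:.2f}"]
        )
        widths = [max(len(r[c]) for r in [head] + rows) for c in range(len(head))]
        fmt = "  ".join("{:<%d}" % w for w in widths)
        return "\n".join(fmt.format(*r) for r in [head] + rows)


def aggregate_accuracy(
    counts: Mapping[str, Sequence[tuple[int, int]]],
    steps: Sequence[int] | None = None,
) -> AccuracyReport:
    """Aggregate per-step identification counts into percentage accuracies.

    ``counts[user]`` is an ordered list of (identified, attempted) pairs,
    one per throwing stage (Step 0 first).  Per-user averages are means of
    that user's step accuracies, per-step averages are means across users,
    and the overall accuracy is the mean of the per-user averages; all are
    computed exactly and truncated toward zero at two decimals.
    """
    if not counts:
        raise ValueError("no counts supplied")
    users = list(counts)
    n_steps = len(counts[users[0]])
    step_ids = list(steps) if steps is not None else list(range(n_steps))
    if len(step_ids) != n_steps:
        raise ValueError("steps must match the per-user count length")
    exact: dict[str, list[Fraction]] = {}
    for u in users:
        if len(counts[u]) != n_steps:
            raise ValueError(f"user {u!r} has a different number of stages")
        row = []
        for k, n in counts[u]:
            if n <= 0:
                raise ValueError(f"user {u!r}: attempt count must be positive")
            if not 0 <= k <= n:
                raise ValueError(f"user {u!r}: identified count outside [0, n]")
            row.append(Fraction(100 * k, n))
        exact[u] = row
    user_avg_exact = {u: sum(exact[u], Fraction(0)) / n_steps for u in users}
    step_avg_exact = [
        sum((exact[u][i] for u in users), Fraction(0)) / len(users) for i in range(n_steps)
    ]
    overall_exact = sum(user_avg_exact.values(), Fraction(0)) / len(users)
    return AccuracyReport(
        users=users,
        steps=step_ids,
        counts={u: [tuple(c) for c in counts[u]] for u in users},
        per_step_pct={u: [_trunc2(v) for v in exact[u]] for u in users},
        user_average={u: _trunc2(user_avg_exact[u]) for u in users},
        step_average=[_trunc2(v) for v in step_avg_exact],
        overall=_trunc2(overall_exact),
    )


def identification_counts(
    report: SessionReport,
    intended: Sequence[Mapping[int, tuple[str, str]]],
    intended_ready: Sequence[bool] | None = None,
) -> list[tuple[int, int]]:
    """Per-stage (identified, attempted) counts against ground-truth verdicts.

    ``intended[i]`` maps step number (1..6) to the (status, message) the
    i-th throw should receive; ``intended_ready[i]`` is the expected Step 0
    outcome (default: all ready).  A stage is identified when the
    recognizer's verdict matches the intended one, including the message
    for erroneous steps.
    """
    n = len(intended)
    ready_ok = [r.ok for r in report.ready_checks]
    exp_ready = list(intended_ready) if intended_ready is not None else [True] * n
    counts: list[tuple[int, int]] = []
    got0 = sum(
        1
        for i in range(n)
        if (ready_ok[i] if i < len(ready_ok) else False) == exp_ready[i]
    )
    counts.append((got0, n))
    for k in range(1, 7):
        hit = 0
        for i in range(n):
            if i >= len(report.throws):
                continue
            got = report.throws[i].steps[k]
            want_status, want_msg = intended[i][k]
            if got.status == want_status and (want_status != ERROR or got.message == want_msg):
                hit += 1
        counts.append((hit, n))
    return counts
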