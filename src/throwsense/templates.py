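"""The throwing-action template database.

Holds the six phase templates (one per throwing step), the thirteen
ordered sub-step/transition templates used for continuous matching, the
erroneous-action message catalogue, and the deviant patterns that allow a
failed step to be given a specific diagnosis.

Class-order convention
----------------------
Phase templates list their symbol classes in temporal (chronological)
order: Step 1 is P then E (standing -> forearm up), Step 2 is Y, M, A, and
so on.  The thirteen sub-templates are stored in their traditional printed
brace notation, which lists classes in *reverse* temporal order — e.g.
"Step 1 = {E-P}" denotes the P-run followed by the E-run.  Read that way
the thirteen templates chain perfectly: the temporal tail class of each
one is the temporal head class of the next, on both channels.  Accessors
``temporal_forearm`` / ``temporal_upper`` return the matching order;
``forearm_classes`` / ``upper_classes`` return the stored order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .encode import FOREARM_ALPHABET, UPPERARM_ALPHABET


@dataclass(frozen=True)
class StepTemplate:
    """Ordered per-channel symbol-class pattern for one step or transition.

    ``step`` is the numbered throwing step (1-6) the template belongs to, or
    ``None`` for a between-step transition.  ``reversed_order`` marks brace
    notation storage (classes listed anti-chronologically).
    """

    id: str
    forearm_classes: tuple[str, ...]
    upper_classes: tuple[str, ...]
    step: int | None = None
    reversed_order: bool = False

    def __post_init__(self) -> None:
        if not self.forearm_classes or not self.upper_classes:
            raise ValueError(f"template {self.id!r} needs at least one class per channel")
        for c in self.forearm_classes:
            if c not in FOREARM_ALPHABET:
                raise ValueError(f"template {self.id!r}: {c!r} is not a forearm symbol")
        for c in self.upper_classes:
            if c not in UPPERARM_ALPHABET:
                raise ValueError(f"template {self.id!r}: {c!r} is not an upper-arm symbol")

    @property
    def temporal_forearm(self) -> tuple[str, ...]:
        return tuple(reversed(self.forearm_classes)) if self.reversed_order else self.forearm_classes

    @property
    def temporal_upper(self) -> tuple[str, ...]:
        return tuple(reversed(self.upper_classes)) if self.reversed_order else self.upper_classes

    @property
    def is_transition(self) -> bool:
        return self.step is None


@dataclass(frozen=True)
class ErrorDefinition:
    """One erroneous-action catalogue entry: a step number and its message."""

    step_id: int
    message: str

    def __post_init__(self) -> None:
        if not 0 <= self.step_id <= 6:
            raise ValueError("step_id must be 0..6")


@dataclass(frozen=True)
class DeviantPattern:
    """A registered signature that maps a failed step to a specific message.

    ``forearm_absent`` — classes that must all be missing from the forearm
    stream after the failure point; ``upper_present`` — classes that must
    all still occur on the upper arm (the channel "proceeds"); ``all_rest``
    — the remainder of both channels is rest/standing only.
    """

    step: int
    message: str
    forearm_absent: tuple[str, ...] = ()
    upper_present: tuple[str, ...] = ()
    all_rest: bool = False


@dataclass
class TemplateDB:
    """The full throwing-action database."""

    phase_templates: dict[int, StepTemplate]
    sub_templates: list[StepTemplate]
    error_defs: list[ErrorDefinition]
    deviants: list[DeviantPattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k in range(1, 7):
            if k not in self.phase_templates:
                raise ValueError(f"phase template for Step {k} missing")
            if not any(e.step_id == k for e in self.error_defs):
                raise ValueError(f"no error definition for Step {k}")

    def errors_for(self, step: int) -> list[str]:
        return [e.message for e in self.error_defs if e.step_id == step]

    def generic_error(self, step: int) -> str:
        """The catch-all message for a step (the 'Error-k' entry when present)."""
        generic = f"Error-{step}"
        return generic if generic in self.errors_for(step) else self.errors_for(step)[0]

    def subs_for(self, step: int) -> list[StepTemplate]:
        return [t for t in self.sub_templates if t.step == step]


def _phase(step: int, fore: str, upper: str) -> StepTemplate:
    return StepTemplate(
        id=f"Step {step}",
        forearm_classes=tuple(fore.split("-")),
        upper_classes=tuple(upper.split("-")),
        step=step,
        reversed_order=False,
    )


def _sub(id_: str, fore: str, upper: str, step: int | None) -> StepTemplate:
    return StepTemplate(
        id=id_,
        forearm_classes=tuple(fore.split("-")),
        upper_classes=tuple(upper.split("-")),
        step=step,
        reversed_order=True,
    )


def builtin_db() -> TemplateDB:
    """The hard-coded throwing-action database.

    Phase templates are stored chronologically; the thirteen sub-templates
    keep their printed brace order (anti-chronological, see module notes).
    """
    phases = {
        1: _phase(1, "P-E", "p"),
        2: _phase(2, "Y-M-A", "k-a"),
        3: _phase(3, "G-B-H", "m-y-r"),
        4: _phase(4, "D-L-F-M", "r-y"),
        5: _phase(5, "A", "a"),
        6: _phase(6, "K", "k"),
    }
    subs = [
        _sub("Step 1", "E-P", "p", 1),
        _sub("Steps 1-2", "Y-E", "k-p", None),
        _sub("Step 2.1", "M-Y", "k", 2),
        _sub("Step 2.2", "A-M", "a-k", 2),
        _sub("Steps 2-3", "G-A", "m-a", None),
        _sub("Step 3.1", "B-G", "y-m", 3),
        _sub("Step 3.2", "H-B", "r-y", 3),
        _sub("Steps 3-4", "D-H", "r", None),
        _sub("Step 4.1", "L-D", "r", 4),
        _sub("Step 4.2", "F-L", "y-r", 4),
        _sub("Step 4.3", "M-F", "y", 4),
        _sub("Step 5", "A-M", "a-y", 5),
        _sub("Step 6", "K-A", "k-a", 6),
    ]
    errors = [
        ErrorDefinition(0, "Worn too inside or outside"),
        ErrorDefinition(1, "Error-1"),
        ErrorDefinition(2, "Error-2"),
        ErrorDefinition(2, "Inverted W"),
        ErrorDefinition(3, "Error-3"),
        ErrorDefinition(3, "Elbow is too low"),
        ErrorDefinition(3, "Forearm flyout"),
        ErrorDefinition(4, "Error-4"),
        ErrorDefinition(4, "Elbow is not high enough"),
        ErrorDefinition(5, "Error-5"),
        ErrorDefinition(6, "Error-6"),
        ErrorDefinition(6, "No follow-through"),
    ]
    deviants = [
        # Arm acceleration never happens on the forearm while the upper arm
        # carries on: the elbow stayed low during the whip.
        DeviantPattern(
            step=4,
            message="Elbow is not high enough",
            forearm_absent=("D", "L", "F", "M"),
            upper_present=("r", "y"),
        ),
        # Nothing at all after ball release: the arm simply stopped.
        DeviantPattern(step=6, message="No follow-through", all_rest=True),
    ]
    return TemplateDB(phases, subs, errors, deviants)


def expand_template(tmpl: StepTemplate, run_lengths) -> tuple[str, str]:
    """Expand a template into a concrete sequence-pair fragment.

    ``run_lengths`` gives one positive run length per forearm class (in the
    stored class order); the upper-arm classes are distributed evenly over
    the same total length so both channels stay aligned.
    """
    lengths = [int(n) for n in run_lengths]
    if len(lengths) != len(tmpl.forearm_classes):
        raise ValueError("one run length per forearm class required")
    if any(n <= 0 for n in lengths):
        raise ValueError("run lengths must be positive")
    fore = "".join(c * n for c, n in zip(tmpl.forearm_classes, lengths))
    total = sum(lengths)
    k = len(tmpl.upper_classes)
    base, extra = divmod(total, k)
    upper = "".join(
        c * (base + (1 if i < extra else 0)) for i, c in enumerate(tmpl.upper_classes)
    )
    return fore, upper


def _tmpl_to_dict(t: StepTemplate) -> dict:
    return {
        "id": t.id,
        "step": t.step,
        "forearm": list(t.forearm_classes),
        "upper": list(t.upper_classes),
        "reversed_order": t.reversed_order,
    }


def _tmpl_from_dict(d: dict) -> StepTemplate:
    return StepTemplate(
        id=d["id"],
        forearm_classes=tuple(d["forearm"]),
        upper_classes=tuple(d["upper"]),
        step=d.get("step"),
        reversed_order=bool(d.get("reversed_order", False)),
    )


def save_db(db: TemplateDB, path) -> None:
    """Write a TemplateDB to JSON, preserving template order."""
    payload = {
        "phase_templates": [_tmpl_to_dict(db.phase_templates[k]) for k in sorted(db.phase_templates)],
        "sub_templates": [_tmpl_to_dict(t) for t in db.sub_templates],
        "errors": [{"step": e.step_id, "message": e.message} for e in db.error_defs],
        "deviants": [
            {
                "step": d.step,
                "message": d.message,
                "forearm_absent": list(d.forearm_absent),
                "upper_present": list(d.upper_present),
                "all_rest": d.all_rest,
            }
            for d in db.deviants
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_db(path) -> TemplateDB:
    """Load a TemplateDB from JSON; symbol validation names the offending entry."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed template database {path}: {exc}") from exc
    phases = {}
    for d in payload.get("phase_templates", []):
        t = _tmpl_from_dict(d)
        if t.step is None:
            raise ValueError(f"phase template {t.id!r} lacks a step number")
        phases[t.step] = t
    subs = [_tmpl_from_dict(d) for d in payload.get("sub_templates", [])]
    errors = [ErrorDefinition(d["step"], d["message"]) for d in payload.get("errors", [])]
    deviants = [
        DeviantPattern(
            step=d["step"],
            message=d["message"],
            forearm_absent=tuple(d.get("forearm_absent", ())),
            upper_present=tuple(d.get("upper_present", ())),
            all_rest=bool(d.get("all_rest", False)),
        )
        for d in payload.get("deviants", [])
    ]
    return TemplateDB(phases, subs, errors, deviants)
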