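"""Motivate-to-self-refer dialogue policy.

When auto-referral is not possible (e.g. an anonymous web service), the
system's remaining lever is to *motivate* the user to contact human care
themselves.  Social-judgement theory predicts that a suggestion lands
differently depending on whether it falls in the user's latitude of
acceptance, noncommitment or rejection, so the policy classifies the user's
situation on a 3x3 grid of initial stance towards seeking human care
(negative / doubting / positive) and health-situation severity
(low / medium / high):

=========  =========  =========  =========
severity   negative   doubting   positive
=========  =========  =========  =========
high       1 (CP)     2 (CP)     3 (AC)
medium     4 (RC)     5 (CP)     6 (AC)
low        7 (RC)     8 (RC)     9 (AC)
=========  =========  =========  =========

*Accept care* (AC, positive stance at any severity) users are in the
latitude of acceptance — the agent simply **facilitates** by providing
contact details.  *Care potential* (CP) users are in the latitude of
noncommitment — the agent **persuades** (tailored to the user's stated
concern: money, travel time, or stigma) and then continues to facilitation
by default, unless the user actively objects.  *Reject care* (RC) users
are in the latitude of rejection, where pushing would backfire — the agent
**accepts the rejection** but keeps a standing offer of contact details.
Note that a negative stance in a *severe* situation (cell 1) is care
potential, not reject care: with high severity there is little to lose by
trying to persuade.

Scripts are data (JSON templates, overridable); the engine's tested
contract is turn ordering, branching and placeholder resolution, not
wording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Mapping, Sequence

from aemh_triage.errors import ConfigurationError, InputError, TemplateError

__all__ = [
    "STANCES",
    "SEVERITIES",
    "SITUATION_TYPES",
    "STRATEGIES",
    "Situation",
    "Concern",
    "DialogueTurn",
    "DialogueScript",
    "classify_situation",
    "select_strategy",
    "render_dialogue",
    "run_policy",
    "load_default_templates",
]

STANCES = ("negative", "doubting", "positive")
SEVERITIES = ("low", "medium", "high")
STRATEGIES = ("facilitate", "persuade", "accept_rejection")
SITUATION_TYPES = ("accept_care", "care_potential", "reject_care")

# Grid ids are row-major with severity rows high -> medium -> low and stance
# columns negative -> doubting -> positive.
_TYPE_BY_ID = {
    1: "care_potential",
    2: "care_potential",
    5: "care_potential",
    3: "accept_care",
    6: "accept_care",
    9: "accept_care",
    4: "reject_care",
    7: "reject_care",
    8: "reject_care",
}

_STRATEGY_BY_TYPE = {
    "accept_care": "facilitate",
    "care_potential": "persuade",
    "reject_care": "accept_rejection",
}

DEFAULT_CONTACT = "the Sleep Clinic, 0800-SLEEP (weekdays 9:00-17:00)"


@dataclass(frozen=True)
class Situation:
    stance: str
    severity: str
    id: int
    sit_type: str


@dataclass(frozen=True)
class Concern:
    """The user's main barrier to seeking human care.

    Exactly the fields belonging to ``kind`` may be set: ``money`` carries
    ``money_problem_amount`` (currency), ``time`` carries
    ``travel_problem_hours``, ``stigma`` carries ``stigma_group`` (family,
    friends or boss).
    """

    kind: str
    money_problem_amount: float | None = None
    travel_problem_hours: float | None = None
    stigma_group: str | None = None

    def __post_init__(self):
        if self.kind not in ("money", "time", "stigma"):
            raise InputError(f"concern kind must be money/time/stigma, got {self.kind!r}")
        expected = {
            "money": "money_problem_amount",
            "time": "travel_problem_hours",
            "stigma": "stigma_group",
        }[self.kind]
        for name in ("money_problem_amount", "travel_problem_hours", "stigma_group"):
            value = getattr(self, name)
            if name == expected and value is None:
                raise InputError(f"concern of kind {self.kind!r} requires {name}")
            if name != expected and value is not None:
                raise InputError(f"concern of kind {self.kind!r} must not set {name}")
        if self.kind == "stigma" and self.stigma_group not in ("family", "friends", "boss"):
            raise InputError("stigma_group must be family, friends or boss")

    def placeholders(self) -> dict[str, str]:
        if self.kind == "money":
            return {"amount": f"${self.money_problem_amount:g}"}
        if self.kind == "time":
            return {"hours": f"{self.travel_problem_hours:g}"}
        return {"stigma_group": str(self.stigma_group)}


@dataclass(frozen=True)
class DialogueTurn:
    id: str
    speaker: str
    text: str
    responses: Mapping[str, str] | None = None  # choice label -> next turn id or "end"
    default: str | None = None
    next: str | None = None  # explicit successor for non-branching turns
    role: str | None = None

    def is_branch(self) -> bool:
        return self.responses is not None


@dataclass(frozen=True)
class DialogueScript:
    strategy: str
    turns: tuple[DialogueTurn, ...]

    def turn(self, turn_id: str) -> DialogueTurn:
        for t in self.turns:
            if t.id == turn_id:
                return t
        raise TemplateError(f"branch label {turn_id!r} resolves to no turn")

    def successor(self, turn: DialogueTurn, choice: str | None = None) -> str:
        """Resolve the id of the next turn ("end" terminates)."""
        if turn.is_branch():
            label = choice if choice is not None else turn.default
            if label is None or label not in turn.responses:  # type: ignore[operator]
                raise TemplateError(
                    f"turn {turn.id!r} has no branch for choice {label!r}"
                )
            return turn.responses[label]  # type: ignore[index]
        if turn.next is not None:
            return turn.next
        # default: the next turn in script order, or end
        ids = [t.id for t in self.turns]
        idx = ids.index(turn.id)
        return ids[idx + 1] if idx + 1 < len(ids) else "end"

    def reachable_roles(self) -> set[str]:
        """Roles reachable from the first turn along *some* branch path."""
        roles: set[str] = set()
        seen: set[str] = set()
        stack = [self.turns[0].id]
        while stack:
            tid = stack.pop()
            if tid == "end" or tid in seen:
                continue
            seen.add(tid)
            t = self.turn(tid)
            if t.role:
                roles.add(t.role)
            if t.is_branch():
                stack.extend(t.responses.values())  # type: ignore[union-attr]
            else:
                stack.append(self.successor(t))
        return roles


def classify_situation(stance: str, severity: str) -> Situation:
    """Map (stance, severity) to its grid cell and situation type."""
    if stance not in STANCES:
        raise InputError(f"stance must be one of {STANCES}, got {stance!r}")
    if severity not in SEVERITIES:
        raise InputError(f"severity must be one of {SEVERITIES}, got {severity!r}")
    row = {"high": 0, "medium": 1, "low": 2}[severity]
    col = STANCES.index(stance)
    sid = row * 3 + col + 1
    return Situation(stance=stance, severity=severity, id=sid, sit_type=_TYPE_BY_ID[sid])


def select_strategy(situation: Situation) -> str:
    """Choose the referral strategy matched to the situation type."""
    return _STRATEGY_BY_TYPE[situation.sit_type]


def load_default_templates() -> dict:
    with resources.files("aemh_triage.data").joinpath("dialogues.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


def _resolve(text: str, values: Mapping[str, str], turn_id: str) -> str:
    try:
        return text.format(**values)
    except (KeyError, IndexError) as exc:
        raise TemplateError(f"unresolved placeholder {exc} in turn {turn_id!r}") from exc


def render_dialogue(
    strategy: str,
    concern: Concern,
    params: Mapping[str, Any] | None = None,
    templates: Mapping[str, Any] | None = None,
) -> DialogueScript:
    """Instantiate the script for a strategy with a user's concern.

    The rendered script contains, in order: greeting, the two
    manipulation-check elicitations (perceived severity and stance, each a
    3-option multiple choice), the optional tips block (skipped when the
    user answers "no"), then the strategy block.  ``params`` may override
    ``contact`` (the contact details inserted into facilitation turns).
    """
    if strategy not in STRATEGIES:
        raise InputError(f"unknown strategy {strategy!r}")
    if templates is None:
        templates = load_default_templates()
    params = dict(params or {})
    values = concern.placeholders()
    values["contact"] = params.get("contact", DEFAULT_CONTACT)

    concern_message = _resolve(
        templates["concern_messages"][concern.kind], values, "concern_message"
    )
    values["concern_message"] = concern_message

    raw_turns = list(templates["common_prefix"]) + list(templates["strategies"][strategy])
    turns = []
    for raw in raw_turns:
        turns.append(
            DialogueTurn(
                id=raw["id"],
                speaker=raw.get("speaker", "agent"),
                text=_resolve(raw.get("text", ""), values, raw["id"]),
                responses=dict(raw["responses"]) if raw.get("responses") else None,
                default=raw.get("default"),
                next=raw.get("next"),
                role=raw.get("role"),
            )
        )
    script = DialogueScript(strategy=strategy, turns=tuple(turns))
    # validate branch labels up front so a broken template fails loudly
    for t in script.turns:
        if t.is_branch():
            for target in t.responses.values():  # type: ignore[union-attr]
                if target != "end":
                    script.turn(target)
    return script


def walk(script: DialogueScript, user_events) -> list[dict]:
    """Execute a script, resolving user choices at branching turns.

    ``user_events`` is either a mapping ``{turn_id: choice}`` or a sequence
    of choice labels; a sequence entry is consumed when it is a legal label
    for the branching turn currently being executed.  A branching turn with
    no matching user event takes its default branch (default continuation —
    the user has to *actively* choose to leave the scripted path).
    Returns the transcript of executed turns with the choices taken.
    """
    if isinstance(user_events, Mapping):
        by_turn = dict(user_events)
        pending: list[str] = []
    else:
        by_turn = {}
        pending = list(user_events)
    transcript: list[dict] = []
    tid = script.turns[0].id
    guard = 0
    while tid != "end":
        guard += 1
        if guard > 10 * len(script.turns):
            raise TemplateError("dialogue walk does not terminate (cyclic branches)")
        turn = script.turn(tid)
        entry: dict[str, Any] = {"turn": turn.id, "speaker": turn.speaker, "text": turn.text}
        if turn.role:
            entry["role"] = turn.role
        choice = None
        if turn.is_branch():
            if turn.id in by_turn:
                choice = by_turn.pop(turn.id)
            elif pending and pending[0] in turn.responses:  # type: ignore[operator]
                choice = pending.pop(0)
            entry["choice"] = choice if choice is not None else turn.default
            entry["defaulted"] = choice is None
        transcript.append(entry)
        tid = script.successor(turn, choice)
    return transcript


def run_policy(
    stance: str,
    severity: str,
    concern: Concern,
    user_events: Mapping[str, str] | Sequence[str] = (),
    strategy_override: str | None = None,
    params: Mapping[str, Any] | None = None,
    templates: Mapping[str, Any] | None = None,
) -> dict:
    """Classify, select, render and walk: the full motivation pipeline.

    ``strategy_override`` crosses any strategy with any situation (as the
    evaluation design requires); by default the matched strategy is used.
    """
    situation = classify_situation(stance, severity)
    strategy = strategy_override or select_strategy(situation)
    script = render_dialogue(strategy, concern, params=params, templates=templates)
    transcript = walk(script, user_events)
    return {
        "situation": vars(situation),
        "strategy": strategy,
        "transcript": transcript,
    }
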