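"""Consent-gated auto-referral workflow.

Once a risk has been detected and referral decided, an AEMH system may
contact a human caregiver on the user's behalf — but only if the user
approved this procedure beforehand.  The workflow is a small finite state
machine with three branches after the consent gate:

* **takeover** — a caregiver can step in directly: the handover is
  announced and the caregiver takes over the interaction;
* **crisis** — the caregiver is alerted immediately and the patient is
  told when to expect contact, given the caregiver's contact details (so
  they can reach out themselves, also covering network failure), and given
  short-term coping options;
* **non-crisis** — the patient is asked to contact the caregiver
  themselves, with the caregiver notified as a safety net; only when the
  self-contact deadline passes without patient contact does the caregiver
  actively seek contact.

Time is modelled by explicit ``tick`` events rather than a wall clock, so
every run is a pure, replayable function of the case and its event
sequence.  The deadline comparison is strict: outreach triggers once the
elapsed clock *exceeds* ``self_contact_deadline``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

from aemh_triage.errors import ConfigurationError, InputError

__all__ = [
    "ReferralCase",
    "WorkflowState",
    "Action",
    "StepResult",
    "route",
    "step",
    "run_case",
]

STATES = (
    "idle",
    "risk_detected",
    "takeover_announced",
    "caregiver_in_control",
    "crisis_alerted",
    "awaiting_self_contact",
    "caregiver_outreach",
    "closed",
)

ACTION_KINDS = (
    "announce_handover",
    "alert_caregiver",
    "inform_patient_eta",
    "provide_contact_info",
    "provide_coping_options",
    "request_self_contact",
    "notify_caregiver_safety_net",
    "trigger_caregiver_outreach",
    "refuse_no_consent",
)

EVENT_KINDS = ("risk_referred", "tick", "patient_contacted", "caregiver_responded", "close")

#: Actions that disclose the case to a caregiver; none of these may ever be
#: emitted without prior consent.
DISCLOSING_ACTIONS = frozenset(
    {
        "announce_handover",
        "alert_caregiver",
        "notify_caregiver_safety_net",
        "trigger_caregiver_outreach",
    }
)


@dataclass(frozen=True)
class ReferralCase:
    case_id: str
    consent_given: bool
    caregiver_can_step_in: bool
    crisis: bool
    caregiver_contact: str = ""
    expected_response_time: float = 1.0
    self_contact_deadline: float = 24.0

    def __post_init__(self):
        if self.expected_response_time <= 0 or self.self_contact_deadline <= 0:
            raise ConfigurationError("deadlines must be strictly positive")
        if self.consent_given and not self.caregiver_contact:
            raise ConfigurationError(
                "caregiver_contact must be non-empty when a referral path can be taken"
            )


@dataclass(frozen=True)
class Action:
    kind: str
    payload: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ACTION_KINDS:
            raise InputError(f"unknown action kind {self.kind!r}")
        if self.kind == "inform_patient_eta" and "expected_response_time" not in self.payload:
            raise InputError("inform_patient_eta must carry expected_response_time")
        if self.kind == "provide_contact_info" and "caregiver_contact" not in self.payload:
            raise InputError("provide_contact_info must carry caregiver_contact")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "payload": dict(self.payload)}


@dataclass(frozen=True)
class WorkflowState:
    state: str = "idle"
    emitted: tuple[Action, ...] = ()
    clock: float = 0.0
    outreach_fired: bool = False

    def __post_init__(self):
        if self.state not in STATES:
            raise InputError(f"unknown state {self.state!r}")


@dataclass(frozen=True)
class StepResult:
    state: WorkflowState
    actions: tuple[Action, ...]
    diagnostic: str | None = None  # set when the event was rejected


def route(case: ReferralCase) -> str:
    """Plan the workflow branch for a referred case.

    Consent is checked first and is absolute; then a caregiver who can step
    in takes over; otherwise the crisis flag selects between the crisis and
    the non-crisis (self-contact) branch.
    """
    if not case.consent_given:
        return "refuse_no_consent"
    if case.caregiver_can_step_in:
        return "takeover"
    if case.crisis:
        return "crisis"
    return "non_crisis"


def _emit(state: WorkflowState, new_state: str, actions: Sequence[Action], **changes) -> StepResult:
    ws = replace(
        state, state=new_state, emitted=state.emitted + tuple(actions), **changes
    )
    return StepResult(ws, tuple(actions))


def _reject(state: WorkflowState, event_kind: str) -> StepResult:
    return StepResult(
        state, (), diagnostic=f"event {event_kind!r} is not legal in state {state.state!r}"
    )


def step(case: ReferralCase, state: WorkflowState, event) -> StepResult:
    """Apply one event to the workflow.

    ``event`` is either a string kind or a ``(kind, payload)`` tuple; only
    ``tick`` takes a payload (the elapsed duration).  Illegal events leave
    the state unchanged and return a diagnostic instead of raising, so a
    replay of a noisy event log is total.
    """
    if isinstance(event, str):
        kind, payload = event, None
    else:
        kind, payload = event[0], (event[1] if len(event) > 1 else None)
    if kind not in EVENT_KINDS:
        raise InputError(f"unknown event kind {kind!r}")

    s = state.state

    if kind == "tick":
        if payload is None or payload < 0:
            raise InputError("tick requires a non-negative duration")
        if s == "closed":
            return _reject(state, kind)
        new_clock = state.clock + float(payload)
        if (
            s == "awaiting_self_contact"
            and new_clock > case.self_contact_deadline
            and not state.outreach_fired
        ):
            action = Action("trigger_caregiver_outreach", {"case_id": case.case_id})
            return _emit(
                state,
                "caregiver_outreach",
                [action],
                clock=new_clock,
                outreach_fired=True,
            )
        return StepResult(replace(state, clock=new_clock), ())

    if kind == "risk_referred":
        if s != "idle":
            return _reject(state, kind)
        branch = route(case)
        if branch == "refuse_no_consent":
            return _emit(
                state,
                "closed",
                [Action("refuse_no_consent", {"case_id": case.case_id})],
            )
        if branch == "takeover":
            return _emit(
                state,
                "caregiver_in_control",
                [Action("announce_handover", {"case_id": case.case_id})],
            )
        if branch == "crisis":
            actions = [
                Action("alert_caregiver", {"case_id": case.case_id}),
                Action(
                    "inform_patient_eta",
                    {"expected_response_time": case.expected_response_time},
                ),
                Action("provide_contact_info", {"caregiver_contact": case.caregiver_contact}),
                Action("provide_coping_options", {}),
            ]
            return _emit(state, "crisis_alerted", actions)
        # non-crisis: incentive lies with the patient; caregiver informed as
        # safety net; contact details always provided (network-failure note)
        actions = [
            Action("request_self_contact", {"deadline": case.self_contact_deadline}),
            Action("provide_contact_info", {"caregiver_contact": case.caregiver_contact}),
            Action("notify_caregiver_safety_net", {"case_id": case.case_id}),
        ]
        return _emit(state, "awaiting_self_contact", actions)

    if kind == "patient_contacted":
        if s in ("crisis_alerted", "awaiting_self_contact", "caregiver_outreach"):
            return _emit(state, "closed", [])
        return _reject(state, kind)

    if kind == "caregiver_responded":
        if s in ("crisis_alerted", "caregiver_outreach", "caregiver_in_control"):
            return _emit(state, "closed", [])
        return _reject(state, kind)

    if kind == "close":
        if s == "closed":
            return _reject(state, kind)
        return _emit(state, "closed", [])

    raise AssertionError("unreachable")


def run_case(case: ReferralCase, events: Iterable) -> list[dict]:
    """Fold :func:`step` over a time-ordered event sequence.

    Returns a transcript: one entry per event with the actions emitted (or
    the rejection diagnostic) and the resulting state.
    """
    state = WorkflowState()
    transcript: list[dict] = []
    for event in events:
        result = step(case, state, event)
        state = result.state
        entry: dict[str, Any] = {
            "event": event if isinstance(event, str) else list(event),
            "state": state.state,
            "actions": [a.to_dict() for a in result.actions],
        }
        if result.diagnostic is not None:
            entry["rejected"] = result.diagnostic
        transcript.append(entry)
    return transcript
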