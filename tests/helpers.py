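"""Shared test utilities: exhaustive exploration of the referral workflow."""

from __future__ import annotations

import itertools

from aemh_triage.auto_referral import ReferralCase, WorkflowState, step

#: Event alphabet used for exhaustive exploration.  Tick sizes are chosen
#: relative to a unit deadline so that repeated small ticks can also cross
#: it (0.4 + 0.4 + 0.4 > 1).
EVENT_ALPHABET = (
    "risk_referred",
    ("tick", 0.4),
    ("tick", 1.1),
    "patient_contacted",
    "caregiver_responded",
    "close",
)


def all_case_configs() -> list[ReferralCase]:
    cases = []
    for consent, step_in, crisis in itertools.product([False, True], repeat=3):
        cases.append(
            ReferralCase(
                case_id=f"c{int(consent)}{int(step_in)}{int(crisis)}",
                consent_given=consent,
                caregiver_can_step_in=step_in,
                crisis=crisis,
                caregiver_contact="0800-1234" if consent else "",
                expected_response_time=0.5,
                self_contact_deadline=1.0,
            )
        )
    return cases


def _signature(state: WorkflowState) -> tuple:
    return (
        state.state,
        round(state.clock, 6),
        state.outreach_fired,
        tuple(a.kind for a in state.emitted),
    )


def explore_machine(case: ReferralCase, max_depth: int = 8):
    """Breadth-first exploration of every event sequence up to ``max_depth``.

    Yields every transition as ``(state_before, event, actions, state_after)``.
    States are deduplicated by signature per depth, which is sound because
    ``step`` is a pure function of (case, state, event).
    """
    frontier = {_signature(WorkflowState()): WorkflowState()}
    for _ in range(max_depth):
        nxt: dict[tuple, WorkflowState] = {}
        for state in frontier.values():
            for event in EVENT_ALPHABET:
                result = step(case, state, event)
                yield state, event, result.actions, result.state
                nxt.setdefault(_signature(result.state), result.state)
        frontier = nxt
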