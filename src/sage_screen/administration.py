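"""Adaptive session engine.

A session walks through the instrument in two phases. The *screener* phase
presents every screener item in authored order, honouring screener-internal
gates (an item with ``gate_item_ids`` is only shown once a gate item has been
answered "yes"; it is skipped outright once all gates are answered "no").
When the screener completes, each module's threshold rule is evaluated and
the *follow-up* phase queues the follow-up sections of screened-in modules,
in instrument order. The engine is fully deterministic: identical response
scripts yield identical item sequences and final state.
"""

from __future__ import annotations

from typing import Mapping, Optional

from pydantic import BaseModel, Field

from .errors import (
    IncompleteResponsesError,
    UnknownItemError,
)
from .model import (
    Instrument,
    Item,
    ResponseKind,
    ResponseValue,
    evaluate_rule,
)


class Response(BaseModel):
    """One recorded answer."""

    item_id: str
    value: ResponseValue
    occasion_timestamp: Optional[str] = None


class Session(BaseModel):
    """One respondent's adaptive pass through an instrument.

    ``screen_in`` is populated only once every administrable screener item is
    answered; ``skipped_item_ids`` records gated screener items whose gates
    all resolved "no".
    """

    session_id: str = "session"
    instrument_name: str = ""
    instrument_version: str = ""
    phase: str = "screener"  # screener | followup | complete
    responses: list[Response] = Field(default_factory=list)
    screen_in: dict[str, bool] = Field(default_factory=dict)
    skipped_item_ids: list[str] = Field(default_factory=list)

    def response_map(self) -> dict[str, ResponseValue]:
        return {r.item_id: r.value for r in self.responses}


def start_session(instr: Instrument, session_id: str = "session") -> Session:
    """Open a fresh session in the screener phase."""
    return Session(
        session_id=session_id,
        instrument_name=instr.name,
        instrument_version=instr.schema_version,
    )


def _gate_state(item: Item, answered: Mapping[str, ResponseValue]) -> str:
    """'open' (administrable), 'closed' (skip), or 'undecided' (gates pending)."""
    if not item.gate_item_ids:
        return "open"
    if any(answered.get(g) is True for g in item.gate_item_ids):
        return "open"
    if all(g in answered for g in item.gate_item_ids):
        return "closed"
    return "undecided"


def skipped_screener_items(
    instr: Instrument, answered: Mapping[str, ResponseValue]
) -> set[str]:
    """Screener items whose gates are all answered and all "no"."""
    return {
        it.item_id
        for it in instr.screener_items()
        if _gate_state(it, answered) == "closed"
    }


def screener_complete(instr: Instrument, answered: Mapping[str, ResponseValue]) -> bool:
    for it in instr.screener_items():
        state = _gate_state(it, answered)
        if state == "closed":
            continue
        if state == "undecided" or it.item_id not in answered:
            return False
    return True


def evaluate_screen_in(
    instr: Instrument, module_id: str, responses: Mapping[str, ResponseValue]
) -> bool:
    """Pure threshold-rule evaluation for one module.

    Requires every administrable screener item of the module to be answered;
    gated items legitimately skipped evaluate their atoms to False. Raises
    ``IncompleteResponsesError`` otherwise.
    """
    module = instr.modules_by_id()[module_id]
    items = instr.items_by_id()
    skipped: set[str] = set()
    missing: list[str] = []
    for iid in module.screener_item_ids:
        if iid in responses:
            continue
        state = _gate_state(items[iid], responses)
        if state == "closed":
            skipped.add(iid)
        else:
            missing.append(iid)
    if missing:
        raise IncompleteResponsesError(missing, context=f"module {module_id!r} screener")
    return evaluate_rule(module.screen_in_rule, responses, absent_false=skipped)


def next_items(instr: Instrument, session: Session) -> list[Item]:
    """The ordered queue of items still to administer.

    Screener items first (authored order, gated items deferred until their
    gates resolve); once the screener completes, follow-up sections of
    screened-in modules in instrument order. Empty iff the session is
    complete.
    """
    answered = session.response_map()
    items = instr.items_by_id()
    pending: list[Item] = []
    if not screener_complete(instr, answered):
        for module in instr.modules:
            for iid in module.screener_item_ids:
                it = items[iid]
                if iid in answered:
                    continue
                if _gate_state(it, answered) == "open":
                    pending.append(it)
        return pending
    for module in instr.modules:
        if session.screen_in.get(module.module_id) or (
            not session.screen_in
            and evaluate_screen_in(instr, module.module_id, answered)
        ):
            for iid in module.followup_item_ids:
                if iid not in answered:
                    pending.append(items[iid])
    return pending


def record_response(instr: Instrument, session: Session, response: Response) -> Session:
    """Record one answer, advance the queue, and update phase state.

    Raises ``UnknownItemError`` for unknown or non-pending items and
    ``ResponseRangeError`` for out-of-range values. Mutates and returns the
    session.
    """
    items = instr.items_by_id()
    item = items.get(response.item_id)
    if item is None:
        raise UnknownItemError(f"unknown item {response.item_id!r}")
    pending_ids = {it.item_id for it in next_items(instr, session)}
    if response.item_id not in pending_ids:
        raise UnknownItemError(
            f"item {response.item_id!r} is not pending in this session"
        )
    item.validate_value(response.value)
    session.responses.append(response)

    answered = session.response_map()
    if session.phase == "screener" and screener_complete(instr, answered):
        session.screen_in = {
            m.module_id: evaluate_screen_in(instr, m.module_id, answered)
            for m in instr.modules
        }
        session.skipped_item_ids = sorted(skipped_screener_items(instr, answered))
        session.phase = "followup"
    if session.phase == "followup" and not next_items(instr, session):
        session.phase = "complete"
    return session


def replay_script(
    instr: Instrument,
    script: Mapping[str, ResponseValue],
    session_id: str = "session",
) -> Session:
    """Administer a full session from a scripted item→value mapping.

    At each step the first pending item is answered from the script; a missing
    script entry raises ``IncompleteResponsesError``. This is the scripted
    (CSV-driven) administration path.
    """
    session = start_session(instr, session_id)
    while True:
        queue = next_items(instr, session)
        if not queue:
            if session.phase != "complete":
                session.phase = "complete"
            break
        item = queue[0]
        if item.item_id not in script:
            raise IncompleteResponsesError(
                [item.item_id], context=f"script for session {session_id!r}"
            )
        record_response(instr, session, Response(item_id=item.item_id,
                                                 value=script[item.item_id]))
        if session.phase == "complete":
            break
    return session
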