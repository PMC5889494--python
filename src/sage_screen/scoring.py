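"""Scoring: endorsement mapping, criterion evaluation, diagnosis rules, and
the differential-diagnosis report.

The endorsement mapping is the empirically validated bridge between the
5-level frequency scale and binary DSM-criterion endorsement: a forward item
endorses at "often" (4) or "always" (5); a reverse-scored item endorses at
"never" (1) or "rarely" (2). Yes/no items endorse on "yes"; day-count items
endorse at their documented per-item cut. Diagnosis thresholds are therefore
strictly more specific than the screen-in thresholds (>= often vs
>= sometimes), mirroring the instrument's sensitive-screen / specific-
diagnose design.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

from pydantic import BaseModel, Field

from .administration import Session, evaluate_screen_in, skipped_screener_items
from .errors import IncompleteResponsesError, ResponseRangeError, UnsupportedModuleError
from .model import (
    CriterionDef,
    DiagnosisRule,
    Instrument,
    Item,
    ResponseKind,
    ResponseValue,
)


def to_endorsement(item: Item, value: ResponseValue) -> bool:
    """Binary criterion endorsement for one response (Stage-II mapping)."""
    item.validate_value(value)
    kind = item.response_kind
    if kind is ResponseKind.likert5:
        return value <= 2 if item.reverse_scored else value >= 4
    if kind is ResponseKind.yes_no:
        return bool(value)
    if item.count_cut is None:
        raise ResponseRangeError(
            f"count_days item {item.item_id!r} has no documented endorsement cut"
        )
    return value >= item.count_cut


def likert_severity(item: Item, value: int) -> int:
    """Severity on the 1..5 frequency scale, with reverse items mirrored."""
    return 6 - value if item.reverse_scored else value


class CriterionEndorsement(BaseModel):
    criterion_id: str
    endorsed: bool
    supporting_item_ids: list[str] = Field(default_factory=list)
    #: Highest mirrored frequency level among mapped Likert items (severity
    #: signal); None when no mapped Likert item was administered.
    max_frequency_level: Optional[int] = None


def evaluate_criterion(
    criterion: CriterionDef,
    instr: Instrument,
    responses: Mapping[str, ResponseValue],
) -> CriterionEndorsement:
    """Endorsed iff any mapped item endorses; severity is the max mirrored
    Likert level over mapped items. Requires all mapped items answered."""
    items = instr.items_by_id()
    missing = [i for i in criterion.mapped_item_ids if i not in responses]
    if missing:
        raise IncompleteResponsesError(missing,
                                       context=f"criterion {criterion.criterion_id!r}")
    supporting = []
    max_level: Optional[int] = None
    for iid in criterion.mapped_item_ids:
        item = items[iid]
        value = responses[iid]
        if to_endorsement(item, value):
            supporting.append(iid)
        if item.response_kind is ResponseKind.likert5:
            level = likert_severity(item, value)
            max_level = level if max_level is None else max(max_level, level)
    return CriterionEndorsement(
        criterion_id=criterion.criterion_id,
        endorsed=bool(supporting),
        supporting_item_ids=supporting,
        max_frequency_level=max_level,
    )


def evaluate_diagnosis(rule: DiagnosisRule, endorsements: Mapping[str, bool]) -> bool:
    """True iff >= required_count criteria endorsed and, when a cardinal
    subset is declared, at least one cardinal criterion endorsed."""
    missing = [c for c in rule.criterion_ids if c not in endorsements]
    if missing:
        raise IncompleteResponsesError(missing,
                                       context=f"diagnosis {rule.diagnosis_name!r}")
    count = sum(bool(endorsements[c]) for c in rule.criterion_ids)
    if count < rule.required_count:
        return False
    if rule.cardinal_criterion_ids:
        return any(endorsements[c] for c in rule.cardinal_criterion_ids)
    return True


class IncludedDiagnosis(BaseModel):
    diagnosis_name: str
    endorsed_criteria_count: int
    required_count: int
    cardinal_satisfied: bool
    episode: bool = False


class SeverityEntry(BaseModel):
    item_id: str
    value: ResponseValue
    reverse_scored: bool = False


class DifferentialReport(BaseModel):
    """Machine-readable differential: screen status per module, rule-level
    inclusions, and the per-item symptom frequency inventory."""

    session_id: str
    screen_status: dict[str, str]  # module_id -> in | out | incomplete
    included_diagnoses: list[IncludedDiagnosis] = Field(default_factory=list)
    severity_inventory: list[SeverityEntry] = Field(default_factory=list)
    incomplete_modules: list[str] = Field(default_factory=list)


def build_differential(instr: Instrument, session: Session) -> DifferentialReport:
    """Score a session into a differential report.

    Only screened-in modules with complete follow-up data contribute
    diagnoses; partial modules are reported as incomplete, never silently
    scored. Incompleteness is data in the report, not an exception.
    """
    responses = session.response_map()
    items = instr.items_by_id()
    criteria = instr.criteria_by_id()

    screen_status: dict[str, str] = {}
    for module in instr.modules:
        try:
            screened = evaluate_screen_in(instr, module.module_id, responses)
        except IncompleteResponsesError:
            screen_status[module.module_id] = "incomplete"
            continue
        screen_status[module.module_id] = "in" if screened else "out"

    incomplete: list[str] = []
    included: list[IncludedDiagnosis] = []
    skipped = skipped_screener_items(instr, responses)
    for module in instr.modules:
        if screen_status.get(module.module_id) != "in":
            continue
        module_rules = [
            r for r in instr.diagnosis_rules
            if instr.module_of_rule(r) == module.module_id
        ]
        needed = {
            iid
            for r in module_rules
            for cid in r.criterion_ids
            for iid in criteria[cid].mapped_item_ids
        }
        missing = [i for i in needed if i not in responses and i not in skipped]
        if missing:
            incomplete.append(module.module_id)
            continue
        endorsements: dict[str, bool] = {}
        for r in module_rules:
            for cid in r.criterion_ids:
                if cid in endorsements:
                    continue
                c = criteria[cid]
                answered_ids = [i for i in c.mapped_item_ids if i in responses]
                supporting = [
                    i for i in answered_ids if to_endorsement(items[i], responses[i])
                ]
                endorsements[cid] = bool(supporting)
        for r in module_rules:
            if evaluate_diagnosis(r, endorsements):
                count = sum(endorsements[c] for c in r.criterion_ids)
                cardinal_ok = (
                    not r.cardinal_criterion_ids
                    or any(endorsements[c] for c in r.cardinal_criterion_ids)
                )
                included.append(IncludedDiagnosis(
                    diagnosis_name=r.diagnosis_name,
                    endorsed_criteria_count=count,
                    required_count=r.required_count,
                    cardinal_satisfied=cardinal_ok,
                    episode=r.episode,
                ))

    inventory = [
        SeverityEntry(
            item_id=r.item_id,
            value=r.value,
            reverse_scored=items[r.item_id].reverse_scored,
        )
        for r in session.responses
    ]
    return DifferentialReport(
        session_id=session.session_id,
        screen_status=screen_status,
        included_diagnoses=included,
        severity_inventory=inventory,
        incomplete_modules=incomplete,
    )


def module_summary_score(
    instr: Instrument,
    module_id: str,
    responses: Mapping[str, ResponseValue],
    symptom_tag: Optional[str] = None,
) -> int:
    """Sum of screener Likert levels (reverse items counted as 6 - value).

    With ``symptom_tag`` the sum runs over the tagged sub-scale only (e.g.
    hallucination items within the psychotic screener). Range is [k, 5k] for
    k contributing items. Raises ``UnsupportedModuleError`` for modules whose
    screener is not pure Likert (those take the kappa path instead) and
    ``IncompleteResponsesError`` for partial data.
    """
    module = instr.modules_by_id()[module_id]
    items = instr.items_by_id()
    selected = [items[i] for i in module.screener_item_ids]
    if any(it.response_kind is not ResponseKind.likert5 for it in selected):
        raise UnsupportedModuleError(
            f"module {module_id!r} screener is not pure Likert; "
            "use categorical (kappa) analysis"
        )
    if symptom_tag is not None:
        selected = [it for it in selected if it.symptom_tag == symptom_tag]
    missing = [it.item_id for it in selected if it.item_id not in responses]
    if missing:
        raise IncompleteResponsesError(missing, context=f"module {module_id!r} summary")
    return sum(likert_severity(it, responses[it.item_id]) for it in selected)


def build_rescreen_form(instr: Instrument, report: DifferentialReport) -> list[Item]:
    """Likert items mapped to the included diagnoses' criteria, deduplicated,
    in instrument order — the focused form for interval re-screening."""
    if not report.included_diagnoses:
        return []
    names = {d.diagnosis_name for d in report.included_diagnoses}
    criteria = instr.criteria_by_id()
    wanted: set[str] = set()
    for rule in instr.diagnosis_rules:
        if rule.diagnosis_name not in names:
            continue
        for cid in rule.criterion_ids:
            wanted.update(criteria[cid].mapped_item_ids)
    return [
        it for it in instr.items
        if it.item_id in wanted and it.response_kind is ResponseKind.likert5
    ]
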