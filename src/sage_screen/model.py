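"""Declarative instrument data model: items, screener modules, threshold rules,
diagnostic criteria, and diagnosis rules, plus the on-disk JSON format.

An *instrument* is a versioned, self-contained description of an adaptive
diagnostic screening questionnaire. The administration engine and the scorer
are pure interpreters of this document: all branching thresholds, criterion
mappings, and symptom-count rules live here as data, never in code.

Response kinds
--------------
``likert5``
    Five ordered frequency levels: 1 never, 2 rarely, 3 sometimes, 4 often,
    5 always. Items may be reverse-scored (low frequency indicates the
    symptom, e.g. "I enjoyed life").
``yes_no``
    Boolean screeners (e.g. lifetime panic attack, past-30-day substance use,
    trauma exposure).
``count_days``
    Integer day counts within the item's timeframe (e.g. days drinking
    alcohol in the last 30 days).
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Annotated, Literal, Mapping, Optional, Union

import pydantic
from pydantic import BaseModel, Field, PositiveInt, model_validator

from .errors import InstrumentParseError, InstrumentValidationError

SCHEMA_VERSION = "1.0"

#: Canonical wording of the five Likert frequency levels.
LIKERT_LABELS = {1: "never", 2: "rarely", 3: "sometimes", 4: "often", 5: "always"}

#: Symbolic aliases usable wherever a Likert level is expected.
NEVER, RARELY, SOMETIMES, OFTEN, ALWAYS = 1, 2, 3, 4, 5

#: A raw response value: a Likert level or day count (int) or a yes/no answer.
ResponseValue = Union[bool, int]


class ResponseKind(str, Enum):
    likert5 = "likert5"
    yes_no = "yes_no"
    count_days = "count_days"


class Section(str, Enum):
    screener = "screener"
    followup = "followup"


class Item(BaseModel):
    """One self-report question.

    ``gate_item_ids`` expresses screener-internal branching: the item is only
    administered once at least one of the gate items has been answered "yes"
    (used for trauma-exposure gating of PTSD symptom screeners). ``count_cut``
    is the documented endorsement cut for ``count_days`` items.
    """

    item_id: str
    text: str
    module_id: str
    section: Section
    response_kind: ResponseKind
    reverse_scored: bool = False
    timeframe_days: PositiveInt = 30
    symptom_tag: Optional[str] = None
    lead_prompt: Optional[str] = None
    gate_item_ids: list[str] = Field(default_factory=list)
    count_cut: Optional[int] = None

    @model_validator(mode="after")
    def _check_kind_constraints(self) -> "Item":
        if self.reverse_scored and self.response_kind is not ResponseKind.likert5:
            raise ValueError(
                f"item {self.item_id!r}: reverse_scored is only valid for likert5 items"
            )
        if self.count_cut is not None:
            if self.response_kind is not ResponseKind.count_days:
                raise ValueError(
                    f"item {self.item_id!r}: count_cut is only valid for count_days items"
                )
            if not (0 <= self.count_cut <= self.timeframe_days):
                raise ValueError(
                    f"item {self.item_id!r}: count_cut must lie in 0..timeframe_days"
                )
        return self

    def validate_value(self, value: ResponseValue) -> None:
        """Raise ``ResponseRangeError`` unless ``value`` fits this item."""
        from .errors import ResponseRangeError

        kind = self.response_kind
        if kind is ResponseKind.likert5:
            if isinstance(value, bool) or not isinstance(value, int) or not 1 <= value <= 5:
                raise ResponseRangeError(
                    f"item {self.item_id!r} expects a Likert level 1..5, got {value!r}"
                )
        elif kind is ResponseKind.yes_no:
            if not isinstance(value, bool):
                raise ResponseRangeError(
                    f"item {self.item_id!r} expects a yes/no (bool) answer, got {value!r}"
                )
        elif kind is ResponseKind.count_days:
            if isinstance(value, bool) or not isinstance(value, int):
                raise ResponseRangeError(
                    f"item {self.item_id!r} expects an integer day count, got {value!r}"
                )
            if not 0 <= value <= self.timeframe_days:
                raise ResponseRangeError(
                    f"item {self.item_id!r} expects a count in 0..{self.timeframe_days}, "
                    f"got {value!r}"
                )


class RuleAtom(BaseModel):
    """A single comparison against one item's response.

    ``ge``/``le`` compare Likert levels or day counts; ``eq`` with a boolean
    level matches yes/no answers.
    """

    kind: Literal["atom"] = "atom"
    item_id: str
    comparator: Literal["ge", "le", "eq"]
    level: ResponseValue


class RuleGroup(BaseModel):
    """A monotone connective over sub-rules: any-of, all-of, or at-least-k."""

    kind: Literal["any", "all", "at_least"]
    k: Optional[int] = None
    clauses: list["ThresholdRule"]

    @model_validator(mode="after")
    def _check_k(self) -> "RuleGroup":
        if self.kind == "at_least":
            if self.k is None or not 1 <= self.k <= len(self.clauses):
                raise ValueError("at_least rule requires 1 <= k <= len(clauses)")
        return self


ThresholdRule = Annotated[Union[RuleAtom, RuleGroup], Field(discriminator="kind")]
RuleGroup.model_rebuild()


def _atom_holds(atom: RuleAtom, value: ResponseValue) -> bool:
    if atom.comparator == "ge":
        return value >= atom.level
    if atom.comparator == "le":
        return value <= atom.level
    return value == atom.level


def rule_item_ids(rule: ThresholdRule) -> list[str]:
    """All item ids referenced by ``rule``, in clause order (with repeats removed)."""
    out: list[str] = []

    def walk(node):
        if isinstance(node, RuleAtom):
            if node.item_id not in out:
                out.append(node.item_id)
        else:
            for c in node.clauses:
                walk(c)

    walk(rule)
    return out


def evaluate_rule(
    rule: ThresholdRule,
    responses: Mapping[str, ResponseValue],
    absent_false: frozenset[str] | set[str] = frozenset(),
) -> bool:
    """Evaluate a threshold rule over a complete response mapping.

    Items in ``absent_false`` (e.g. gated screeners that were legitimately
    skipped) evaluate atoms to False; any other missing item raises
    ``IncompleteResponsesError`` so partial data is never silently scored.
    """
    from .errors import IncompleteResponsesError

    missing = [
        i for i in rule_item_ids(rule) if i not in responses and i not in absent_false
    ]
    if missing:
        raise IncompleteResponsesError(missing, context="threshold rule")

    def ev(node) -> bool:
        if isinstance(node, RuleAtom):
            if node.item_id not in responses:
                return False
            return _atom_holds(node, responses[node.item_id])
        results = [ev(c) for c in node.clauses]
        if node.kind == "any":
            return any(results)
        if node.kind == "all":
            return all(results)
        return sum(results) >= node.k

    return ev(rule)


def satisfied_atoms(
    rule: ThresholdRule, responses: Mapping[str, ResponseValue]
) -> list[str]:
    """Item ids of atoms that individually hold under ``responses``.

    Used by the screening-consistency diagnostic to find which screener item
    was responsible for a threshold crossing; missing items count as
    unsatisfied.
    """
    out: list[str] = []

    def walk(node):
        if isinstance(node, RuleAtom):
            if node.item_id in responses and _atom_holds(node, responses[node.item_id]):
                if node.item_id not in out:
                    out.append(node.item_id)
        else:
            for c in node.clauses:
                walk(c)

    walk(rule)
    return out


class ScreenerModule(BaseModel):
    """One diagnostic category's screener block and its follow-up section."""

    module_id: str
    category_name: str
    screener_item_ids: list[str]
    screen_in_rule: ThresholdRule
    followup_item_ids: list[str] = Field(default_factory=list)
    #: Transform applied to the module summary score before reliability analysis.
    summary_transform: Literal["none", "log"] = "none"
    #: Symptom tags that define reliability sub-scales (e.g. hallucinations,
    #: delusions within the psychotic-disorders screener).
    subscale_tags: list[str] = Field(default_factory=list)


class CriterionDef(BaseModel):
    """A diagnosis-agnostic DSM symptom criterion mapped onto one or more items.

    The criterion is endorsed when any mapped item is endorsed under the
    Stage-II endorsement mapping (often/always forward, never/rarely reverse).
    """

    criterion_id: str
    label: str
    mapped_item_ids: list[str] = Field(min_length=1)
    cardinal: bool = False


class DiagnosisRule(BaseModel):
    """Symptom-count rule: at least ``required_count`` of ``criterion_ids``
    endorsed, with at least one endorsed from ``cardinal_criterion_ids`` when
    that subset is nonempty.

    ``window_days`` records the DSM concurrency window (metadata: concurrency
    is realized by lead-prompt anchoring, not date arithmetic). ``notes``
    holds clinician-judgment components (exclusions, "not better explained
    by…") that are deliberately never machine-evaluated.
    """

    diagnosis_name: str
    criterion_ids: list[str] = Field(min_length=1)
    required_count: int
    cardinal_criterion_ids: list[str] = Field(default_factory=list)
    window_days: PositiveInt = 14
    notes: str = ""
    episode: bool = False

    @model_validator(mode="after")
    def _check_counts(self) -> "DiagnosisRule":
        n = len(self.criterion_ids)
        if not 1 <= self.required_count <= n:
            raise ValueError(
                f"rule {self.diagnosis_name!r}: required_count must lie in 1..{n}"
            )
        extra = set(self.cardinal_criterion_ids) - set(self.criterion_ids)
        if extra:
            raise ValueError(
                f"rule {self.diagnosis_name!r}: cardinal criteria {sorted(extra)} "
                "are not in criterion_ids"
            )
        return self


class Instrument(BaseModel):
    """A complete, versioned instrument definition.

    ``catalog`` lists the disorders the instrument can return in a
    differential; current-episode rules (major depressive, manic, hypomanic
    episode) are additionally carried in ``diagnosis_rules`` with
    ``episode=True`` and reported alongside catalog disorders.
    """

    schema_version: str = SCHEMA_VERSION
    name: str = "instrument"
    items: list[Item]
    modules: list[ScreenerModule]
    criteria: list[CriterionDef] = Field(default_factory=list)
    diagnosis_rules: list[DiagnosisRule] = Field(default_factory=list)
    catalog: list[str] = Field(default_factory=list)

    # -- lookup helpers ----------------------------------------------------
    def items_by_id(self) -> dict[str, Item]:
        return {i.item_id: i for i in self.items}

    def modules_by_id(self) -> dict[str, ScreenerModule]:
        return {m.module_id: m for m in self.modules}

    def criteria_by_id(self) -> dict[str, CriterionDef]:
        return {c.criterion_id: c for c in self.criteria}

    def screener_items(self) -> list[Item]:
        return [i for i in self.items if i.section is Section.screener]

    def module_of_rule(self, rule: DiagnosisRule) -> Optional[str]:
        """Module id owning a diagnosis rule (via its criteria's items), or
        None if the rule's items span modules."""
        crit = self.criteria_by_id()
        items = self.items_by_id()
        mods = set()
        for cid in rule.criterion_ids:
            c = crit.get(cid)
            if c is None:
                return None
            for iid in c.mapped_item_ids:
                it = items.get(iid)
                if it is None:
                    return None
                mods.add(it.module_id)
        return mods.pop() if len(mods) == 1 else None


# ---------------------------------------------------------------------------
# Validation


def validate_instrument(instr: Instrument) -> list[str]:
    """Check every cross-reference and structural invariant.

    Returns a list of human-readable issues (empty iff the instrument is
    valid); each issue names the offending entity. Never raises.
    """
    issues: list[str] = []
    items = {}
    for it in instr.items:
        if it.item_id in items:
            issues.append(f"duplicate item_id {it.item_id!r}")
        items[it.item_id] = it
    modules = {}
    for m in instr.modules:
        if m.module_id in modules:
            issues.append(f"duplicate module_id {m.module_id!r}")
        modules[m.module_id] = m
    criteria = {}
    for c in instr.criteria:
        if c.criterion_id in criteria:
            issues.append(f"duplicate criterion_id {c.criterion_id!r}")
        criteria[c.criterion_id] = c

    seen_screener: dict[str, str] = {}
    for m in instr.modules:
        if not m.screener_item_ids:
            issues.append(f"module {m.module_id!r} has no screener items")
        for iid in m.screener_item_ids + m.followup_item_ids:
            it = items.get(iid)
            if it is None:
                issues.append(f"module {m.module_id!r} references missing item {iid!r}")
                continue
            if it.module_id != m.module_id:
                issues.append(
                    f"item {iid!r} listed in module {m.module_id!r} but declares "
                    f"module_id {it.module_id!r}"
                )
        for iid in m.screener_item_ids:
            if iid in seen_screener:
                issues.append(
                    f"screener item {iid!r} belongs to both modules "
                    f"{seen_screener[iid]!r} and {m.module_id!r}"
                )
            seen_screener[iid] = m.module_id
            it = items.get(iid)
            if it is not None and it.section is not Section.screener:
                issues.append(f"item {iid!r} in screener list but section={it.section.value}")
        for iid in m.followup_item_ids:
            it = items.get(iid)
            if it is not None and it.section is not Section.followup:
                issues.append(f"item {iid!r} in followup list but section={it.section.value}")
        for iid in rule_item_ids(m.screen_in_rule):
            if iid not in items:
                issues.append(
                    f"screen-in rule of module {m.module_id!r} references missing "
                    f"item {iid!r}"
                )
            elif iid not in m.screener_item_ids:
                issues.append(
                    f"screen-in rule of module {m.module_id!r} references "
                    f"non-screener item {iid!r}"
                )

    listed = {iid for m in instr.modules for iid in m.screener_item_ids + m.followup_item_ids}
    for it in instr.items:
        if it.module_id not in modules:
            issues.append(f"item {it.item_id!r} references missing module {it.module_id!r}")
        if it.item_id not in listed:
            issues.append(f"item {it.item_id!r} is not listed by any module")
        for gid in it.gate_item_ids:
            g = items.get(gid)
            if g is None:
                issues.append(f"item {it.item_id!r} gated on missing item {gid!r}")
            elif g.response_kind is not ResponseKind.yes_no:
                issues.append(f"item {it.item_id!r} gated on non-yes/no item {gid!r}")

    for c in instr.criteria:
        for iid in c.mapped_item_ids:
            if iid not in items:
                issues.append(
                    f"criterion {c.criterion_id!r} references missing item {iid!r}"
                )

    catalog = set(instr.catalog)
    if len(catalog) != len(instr.catalog):
        issues.append("catalog contains duplicate diagnosis names")
    for r in instr.diagnosis_rules:
        for cid in r.criterion_ids:
            if cid not in criteria:
                issues.append(
                    f"diagnosis rule {r.diagnosis_name!r} references missing "
                    f"criterion {cid!r}"
                )
        if not r.episode and r.diagnosis_name not in catalog:
            issues.append(
                f"diagnosis rule {r.diagnosis_name!r} is not in the catalog and not "
                "flagged as an episode"
            )
    return issues


# ---------------------------------------------------------------------------
# On-disk format (JSON, sorted keys, schema_version mandatory)


def save_instrument(instr: Instrument, path: str | Path) -> None:
    """Write an instrument as pretty-printed, key-sorted JSON."""
    doc = instr.model_dump(mode="json")
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_instrument(path: str | Path) -> Instrument:
    """Load and fully validate an instrument file.

    Raises ``InstrumentParseError`` for malformed documents and
    ``InstrumentValidationError`` (listing every issue) for well-formed
    documents that break referential integrity.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InstrumentParseError(f"cannot parse instrument file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise InstrumentParseError(f"{path}: missing mandatory schema_version field")
    try:
        instr = Instrument.model_validate(doc)
    except pydantic.ValidationError as exc:
        raise InstrumentParseError(f"{path}: {exc}") from exc
    issues = validate_instrument(instr)
    if issues:
        raise InstrumentValidationError(issues)
    return instr
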