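"""Endorsement mapping, criterion and diagnosis-rule evaluation against
enumeration oracles, differential reports, and summary scores."""

import itertools

import numpy as np
import pytest

from sage_screen import (
    IncompleteResponsesError,
    UnsupportedModuleError,
    build_differential,
    build_rescreen_form,
    evaluate_criterion,
    evaluate_diagnosis,
    evaluate_screen_in,
    module_summary_score,
    replay_script,
    to_endorsement,
)
from sage_screen.model import Instrument, Item, ResponseKind, RuleAtom, ScreenerModule

from conftest import make_toy_instrument


def brute_force_accept_set(rule):
    """Enumeration oracle: all endorsement vectors the symptom-count +
    cardinal rule accepts, computed directly from its definition."""
    accepted = []
    n = len(rule.criterion_ids)
    cardinal_idx = [rule.criterion_ids.index(c) for c in rule.cardinal_criterion_ids]
    for bits in itertools.product([False, True], repeat=n):
        ok = sum(bits) >= rule.required_count
        if ok and cardinal_idx:
            ok = any(bits[i] for i in cardinal_idx)
        if ok:
            accepted.append(bits)
    return accepted


class TestEndorsementMapping:
    @pytest.mark.parametrize("reverse,expected", [
        (False, {1: False, 2: False, 3: False, 4: True, 5: True}),
        (True, {1: True, 2: True, 3: False, 4: False, 5: False}),
    ])
    def test_exhaustive_over_levels_and_polarities(self, reverse, expected):
        """Forward items endorse at often/always; reverse at never/rarely."""
        item = Item(item_id="x", text="x", module_id="m", section="screener",
                    response_kind="likert5", reverse_scored=reverse)
        assert {v: to_endorsement(item, v) for v in range(1, 6)} == expected

    def test_yes_no_and_count_cut(self, fixture_instrument):
        items = fixture_instrument.items_by_id()
        assert to_endorsement(items["panic_scr_attack"], True) is True
        assert to_endorsement(items["panic_scr_attack"], False) is False
        assert to_endorsement(items["alcohol_scr_days"], 5) is True
        assert to_endorsement(items["alcohol_scr_days"], 4) is False


class TestCriterionEvaluation:
    def test_depressed_mood_always_gives_level_five(self, fixture_instrument):
        crit = fixture_instrument.criteria_by_id()["dep_depressed_mood"]
        responses = {"dep_scr_felt_sad": 1, "dep_scr_felt_depressed": 5,
                     "dep_scr_felt_hopeless": 1}
        e = evaluate_criterion(crit, fixture_instrument, responses)
        assert e.endorsed and e.max_frequency_level == 5
        assert e.supporting_item_ids == ["dep_scr_felt_depressed"]

    def test_all_never_not_endorsed_level_one(self, fixture_instrument):
        crit = fixture_instrument.criteria_by_id()["dep_depressed_mood"]
        e = evaluate_criterion(crit, fixture_instrument,
                               {i: 1 for i in crit.mapped_item_ids})
        assert not e.endorsed and e.max_frequency_level == 1
        assert e.supporting_item_ids == []

    def test_reverse_item_contributes_mirrored_level(self, fixture_instrument):
        crit = fixture_instrument.criteria_by_id()["dep_anhedonia"]
        responses = {"dep_scr_enjoyed_life": 2, "dep_scr_difficulty_enjoying": 1,
                     "dep_scr_interested_usual": 5}
        e = evaluate_criterion(crit, fixture_instrument, responses)
        assert e.endorsed and e.supporting_item_ids == ["dep_scr_enjoyed_life"]
        assert e.max_frequency_level == 4  # 6 - 2

    def test_incomplete_mapped_items_raise(self, fixture_instrument):
        crit = fixture_instrument.criteria_by_id()["dep_depressed_mood"]
        with pytest.raises(IncompleteResponsesError):
            evaluate_criterion(crit, fixture_instrument, {"dep_scr_felt_sad": 4})


class TestDiagnosisRule:
    def test_five_with_cardinal_accepts(self, fixture_instrument):
        rule = next(r for r in fixture_instrument.diagnosis_rules
                    if r.diagnosis_name == "major depressive episode")
        e = {c: False for c in rule.criterion_ids}
        for c in ["dep_depressed_mood", "dep_sleep", "dep_appetite", "dep_fatigue",
                  "dep_concentration"]:
            e[c] = True
        assert evaluate_diagnosis(rule, e) is True

    def test_five_without_cardinal_rejects(self, fixture_instrument):
        rule = next(r for r in fixture_instrument.diagnosis_rules
                    if r.diagnosis_name == "major depressive episode")
        e = {c: False for c in rule.criterion_ids}
        for c in ["dep_sleep", "dep_appetite", "dep_fatigue", "dep_concentration",
                  "dep_psychomotor"]:
            e[c] = True
        assert evaluate_diagnosis(rule, e) is False

    def test_depression_brute_force_512_vectors(self, fixture_instrument):
        """227 of the 512 endorsement vectors are accepted (256 with count
        >= 5, minus the 29 reaching 5 from non-cardinal criteria alone), and
        the engine agrees with the oracle on every vector."""
        rule = next(r for r in fixture_instrument.diagnosis_rules
                    if r.diagnosis_name == "major depressive episode")
        oracle = brute_force_accept_set(rule)
        assert len(oracle) == 227
        assert min(sum(bits) for bits in oracle) == 5
        for bits in itertools.product([False, True], repeat=9):
            expected = bits in set(oracle)
            assert evaluate_diagnosis(
                rule, dict(zip(rule.criterion_ids, bits))) == expected

    def test_engine_matches_oracle_on_every_fixture_rule(self, fixture_instrument):
        for rule in fixture_instrument.diagnosis_rules:
            oracle = set(brute_force_accept_set(rule))
            for bits in itertools.product([False, True],
                                          repeat=len(rule.criterion_ids)):
                got = evaluate_diagnosis(rule, dict(zip(rule.criterion_ids, bits)))
                assert got == (bits in oracle), (rule.diagnosis_name, bits)

    def test_adding_endorsement_never_removes_diagnosis(self, fixture_instrument):
        """Monotonicity of the symptom-count rules."""
        rng = np.random.default_rng(11)
        for rule in fixture_instrument.diagnosis_rules:
            n = len(rule.criterion_ids)
            for _ in range(50):
                bits = rng.random(n) < 0.5
                e = dict(zip(rule.criterion_ids, bits))
                if not evaluate_diagnosis(rule, e):
                    continue
                j = int(rng.integers(n))
                e[rule.criterion_ids[j]] = True
                assert evaluate_diagnosis(rule, e)


class TestDifferentialReport:
    def test_all_never_session_empty_differential(self, fixture_instrument,
                                                  all_never_script):
        session = replay_script(fixture_instrument, all_never_script)
        report = build_differential(fixture_instrument, session)
        assert report.included_diagnoses == []
        assert set(report.screen_status.values()) == {"out"}
        assert report.incomplete_modules == []
        assert len(report.severity_inventory) == len(session.responses)

    def test_depressed_respondent_script(self, fixture_instrument,
                                         all_never_script):
        """A hand-constructed depressed respondent: 7 of 9 criteria endorsed
        including both cardinals -> major depressive episode included."""
        script = dict(all_never_script)
        script.update({
            "dep_scr_felt_sad": 4, "dep_scr_felt_depressed": 5,
            "dep_scr_felt_hopeless": 3, "dep_scr_enjoyed_life": 2,
            "dep_scr_difficulty_enjoying": 4, "dep_scr_interested_usual": 2,
            "dep_fu_sleep": 4, "dep_fu_appetite": 4, "dep_fu_fatigue": 5,
            "dep_fu_worthless": 4, "dep_fu_concentrate": 4,
            "dep_fu_psychomotor": 1, "dep_fu_death": 1,
        })
        session = replay_script(fixture_instrument, script)
        report = build_differential(fixture_instrument, session)
        names = {d.diagnosis_name for d in report.included_diagnoses}
        assert "major depressive episode" in names
        mde = next(d for d in report.included_diagnoses
                   if d.diagnosis_name == "major depressive episode")
        assert mde.endorsed_criteria_count == 7 and mde.required_count == 5
        assert mde.cardinal_satisfied and mde.episode

    def test_screened_in_subthreshold_followups_no_diagnosis(self,
                                                             fixture_instrument,
                                                             all_never_script):
        """Screen-in at 'sometimes' without any item at 'often' yields a
        screened-in module but an empty differential (sensitive screen,
        specific diagnosis)."""
        script = dict(all_never_script)
        script["gad_scr_worry"] = 3
        for iid in fixture_instrument.modules_by_id()["gad"].followup_item_ids:
            script[iid] = 3
        session = replay_script(fixture_instrument, script)
        report = build_differential(fixture_instrument, session)
        assert report.screen_status["gad"] == "in"
        assert report.included_diagnoses == []
        assert report.incomplete_modules == []

    def test_partial_module_reported_incomplete_not_scored(self,
                                                           fixture_instrument,
                                                           all_never_script):
        from sage_screen import Response, next_items, record_response, start_session

        script = dict(all_never_script)
        script["dep_scr_felt_depressed"] = 5
        session = start_session(fixture_instrument)
        while session.phase == "screener":
            item = next_items(fixture_instrument, session)[0]
            record_response(fixture_instrument, session,
                            Response(item_id=item.item_id, value=script[item.item_id]))
        # answer only part of the depression follow-up section
        record_response(fixture_instrument, session,
                        Response(item_id="dep_fu_sleep", value=5))
        report = build_differential(fixture_instrument, session)
        assert report.screen_status["dep"] == "in"
        assert report.incomplete_modules == ["dep"]
        assert report.included_diagnoses == []


class TestScreenDiagnoseConsistency:
    def test_meeting_any_diagnosis_implies_screening_in(self, fixture_instrument):
        """Simulation over random complete response vectors: every respondent
        whose follow-ups meet a module's diagnosis rule would also have
        screened in (the sensitive-screen / specific-diagnose ordering)."""
        rng = np.random.default_rng(2024)
        items = fixture_instrument.items_by_id()
        criteria = fixture_instrument.criteria_by_id()
        checked = 0
        for module in fixture_instrument.modules:
            rules = [r for r in fixture_instrument.diagnosis_rules
                     if fixture_instrument.module_of_rule(r) == module.module_id]
            module_items = [items[i] for i in
                            module.screener_item_ids + module.followup_item_ids]
            for _ in range(800):
                responses = {}
                for it in module_items:
                    if it.response_kind is ResponseKind.likert5:
                        responses[it.item_id] = int(rng.integers(1, 6))
                    elif it.response_kind is ResponseKind.yes_no:
                        responses[it.item_id] = bool(rng.random() < 0.5)
                    else:
                        responses[it.item_id] = int(
                            rng.integers(0, it.timeframe_days + 1))
                endorse = {
                    cid: any(to_endorsement(items[i], responses[i])
                             for i in criteria[cid].mapped_item_ids)
                    for r in rules for cid in r.criterion_ids
                }
                if any(evaluate_diagnosis(r, endorse) for r in rules):
                    assert evaluate_screen_in(fixture_instrument,
                                              module.module_id, responses)
                checked += 1
        assert checked >= 10_000


class TestSummaryScore:
    def test_floor_is_item_count(self, fixture_instrument):
        ids = fixture_instrument.modules_by_id()["gad"].screener_item_ids
        assert module_summary_score(fixture_instrument, "gad",
                                    {i: 1 for i in ids}) == len(ids)

    def test_ceiling_with_reverse_items(self, fixture_instrument):
        responses = {"dep_scr_felt_sad": 5, "dep_scr_felt_depressed": 5,
                     "dep_scr_felt_hopeless": 5, "dep_scr_enjoyed_life": 1,
                     "dep_scr_difficulty_enjoying": 5, "dep_scr_interested_usual": 1}
        assert module_summary_score(fixture_instrument, "dep", responses) == 30

    def test_mixed_levels_with_reverse_item(self):
        """Three forward items at 2, 3, 4 plus one reverse item at 2:
        2 + 3 + 4 + (6 - 2) = 13."""
        toy = make_toy_instrument(4, reverse_last=True)
        responses = {"toy_scr_0": 2, "toy_scr_1": 3, "toy_scr_2": 4, "toy_scr_3": 2}
        assert module_summary_score(toy, "toy", responses) == 13

    def test_subscale_tag_restricts_items(self, fixture_instrument):
        ids = fixture_instrument.modules_by_id()["psych"].screener_item_ids
        responses = {i: 1 for i in ids}
        responses["psych_scr_voices"] = 5
        full = module_summary_score(fixture_instrument, "psych", responses)
        hall = module_summary_score(fixture_instrument, "psych", responses,
                                    symptom_tag="hallucination")
        assert full == 14 and hall == 9

    def test_non_likert_module_unsupported(self, fixture_instrument):
        with pytest.raises(UnsupportedModuleError):
            module_summary_score(fixture_instrument, "panic",
                                 {"panic_scr_attack": True})

    def test_incomplete_raises(self, fixture_instrument):
        with pytest.raises(IncompleteResponsesError):
            module_summary_score(fixture_instrument, "gad", {"gad_scr_worry": 3})


class TestRescreenForm:
    def test_included_diagnoses_items_only_and_deduplicated(self,
                                                            fixture_instrument,
                                                            all_never_script):
        script = dict(all_never_script)
        script.update({
            "dep_scr_felt_sad": 5, "dep_scr_felt_depressed": 5,
            "dep_scr_felt_hopeless": 5, "dep_scr_enjoyed_life": 1,
            "dep_scr_difficulty_enjoying": 5, "dep_scr_interested_usual": 1,
            "dep_fu_sleep": 5, "dep_fu_appetite": 5, "dep_fu_fatigue": 5,
            "dep_fu_worthless": 5, "dep_fu_concentrate": 5,
            "dep_fu_psychomotor": 5, "dep_fu_death": 5,
        })
        session = replay_script(fixture_instrument, script)
        report = build_differential(fixture_instrument, session)
        # MDE + MDD + persistent depressive all share depression items
        assert len(report.included_diagnoses) >= 2
        form = build_rescreen_form(fixture_instrument, report)
        ids = [i.item_id for i in form]
        assert len(ids) == len(set(ids))
        assert set(ids) == {i for i in ids if i.startswith("dep_")}
        order = [i.item_id for i in fixture_instrument.items]
        assert ids == sorted(ids, key=order.index)

    def test_empty_differential_empty_form(self, fixture_instrument,
                                           all_never_script):
        session = replay_script(fixture_instrument, all_never_script)
        report = build_differential(fixture_instrument, session)
        assert build_rescreen_form(fixture_instrument, report) == []
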