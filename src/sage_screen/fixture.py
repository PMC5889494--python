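"""The packaged fixture instrument.

Reproduces the published structure of the SAGE-SR screener: a 65-item
screener over 13 diagnostic categories, threshold-gated branching into
follow-up sections, Stage-II endorsement-based criterion scoring, and a
28-disorder catalog (plus the three current-episode rules reported in the
differential).

Published content used verbatim: the six depression screener items (three
depressed-mood, three loss-of-interest with two reverse-coded), the raised
"often" threshold for "I felt sad", the four PTSD trauma-exposure yes/no
screeners, the panic-attack / past-30-day-use / days-drinking screeners, and
two psychotic-domain items retained during cognitive interviewing. All other
item texts are authored here from DSM-5 symptom labels in the same style
(single concept, no idioms, simple syntax) and are NOT the instrument's
unpublished item pool; see docs/methods.md.

Fixture threshold conventions (declared assumptions, configurable by editing
the produced instrument document):

* screen-in is sensitive: any screener item at >= "sometimes" (reverse items
  <= "sometimes"), except "I felt sad" which requires >= "often";
* diagnosis is specific: criteria endorse only at >= "often" (reverse
  <= "rarely") via the endorsement mapping;
* the alcohol screener screens in at >= 5 drinking days in 30 (also its
  documented endorsement cut);
* every diagnosis rule's cardinal criteria map only to screener items, so
  meeting a diagnosis from follow-ups implies having screened in.
"""

from __future__ import annotations

from .model import (
    OFTEN,
    RARELY,
    SOMETIMES,
    CriterionDef,
    DiagnosisRule,
    Instrument,
    Item,
    RuleAtom,
    RuleGroup,
    ScreenerModule,
)

FIXTURE_NAME = "sage-sr-structural-fixture"

# The 13 diagnostic categories, in presentation (and reliability-table) order.
CATEGORIES = [
    ("dep", "Depressive disorders"),
    ("mania", "Manic and hypomanic disorders"),
    ("gad", "Generalized anxiety disorder"),
    ("panic", "Panic disorder"),
    ("agora", "Agoraphobia"),
    ("social", "Social anxiety disorder"),
    ("ocd", "Obsessive-compulsive disorder"),
    ("ptsd", "Posttraumatic stress disorder"),
    ("adhd", "Adult attention-deficit/hyperactivity disorder"),
    ("psych", "Psychotic disorders"),
    ("alcohol", "Alcohol use disorder"),
    ("cannabis", "Cannabis use disorder"),
    ("othersub", "Other substance use disorders"),
]

# The 28 disorders returned in the differential (episodes are rule-level
# outputs, not catalog entries).
DIAGNOSIS_CATALOG = [
    "persistent depressive disorder",
    "major depressive disorder",
    "other specified depressive disorder",
    "bipolar I disorder",
    "bipolar II disorder",
    "other specified bipolar disorder",
    "panic disorder",
    "agoraphobia",
    "social anxiety disorder",
    "generalized anxiety disorder",
    "obsessive-compulsive disorder",
    "posttraumatic stress disorder",
    "attention-deficit/hyperactivity disorder",
    "schizophrenia",
    "schizophreniform disorder",
    "schizoaffective disorder",
    "delusional disorder",
    "brief psychotic disorder",
    "other specified psychotic disorder",
    "alcohol use disorder",
    "cannabis use disorder",
    "inhalant use disorder",
    "other hallucinogen use disorder",
    "opioid use disorder",
    "phencyclidine use disorder",
    "sedative, hypnotic, or anxiolytic use disorder",
    "stimulant use disorder",
    "other or unknown substance use disorder",
]

# The 11 DSM-5 substance-use-disorder symptom criteria, reused for alcohol,
# cannabis, and other substances with substance-appropriate wording.
_SUD_SYMPTOMS = [
    ("larger", "I used {s} more than I intended"),
    ("cut_down", "I tried to cut down on {s} but could not"),
    ("time_spent", "I spent a lot of time using {s} or recovering from it"),
    ("craving", "I craved {s}"),
    ("obligations", "Using {s} kept me from meeting my obligations"),
    ("social", "I kept using {s} even though it caused problems with other people"),
    ("activities", "I gave up activities because of {s}"),
    ("hazard", "I used {s} in situations where it was dangerous"),
    ("physical", "I kept using {s} even though it made me feel bad"),
    ("tolerance", "I needed more {s} to get the same effect"),
    ("withdrawal", "I felt sick when I stopped using {s}"),
]


def _ge(item_id: str, level: int) -> RuleAtom:
    return RuleAtom(item_id=item_id, comparator="ge", level=level)


def _le(item_id: str, level: int) -> RuleAtom:
    return RuleAtom(item_id=item_id, comparator="le", level=level)


def _yes(item_id: str) -> RuleAtom:
    return RuleAtom(item_id=item_id, comparator="eq", level=True)


def build_fixture_instrument() -> Instrument:
    """Deterministically construct the packaged fixture instrument."""
    items: list[Item] = []
    modules: list[ScreenerModule] = []
    criteria: list[CriterionDef] = []
    rules: list[DiagnosisRule] = []

    def likert(iid, text, module, section, *, reverse=False, timeframe=30, tag=None,
               lead=None, gates=()):
        items.append(Item(
            item_id=iid, text=text, module_id=module, section=section,
            response_kind="likert5", reverse_scored=reverse,
            timeframe_days=timeframe, symptom_tag=tag, lead_prompt=lead,
            gate_item_ids=list(gates),
        ))
        return iid

    def yesno(iid, text, module, section, *, timeframe=30, tag=None, lead=None):
        items.append(Item(
            item_id=iid, text=text, module_id=module, section=section,
            response_kind="yes_no", timeframe_days=timeframe, symptom_tag=tag,
            lead_prompt=lead,
        ))
        return iid

    def crit(cid, label, mapped, *, cardinal=False):
        criteria.append(CriterionDef(
            criterion_id=cid, label=label, mapped_item_ids=mapped, cardinal=cardinal,
        ))
        return cid

    # -- depressive disorders ---------------------------------------------
    likert("dep_scr_felt_sad", "I felt sad", "dep", "screener", tag="depressed_mood")
    likert("dep_scr_felt_depressed", "I felt depressed", "dep", "screener",
           tag="depressed_mood")
    likert("dep_scr_felt_hopeless", "I felt hopeless", "dep", "screener",
           tag="depressed_mood")
    likert("dep_scr_enjoyed_life", "I enjoyed life", "dep", "screener",
           reverse=True, tag="anhedonia")
    likert("dep_scr_difficulty_enjoying",
           "I had difficulty enjoying things that I used to enjoy", "dep",
           "screener", tag="anhedonia")
    likert("dep_scr_interested_usual", "I was interested in my usual activities",
           "dep", "screener", reverse=True, tag="anhedonia")
    _dep_lead = "During the time(s) when I felt sad or down…"
    for iid, text in [
        ("dep_fu_sleep", "My sleeping was different than usual"),
        ("dep_fu_appetite", "My appetite was different than usual"),
        ("dep_fu_fatigue", "I felt tired"),
        ("dep_fu_worthless", "I felt worthless"),
        ("dep_fu_concentrate", "I had trouble concentrating"),
        ("dep_fu_psychomotor", "I moved or spoke more slowly than usual"),
        ("dep_fu_death", "I thought about death"),
    ]:
        likert(iid, text, "dep", "followup", timeframe=14, lead=_dep_lead)
    modules.append(ScreenerModule(
        module_id="dep", category_name="Depressive disorders",
        screener_item_ids=[
            "dep_scr_felt_sad", "dep_scr_felt_depressed", "dep_scr_felt_hopeless",
            "dep_scr_enjoyed_life", "dep_scr_difficulty_enjoying",
            "dep_scr_interested_usual",
        ],
        # "I felt sad" was overinclusive at "sometimes"; raised to "often".
        screen_in_rule=RuleGroup(kind="any", clauses=[
            _ge("dep_scr_felt_sad", OFTEN),
            _ge("dep_scr_felt_depressed", SOMETIMES),
            _ge("dep_scr_felt_hopeless", SOMETIMES),
            _le("dep_scr_enjoyed_life", SOMETIMES),
            _ge("dep_scr_difficulty_enjoying", SOMETIMES),
            _le("dep_scr_interested_usual", SOMETIMES),
        ]),
        followup_item_ids=[
            "dep_fu_sleep", "dep_fu_appetite", "dep_fu_fatigue", "dep_fu_worthless",
            "dep_fu_concentrate", "dep_fu_psychomotor", "dep_fu_death",
        ],
    ))
    crit("dep_depressed_mood", "depressed mood",
         ["dep_scr_felt_sad", "dep_scr_felt_depressed", "dep_scr_felt_hopeless"],
         cardinal=True)
    crit("dep_anhedonia", "loss of interest or pleasure",
         ["dep_scr_enjoyed_life", "dep_scr_difficulty_enjoying",
          "dep_scr_interested_usual"], cardinal=True)
    crit("dep_sleep", "sleep disturbance", ["dep_fu_sleep"])
    crit("dep_appetite", "appetite or weight change", ["dep_fu_appetite"])
    crit("dep_fatigue", "fatigue or loss of energy", ["dep_fu_fatigue"])
    crit("dep_worthlessness", "worthlessness or excessive guilt", ["dep_fu_worthless"])
    crit("dep_concentration", "diminished concentration", ["dep_fu_concentrate"])
    crit("dep_psychomotor", "psychomotor retardation or agitation",
         ["dep_fu_psychomotor"])
    crit("dep_suicidality", "recurrent thoughts of death", ["dep_fu_death"])
    _dep_criteria = [
        "dep_depressed_mood", "dep_anhedonia", "dep_sleep", "dep_appetite",
        "dep_fatigue", "dep_worthlessness", "dep_concentration",
        "dep_psychomotor", "dep_suicidality",
    ]
    rules.append(DiagnosisRule(
        diagnosis_name="major depressive episode",
        criterion_ids=_dep_criteria, required_count=5,
        cardinal_criterion_ids=["dep_depressed_mood", "dep_anhedonia"],
        window_days=14, episode=True,
        notes="Symptoms concurrent within the same 2-week period (lead-prompt "
              "anchored); change from previous functioning per clinician review.",
    ))
    rules.append(DiagnosisRule(
        diagnosis_name="major depressive disorder",
        criterion_ids=_dep_criteria, required_count=5,
        cardinal_criterion_ids=["dep_depressed_mood", "dep_anhedonia"],
        window_days=14,
        notes="Requires a major depressive episode not better explained by a "
              "psychotic disorder and no history of mania/hypomania (clinician "
              "judgment; not machine-evaluated).",
    ))
    rules.append(DiagnosisRule(
        diagnosis_name="persistent depressive disorder",
        criterion_ids=["dep_depressed_mood", "dep_appetite", "dep_sleep",
                       "dep_fatigue", "dep_worthlessness", "dep_concentration"],
        required_count=3, cardinal_criterion_ids=["dep_depressed_mood"],
        window_days=730,
        notes="2-year duration requirement assessed by clinician; screener "
              "timeframe is 30 days.",
    ))

    # -- manic and hypomanic disorders ------------------------------------
    for iid, text in [
        ("mania_scr_elevated", "I felt extremely happy"),
        ("mania_scr_irritable", "I felt irritable"),
        ("mania_scr_energy", "I had much more energy than usual"),
        ("mania_scr_sleep", "I needed less sleep than usual"),
        ("mania_scr_talkative", "I talked more than usual"),
        ("mania_scr_racing", "My thoughts raced"),
        ("mania_scr_confident", "I felt much more confident than usual"),
    ]:
        likert(iid, text, "mania", "screener")
    _mania_lead = "During the time(s) when I had much more energy than usual…"
    for iid, text in [
        ("mania_fu_distractible", "I was easily distracted"),
        ("mania_fu_goal", "I was much more active than usual"),
        ("mania_fu_risky", "I did risky things without thinking about what could happen"),
    ]:
        likert(iid, text, "mania", "followup", timeframe=7, lead=_mania_lead)
    modules.append(ScreenerModule(
        module_id="mania", category_name="Manic and hypomanic disorders",
        screener_item_ids=[
            "mania_scr_elevated", "mania_scr_irritable", "mania_scr_energy",
            "mania_scr_sleep", "mania_scr_talkative", "mania_scr_racing",
            "mania_scr_confident",
        ],
        screen_in_rule=RuleGroup(kind="any", clauses=[
            _ge(i, SOMETIMES) for i in [
                "mania_scr_elevated", "mania_scr_irritable", "mania_scr_energy",
                "mania_scr_sleep", "mania_scr_talkative", "mania_scr_racing",
                "mania_scr_confident"]
        ]),
        followup_item_ids=["mania_fu_distractible", "mania_fu_goal", "mania_fu_risky"],
    ))
    crit("mania_mood", "elevated, expansive, or irritable mood",
         ["mania_scr_elevated", "mania_scr_irritable"], cardinal=True)
    crit("mania_grandiosity", "inflated self-esteem or grandiosity",
         ["mania_scr_confident"])
    crit("mania_sleep", "decreased need for sleep", ["mania_scr_sleep"])
    crit("mania_talkative", "more talkative than usual", ["mania_scr_talkative"])
    crit("mania_racing", "flight of ideas or racing thoughts", ["mania_scr_racing"])
    crit("mania_distractibility", "distractibility", ["mania_fu_distractible"])
    crit("mania_goal_activity", "increase in goal-directed activity",
         ["mania_fu_goal", "mania_scr_energy"])
    crit("mania_risk", "excessive involvement in risky activities", ["mania_fu_risky"])
    _mania_criteria = ["mania_mood", "mania_grandiosity", "mania_sleep",
                       "mania_talkative", "mania_racing", "mania_distractibility",
                       "mania_goal_activity", "mania_risk"]
    rules.append(DiagnosisRule(
        diagnosis_name="manic episode", criterion_ids=_mania_criteria,
        required_count=4, cardinal_criterion_ids=["mania_mood"], window_days=7,
        episode=True,
        notes="Mood disturbance plus 3 or more associated symptoms for at least "
              "1 week; marked impairment per clinician.",
    ))
    rules.append(DiagnosisRule(
        diagnosis_name="hypomanic episode", criterion_ids=_mania_criteria,
        required_count=4, cardinal_criterion_ids=["mania_mood"], window_days=4,
        episode=True,
        notes="Same symptom set over at least 4 consecutive days without marked "
              "impairment (clinician judgment).",
    ))
    rules.append(DiagnosisRule(
        diagnosis_name="bipolar I disorder", criterion_ids=_mania_criteria,
        required_count=4, cardinal_criterion_ids=["mania_mood"], window_days=7,
        notes="Requires at least one manic episode; past-episode history is not "
              "collected by this instrument version.",
    ))
    rules.append(DiagnosisRule(
        diagnosis_name="bipolar II disorder", criterion_ids=_mania_criteria,
        required_count=4, cardinal_criterion_ids=["mania_mood"], window_days=4,
        notes="Requires a hypomanic episode plus a lifetime major depressive "
              "episode; past-episode history is not collected.",
    ))

    # -- generalized anxiety disorder -------------------------------------
    _gad_tf = 180  # DSM window: more days than not for 6 months
    for iid, text in [
        ("gad_scr_anxiety", "I had anxiety"),
        ("gad_scr_worry", "I worried about many different things"),
        ("gad_scr_control", "I had trouble controlling my worry"),
        ("gad_scr_restless", "I felt restless"),
        ("gad_scr_tense", "My muscles felt tense"),
        ("gad_scr_edge", "I felt on edge"),
    ]:
        likert(iid, text, "gad", "screener", timeframe=_gad_tf)
    _gad_lead = "During the time(s) when I felt anxious…"
    for iid, text in [
        ("gad_fu_fatigue", "I got tired easily"),
        ("gad_fu_blank", "My mind went blank"),
        ("gad_fu_sleep", "I had trouble falling asleep"),
        ("gad_fu_irritable", "I was easily annoyed"),
    ]:
        likert(iid, text, "gad", "followup", timeframe=_gad_tf, lead=_gad_lead)
    modules.append(ScreenerModule(
        module_id="gad", category_name="Generalized anxiety disorder",
        screener_item_ids=["gad_scr_anxiety", "gad_scr_worry", "gad_scr_control",
                           "gad_scr_restless", "gad_scr_tense", "gad_scr_edge"],
        screen_in_rule=RuleGroup(kind="any", clauses=[
            _ge(i, SOMETIMES) for i in
            ["gad_scr_anxiety", "gad_scr_worry", "gad_scr_control",
             "gad_scr_restless", "gad_scr_tense", "gad_scr_edge"]
        ]),
        followup_item_ids=["gad_fu_fatigue", "gad_fu_blank", "gad_fu_sleep",
                           "gad_fu_irritable"],
    ))
    crit("gad_worry", "excessive anxiety and worry",
         ["gad_scr_anxiety", "gad_scr_worry"], cardinal=True)
    crit("gad_control", "difficulty controlling the worry", ["gad_scr_control"])
    crit("gad_restless", "restlessness or feeling on edge",
         ["gad_scr_restless", "gad_scr_edge"])
    crit("gad_fatigue", "easily fatigued", ["gad_fu_fatigue"])
    crit("gad_concentration", "difficulty concentrating or mind going blank",
         ["gad_fu_blank"])
    crit("gad_irritability", "irritability", ["gad_fu_irritable"])
    crit("gad_tension", "muscle tension", ["gad_scr_tense"])
    crit("gad_sleep", "sleep disturbance", ["gad_fu_sleep"])
    rules.append(DiagnosisRule(
        diagnosis_name="generalized anxiety disorder",
        criterion_ids=["gad_worry", "gad_control", "gad_restless", "gad_fatigue",
                       "gad_concentration", "gad_irritability", "gad_tension",
                       "gad_sleep"],
        required_count=5, cardinal_criterion_ids=["gad_worry"], window_days=_gad_tf,
        notes="Worry plus difficulty controlling it plus 3 or more associated "
              "symptoms, more days than not for 6 months.",
    ))

    # -- panic disorder ----------------------------------------------------
    yesno("panic_scr_attack", "I have had a panic attack", "panic", "screener",
          timeframe=36500)  # lifetime screener
    _panic_lead = "Thinking about my panic attacks…"
    for iid, text in [
        ("panic_fu_worry", "I worried about having more panic attacks"),
        ("panic_fu_avoid", "I avoided places or activities because of panic attacks"),
        ("panic_fu_heart", "My heart pounded during my panic attacks"),
        ("panic_fu_breath", "I had trouble breathing during my panic attacks"),
    ]:
        likert(iid, text, "panic", "followup", lead=_panic_lead)
    modules.append(ScreenerModule(
        module_id="panic", category_name="Panic disorder",
        screener_item_ids=["panic_scr_attack"],
        screen_in_rule=_yes("panic_scr_attack"),
        followup_item_ids=["panic_fu_worry", "panic_fu_avoid", "panic_fu_heart",
                           "panic_fu_breath"],
    ))
    crit("panic_attacks", "recurrent unexpected panic attacks",
         ["panic_scr_attack"], cardinal=True)
    crit("panic_worry", "persistent concern about additional attacks",
         ["panic_fu_worry"])
    crit("panic_behavior", "maladaptive change in behavior related to attacks",
         ["panic_fu_avoid"])
    crit("panic_physical", "prominent physical attack symptoms",
         ["panic_fu_heart", "panic_fu_breath"])
    rules.append(DiagnosisRule(
        diagnosis_name="panic disorder",
        criterion_ids=["panic_attacks", "panic_worry", "panic_behavior",
                       "panic_physical"],
        required_count=3, cardinal_criterion_ids=["panic_attacks"], window_days=30,
        notes="Attacks plus at least a month of concern or behavior change.",
    ))

    # -- agoraphobia --------------------------------------------------------
    for iid, text, tag in [
        ("agora_scr_transport", "I felt afraid when using public transportation",
         "situation"),
        ("agora_scr_open", "I felt afraid in open spaces", "situation"),
        ("agora_scr_enclosed", "I felt afraid in enclosed places", "situation"),
        ("agora_scr_crowd", "I felt afraid standing in line or being in a crowd",
         "situation"),
        ("agora_scr_alone", "I felt afraid being outside of my home alone",
         "situation"),
        ("agora_scr_avoid", "I avoided situations where escape might be difficult",
         None),
    ]:
        likert(iid, text, "agora", "screener", timeframe=180, tag=tag)
    _agora_lead = "During the time(s) when I felt afraid in these situations…"
    for iid, text in [
        ("agora_fu_help", "I feared that help would not be available if I panicked"),
        ("agora_fu_companion", "I needed someone with me to go out"),
        ("agora_fu_distress", "My fear of these situations caused me great distress"),
    ]:
        likert(iid, text, "agora", "followup", timeframe=180, lead=_agora_lead)
    modules.append(ScreenerModule(
        module_id="agora", category_name="Agoraphobia",
        screener_item_ids=["agora_scr_transport", "agora_scr_open",
                           "agora_scr_enclosed", "agora_scr_crowd",
                           "agora_scr_alone", "agora_scr_avoid"],
        screen_in_rule=RuleGroup(kind="any", clauses=[
            _ge(i, SOMETIMES) for i in
            ["agora_scr_transport", "agora_scr_open", "agora_scr_enclosed",
             "agora_scr_crowd", "agora_scr_alone", "agora_scr_avoid"]
        ]),
        followup_item_ids=["agora_fu_help", "agora_fu_companion", "agora_fu_distress"],
        summary_transform="log",  # summary scores are highly right-skewed
    ))
    crit("agora_transport", "fear of public transportation", ["agora_scr_transport"],
         cardinal=True)
    crit("agora_open", "fear of open spaces", ["agora_scr_open"], cardinal=True)
    crit("agora_enclosed", "fear of enclosed places", ["agora_scr_enclosed"],
         cardinal=True)
    crit("agora_crowd", "fear of crowds or lines", ["agora_scr_crowd"], cardinal=True)
    crit("agora_alone", "fear of being outside the home alone", ["agora_scr_alone"],
         cardinal=True)
    crit("agora_avoidance", "active avoidance of feared situations",
         ["agora_scr_avoid", "agora_fu_companion"])
    crit("agora_escape", "fear that escape or help would be unavailable",
         ["agora_fu_help"])
    crit("agora_distress", "marked distress or impairment", ["agora_fu_distress"])
    rules.append(DiagnosisRule(
        diagnosis_name="agoraphobia",
        criterion_ids=["agora_transport", "agora_open", "agora_enclosed",
                       "agora_crowd", "agora_alone", "agora_avoidance",
                       "agora_escape", "agora_distress"],
        required_count=4,
        cardinal_criterion_ids=["agora_transport", "agora_open", "agora_enclosed",
                                "agora_crowd", "agora_alone"],
        window_days=180,
        notes="Marked fear in 2 or more agoraphobic situations with avoidance "
              "and distress, lasting 6 months or more.",
    ))

    # -- social anxiety disorder --------------------------------------------
    for iid, text in [
        ("social_scr_judged", "I was afraid other people would judge me"),
        ("social_scr_embarrass", "I was afraid I would embarrass myself"),
        ("social_scr_watched", "I felt nervous when people watched me do things"),
        ("social_scr_meeting", "I felt afraid when meeting new people"),
        ("social_scr_speaking", "I felt afraid of speaking in front of others"),
        ("social_scr_avoid", "I avoided social situations"),
    ]:
        likert(iid, text, "social", "screener", timeframe=180)
    _social_lead = "During the time(s) when I felt afraid in social situations…"
    for iid, text in [
        ("social_fu_intense", "My fear in social situations was intense"),
        ("social_fu_distress", "My fear of social situations caused me great distress"),
        ("social_fu_interfere", "My fear of social situations got in the way of my "
                                "daily life"),
    ]:
        likert(iid, text, "social", "followup", timeframe=180, lead=_social_lead)
    modules.append(ScreenerModule(
        module_id="social", category_name="Social anxiety disorder",
        screener_item_ids=["social_scr_judged", "social_scr_embarrass",
                           "social_scr_watched", "social_scr_meeting",
                           "social_scr_speaking", "social_scr_avoid"],
        screen_in_rule=RuleGroup(kind="any", clauses=[
            _ge(i, SOMETIMES) for i in
            ["social_scr_judged", "social_scr_embarrass", "social_scr_watched",
             "social_scr_meeting", "social_scr_speaking", "social_scr_avoid"]
        ]),
        followup_item_ids=["social_fu_intense", "social_fu_distress",
                           "social_fu_interfere"],
    ))
    crit("social_fear", "marked fear of social scrutiny",
         ["social_scr_judged", "social_scr_embarrass", "social_scr_watched"],
         cardinal=True)
    crit("social_performance", "fear of performance or interaction situations",
         ["social_scr_meeting", "social_scr_speaking"])
    crit("social_avoidance", "avoidance of social situations", ["social_scr_avoid"])
    crit("social_intensity", "fear out of proportion to actual threat",
         ["social_fu_intense"])
    crit("social_impairment", "clinically significant distress or impairment",
         ["social_fu_distress", "social_fu_interfere"])
    rules.append(DiagnosisRule(
        diagnosis_name="social anxiety disorder",
        criterion_ids=["social_fear", "social_performance", "social_avoidance",
                       "social_intensity", "social_impairment"],
        required_count=4, cardinal_criterion_ids=["social_fear"], window_days=180,
        notes="Fear, avoidance, and impairment persisting 6 months or more.",
    ))

    # -- obsessive-compulsive disorder --------------------------------------
    for iid, text in [
        ("ocd_scr_unwanted", "I had unwanted thoughts that kept coming back"),
        ("ocd_scr_upset", "My unwanted thoughts upset me"),
        ("ocd_scr_repeat", "I repeated actions over and over"),
        ("ocd_scr_check", "I checked things more than necessary"),
        ("ocd_scr_order", "I needed things to be in a certain order"),
    ]:
        likert(iid, text, "ocd", "screener")
    _ocd_lead = "Thinking about my unwanted thoughts or repeated actions…"
    for iid, text in [
        ("ocd_fu_suppress", "I tried to ignore or push away my unwanted thoughts"),
        ("ocd_fu_driven", "I felt driven to repeat actions to feel less anxious"),
        ("ocd_fu_time", "My unwanted thoughts or repeated actions took more than "
                        "an hour a day"),
        ("ocd_fu_interfere", "My unwanted thoughts or repeated actions got in the "
                             "way of my daily life"),
    ]:
        likert(iid, text, "ocd", "followup", lead=_ocd_lead)
    modules.append(ScreenerModule(
        module_id="ocd", category_name="Obsessive-compulsive disorder",
        screener_item_ids=["ocd_scr_unwanted", "ocd_scr_upset", "ocd_scr_repeat",
                           "ocd_scr_check", "ocd_scr_order"],
        screen_in_rule=RuleGroup(kind="any", clauses=[
            _ge(i, SOMETIMES) for i in
            ["ocd_scr_unwanted", "ocd_scr_upset", "ocd_scr_repeat",
             "ocd_scr_check", "ocd_scr_order"]
        ]),
        followup_item_ids=["ocd_fu_suppress", "ocd_fu_driven", "ocd_fu_time",
                           "ocd_fu_interfere"],
    ))
    crit("ocd_obsessions", "recurrent intrusive thoughts causing distress",
         ["ocd_scr_unwanted", "ocd_scr_upset"], cardinal=True)
    crit("ocd_compulsions", "repetitive behaviors or mental acts",
         ["ocd_scr_repeat", "ocd_scr_check", "ocd_scr_order"], cardinal=True)
    crit("ocd_time", "obsessions or compulsions are time-consuming", ["ocd_fu_time"])
    crit("ocd_impairment", "clinically significant distress or impairment",
         ["ocd_fu_interfere"])
    rules.append(DiagnosisRule(
        diagnosis_name="obsessive-compulsive disorder",
        criterion_ids=["ocd_obsessions", "ocd_compulsions", "ocd_time",
                       "ocd_impairment"],
        required_count=2,
        cardinal_criterion_ids=["ocd_obsessions", "ocd_compulsions"],
        window_days=14,
        notes="Obsessions or compulsions that are time-consuming or impairing.",
    ))

    # -- posttraumatic stress disorder --------------------------------------
    _trauma_ids = []
    for iid, text in [
        ("ptsd_scr_trauma_experienced", "I have experienced a serious trauma"),
        ("ptsd_scr_trauma_witnessed", "I have witnessed a serious trauma"),
        ("ptsd_scr_trauma_close", "A close friend or family member of mine "
                                  "experienced a serious trauma"),
        ("ptsd_scr_trauma_work", "My work repeatedly exposed me to traumatic events"),
    ]:
        yesno(iid, text, "ptsd", "screener", timeframe=36500, tag="trauma_exposure")
        _trauma_ids.append(iid)
    # Screener-internal branching: symptom screeners unlock on any trauma "yes".
    for iid, text, tag in [
        ("ptsd_scr_memories", "I had unwanted memories of the trauma", "intrusion"),
        ("ptsd_scr_nightmares", "I had dreams about the trauma", "intrusion"),
        ("ptsd_scr_avoid", "I avoided things that reminded me of the trauma",
         "avoidance"),
        ("ptsd_scr_onguard", "I felt on guard", "arousal"),
    ]:
        likert(iid, text, "ptsd", "screener", tag=tag, gates=_trauma_ids)
    _ptsd_lead = "Thinking about the time after the trauma…"
    for iid, text in [
        ("ptsd_fu_flashback", "I felt as if the trauma was happening again"),
        ("ptsd_fu_avoid_thoughts", "I avoided thinking about the trauma"),
        ("ptsd_fu_negative", "I had strong negative beliefs about myself"),
        ("ptsd_fu_blame", "I blamed myself for the trauma"),
        ("ptsd_fu_startle", "I was easily startled"),
        ("ptsd_fu_sleep", "I had trouble sleeping"),
    ]:
        likert(iid, text, "ptsd", "followup", lead=_ptsd_lead)
    modules.append(ScreenerModule(
        module_id="ptsd", category_name="Posttraumatic stress disorder",
        screener_item_ids=_trauma_ids + ["ptsd_scr_memories", "ptsd_scr_nightmares",
                                         "ptsd_scr_avoid", "ptsd_scr_onguard"],
        screen_in_rule=RuleGroup(kind="any", clauses=[_yes(i) for i in _trauma_ids]),
        followup_item_ids=["ptsd_fu_flashback", "ptsd_fu_avoid_thoughts",
                           "ptsd_fu_negative", "ptsd_fu_blame", "ptsd_fu_startle",
                           "ptsd_fu_sleep"],
    ))
    crit("ptsd_exposure", "exposure to actual or threatened trauma", _trauma_ids,
         cardinal=True)
    crit("ptsd_intrusion", "intrusion symptoms",
         ["ptsd_scr_memories", "ptsd_scr_nightmares", "ptsd_fu_flashback"])
    crit("ptsd_avoidance", "avoidance of trauma reminders",
         ["ptsd_scr_avoid", "ptsd_fu_avoid_thoughts"])
    crit("ptsd_negative_mood", "negative alterations in cognitions and mood",
         ["ptsd_fu_negative", "ptsd_fu_blame"])
    crit("ptsd_arousal", "marked alterations in arousal and reactivity",
         ["ptsd_scr_onguard", "ptsd_fu_startle", "ptsd_fu_sleep"])
    rules.append(DiagnosisRule(
        diagnosis_name="posttraumatic stress disorder",
        criterion_ids=["ptsd_exposure", "ptsd_intrusion", "ptsd_avoidance",
                       "ptsd_negative_mood", "ptsd_arousal"],
        required_count=5, cardinal_criterion_ids=["ptsd_exposure"], window_days=30,
        notes="All symptom clusters present for more than 1 month after exposure.",
    ))

    # -- adult ADHD ----------------------------------------------------------
    for iid, text in [
        ("adhd_scr_sitting", "I had difficulty sitting still"),
        ("adhd_scr_attention", "I had trouble paying attention"),
        ("adhd_scr_distracted", "I was easily distracted by things around me"),
        ("adhd_scr_forget", "I forgot things in my daily activities"),
        ("adhd_scr_organize", "I had trouble staying organized"),
        ("adhd_scr_interrupt", "I interrupted others"),
        ("adhd_scr_fidget", "I fidgeted with my hands or feet"),
    ]:
        likert(iid, text, "adhd", "screener", timeframe=180)
    for iid, text in [
        ("adhd_fu_careless", "I made careless mistakes"),
        ("adhd_fu_finish", "I had trouble finishing tasks"),
        ("adhd_fu_motor", "I felt driven, like I could not slow down"),
        ("adhd_fu_wait", "I had trouble waiting my turn"),
    ]:
        likert(iid, text, "adhd", "followup", timeframe=180)
    modules.append(ScreenerModule(
        module_id="adhd",
        category_name="Adult attention-deficit/hyperactivity disorder",
        screener_item_ids=["adhd_scr_sitting", "adhd_scr_attention",
                           "adhd_scr_distracted", "adhd_scr_forget",
                           "adhd_scr_organize", "adhd_scr_interrupt",
                           "adhd_scr_fidget"],
        screen_in_rule=RuleGroup(kind="any", clauses=[
            _ge(i, SOMETIMES) for i in
            ["adhd_scr_sitting", "adhd_scr_attention", "adhd_scr_distracted",
             "adhd_scr_forget", "adhd_scr_organize", "adhd_scr_interrupt",
             "adhd_scr_fidget"]
        ]),
        followup_item_ids=["adhd_fu_careless", "adhd_fu_finish", "adhd_fu_motor",
                           "adhd_fu_wait"],
    ))
    crit("adhd_inattention_core", "sustained-attention difficulty",
         ["adhd_scr_attention", "adhd_scr_distracted"], cardinal=True)
    crit("adhd_hyperactivity_core", "hyperactivity",
         ["adhd_scr_sitting", "adhd_scr_fidget"], cardinal=True)
    crit("adhd_forgetful", "forgetfulness in daily activities", ["adhd_scr_forget"])
    crit("adhd_disorganized", "difficulty organizing tasks", ["adhd_scr_organize"])
    crit("adhd_interrupting", "interrupting or intruding on others",
         ["adhd_scr_interrupt"])
    crit("adhd_careless", "careless mistakes", ["adhd_fu_careless"])
    crit("adhd_task_completion", "failure to finish tasks", ["adhd_fu_finish"])
    crit("adhd_inner_restlessness", "feeling driven or restless", ["adhd_fu_motor"])
    crit("adhd_impatience", "difficulty awaiting turn", ["adhd_fu_wait"])
    rules.append(DiagnosisRule(
        diagnosis_name="attention-deficit/hyperactivity disorder",
        criterion_ids=["adhd_inattention_core", "adhd_hyperactivity_core",
                       "adhd_forgetful", "adhd_disorganized", "adhd_interrupting",
                       "adhd_careless", "adhd_task_completion",
                       "adhd_inner_restlessness", "adhd_impatience"],
        required_count=5,
        cardinal_criterion_ids=["adhd_inattention_core", "adhd_hyperactivity_core"],
        window_days=180,
        notes="Adult threshold of 5 symptoms; childhood onset before age 12 "
              "assessed by clinician.",
    ))

    # -- psychotic disorders -------------------------------------------------
    for iid, text in [
        ("psych_scr_voices", "I heard voices that other people could not hear"),
        ("psych_scr_sounds", "I heard sounds that were not really there"),
        ("psych_scr_visions", "I saw things that other people could not see"),
        ("psych_scr_smells", "I smelled things that were not really there"),
        ("psych_scr_touch", "I felt things touching me that were not really there"),
    ]:
        likert(iid, text, "psych", "screener", tag="hallucination")
    for iid, text in [
        ("psych_scr_control", "I felt like my thoughts were being controlled "
                              "against my will"),
        ("psych_scr_spied", "I believed I was being spied on"),
        ("psych_scr_messages", "I received special messages through the TV or radio"),
        ("psych_scr_punish", "I thought I deserved to be punished"),
        ("psych_scr_powers", "I believed I had special powers that other people "
                             "did not have"),
    ]:
        likert(iid, text, "psych", "screener", tag="delusion")
    for iid, text in [
        ("psych_fu_speech", "People said my speech did not make sense"),
        ("psych_fu_fixed", "I kept my beliefs even when others showed me proof "
                           "they were wrong"),
        ("psych_fu_function", "My experiences made it hard to do my daily "
                              "activities"),
    ]:
        likert(iid, text, "psych", "followup")
    _psych_scr = ["psych_scr_voices", "psych_scr_sounds", "psych_scr_visions",
                  "psych_scr_smells", "psych_scr_touch", "psych_scr_control",
                  "psych_scr_spied", "psych_scr_messages", "psych_scr_punish",
                  "psych_scr_powers"]
    modules.append(ScreenerModule(
        module_id="psych", category_name="Psychotic disorders",
        screener_item_ids=_psych_scr,
        screen_in_rule=RuleGroup(kind="any",
                                 clauses=[_ge(i, SOMETIMES) for i in _psych_scr]),
        followup_item_ids=["psych_fu_speech", "psych_fu_fixed", "psych_fu_function"],
        subscale_tags=["hallucination", "delusion"],
    ))
    crit("psych_hallucinations", "hallucinations",
         ["psych_scr_voices", "psych_scr_sounds", "psych_scr_visions",
          "psych_scr_smells", "psych_scr_touch"], cardinal=True)
    crit("psych_delusions", "delusions",
         ["psych_scr_control", "psych_scr_spied", "psych_scr_messages",
          "psych_scr_punish", "psych_scr_powers"], cardinal=True)
    crit("psych_disorganized", "disorganized speech", ["psych_fu_speech"])
    crit("psych_conviction", "fixed beliefs despite contrary evidence",
         ["psych_fu_fixed"])
    crit("psych_function", "functional decline", ["psych_fu_function"])
    rules.append(DiagnosisRule(
        diagnosis_name="brief psychotic disorder",
        criterion_ids=["psych_hallucinations", "psych_delusions",
                       "psych_disorganized"],
        required_count=1,
        cardinal_criterion_ids=["psych_hallucinations", "psych_delusions"],
        window_days=30,
        notes="At least 1 day but less than 1 month of psychotic symptoms with "
              "eventual full return to premorbid functioning (duration assessed "
              "by clinician). Longer courses point to schizophreniform disorder "
              "or schizophrenia.",
    ))
    rules.append(DiagnosisRule(
        diagnosis_name="delusional disorder",
        criterion_ids=["psych_delusions", "psych_conviction"],
        required_count=2, cardinal_criterion_ids=["psych_delusions"],
        window_days=30,
        notes="Delusions for 1 month or longer without prominent hallucinations "
              "or functional deterioration (clinician judgment).",
    ))

    # -- substance-use modules ------------------------------------------------
    def substance_module(mid, category, diagnosis, substance_word, screener_item,
                         screen_rule, use_label):
        lead = f"Thinking about my use of {substance_word}…"
        fu_ids = []
        for key, template in _SUD_SYMPTOMS:
            iid = f"{mid}_fu_{key}"
            likert(iid, template.format(s=substance_word), mid, "followup",
                   lead=lead, timeframe=30)
            fu_ids.append(iid)
        modules.append(ScreenerModule(
            module_id=mid, category_name=category,
            screener_item_ids=[screener_item], screen_in_rule=screen_rule,
            followup_item_ids=fu_ids,
        ))
        use_cid = crit(f"{mid}_use", use_label, [screener_item], cardinal=True)
        cids = [use_cid]
        for key, _ in _SUD_SYMPTOMS:
            cids.append(crit(f"{mid}_{key}", f"{key.replace('_', ' ')} symptom",
                             [f"{mid}_fu_{key}"]))
        rules.append(DiagnosisRule(
            diagnosis_name=diagnosis, criterion_ids=cids, required_count=3,
            cardinal_criterion_ids=[use_cid], window_days=365,
            notes="Recurrent use plus at least 2 of the 11 DSM-5 symptom "
                  "criteria within a 12-month period (30-day reporting window).",
        ))

    items.append(Item(
        item_id="alcohol_scr_days",
        text="In the last 30 days, on how many days did you drink alcohol?",
        module_id="alcohol", section="screener", response_kind="count_days",
        timeframe_days=30, count_cut=5,
    ))
    substance_module(
        "alcohol", "Alcohol use disorder", "alcohol use disorder", "alcohol",
        "alcohol_scr_days",
        _ge("alcohol_scr_days", 5),  # fixture screen-in cut: >= 5 drinking days/30
        "recurrent alcohol use",
    )

    yesno("cannabis_scr_use", "I used marijuana in the last 30 days", "cannabis",
          "screener")
    substance_module(
        "cannabis", "Cannabis use disorder", "cannabis use disorder", "marijuana",
        "cannabis_scr_use", _yes("cannabis_scr_use"), "cannabis use in the past 30 days",
    )

    yesno("othersub_scr_use",
          "I used drugs other than marijuana or alcohol in the last 30 days",
          "othersub", "screener")
    substance_module(
        "othersub", "Other substance use disorders",
        "other or unknown substance use disorder", "other drugs",
        "othersub_scr_use", _yes("othersub_scr_use"),
        "other substance use in the past 30 days",
    )

    instr = Instrument(
        name=FIXTURE_NAME,
        items=items,
        modules=modules,
        criteria=criteria,
        diagnosis_rules=rules,
        catalog=list(DIAGNOSIS_CATALOG),
    )
    return instr
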