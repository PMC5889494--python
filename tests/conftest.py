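import pytest

from sage_screen import build_fixture_instrument
from sage_screen.model import (
    Instrument,
    Item,
    RuleAtom,
    RuleGroup,
    ScreenerModule,
)


@pytest.fixture(scope="session")
def fixture_instrument():
    return build_fixture_instrument()


@pytest.fixture(scope="session")
def all_never_script(fixture_instrument):
    """A complete response script for a floor respondent: every Likert item
    at 'never' severity (reverse items at 'always'), every yes/no at no,
    every count at zero."""
    script = {}
    for it in fixture_instrument.items:
        if it.response_kind.value == "likert5":
            script[it.item_id] = 5 if it.reverse_scored else 1
        elif it.response_kind.value == "yes_no":
            script[it.item_id] = False
        else:
            script[it.item_id] = 0
    return script


def make_toy_instrument(n_items: int = 2, reverse_last: bool = False) -> Instrument:
    """A minimal single-module Likert instrument for hand-traceable tests."""
    items = [
        Item(
            item_id=f"toy_scr_{j}",
            text=f"toy screener {j}",
            module_id="toy",
            section="screener",
            response_kind="likert5",
            reverse_scored=reverse_last and j == n_items - 1,
        )
        for j in range(n_items)
    ]
    items.append(Item(item_id="toy_fu_0", text="toy follow-up", module_id="toy",
                      section="followup", response_kind="likert5"))
    clauses = [
        RuleAtom(item_id=f"toy_scr_{j}", comparator="le" if it.reverse_scored else "ge",
                 level=3)
        for j, it in enumerate(items[:n_items])
    ]
    module = ScreenerModule(
        module_id="toy",
        category_name="Toy category",
        screener_item_ids=[f"toy_scr_{j}" for j in range(n_items)],
        screen_in_rule=RuleGroup(kind="any", clauses=clauses),
        followup_item_ids=["toy_fu_0"],
    )
    return Instrument(name="toy", items=items, modules=[module])
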