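import logging
import random

import pytest
from hypothesis import settings

from neurocds import kb_dsl
from neurocds.config import default_layout_config, demo_kb_source
from neurocds.ehr_extract import (
    ComorbidityMap,
    DrugTaxonomy,
    declared_input_variables,
)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

# the missing-input default is exercised deliberately and is noisy
logging.getLogger("neurocds.kb_engine").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def taxonomy() -> DrugTaxonomy:
    return DrugTaxonomy.from_config()


@pytest.fixture(scope="session")
def comorbidity_map() -> ComorbidityMap:
    return ComorbidityMap.from_config()


@pytest.fixture(scope="session")
def layout_config() -> dict:
    return default_layout_config()


@pytest.fixture(scope="session")
def declared_inputs(taxonomy, comorbidity_map) -> list[str]:
    return declared_input_variables(taxonomy, comorbidity_map)


BOX1_SOURCE = """\
if (amitriptyline_tx
    || nortriptyline_tx)
       tca_tx = true;
"""

BOX2_SOURCE = """\
Comment TCA_depression {
    Condition: tca_tx & depression_hx; Where: Recommendations (order: 7);
    Condition: depression_hx; Where: TCA_comments (order: 5);
    Text: "The presence of depression is not required for the analgesic \
effects of TCAs, although they may be particularly useful in patients \
with inadequately treated depression."
}
"""

BOX_INPUTS = ["amitriptyline_tx", "nortriptyline_tx", "depression_hx"]
BOX_LOCATIONS = ["Recommendations", "TCA_comments"]


@pytest.fixture(scope="session")
def box_kb() -> kb_dsl.KnowledgeBase:
    """Box 1 rule + Box 2 comment, the two statements of the worked example."""
    return kb_dsl.parse_kb(BOX1_SOURCE + BOX2_SOURCE,
                           declared_inputs=BOX_INPUTS,
                           locations=BOX_LOCATIONS)


@pytest.fixture(scope="session")
def box_plan(box_kb) -> kb_dsl.EvaluationPlan:
    return kb_dsl.compile_kb(box_kb)


@pytest.fixture(scope="session")
def demo_kb(declared_inputs, layout_config) -> kb_dsl.KnowledgeBase:
    return kb_dsl.parse_kb(demo_kb_source(),
                           declared_inputs=declared_inputs,
                           locations=layout_config["locations"])


# ---------------------------------------------------------------------------
# Random-KB generator shared by round-trip and oracle-equivalence checks
# ---------------------------------------------------------------------------

def random_expr(rng: random.Random, names: list[str],
                depth: int = 0) -> kb_dsl.BoolExpr:
    choice = rng.random()
    if depth >= 3 or choice < 0.45:
        return kb_dsl.VarRef(rng.choice(names))
    if choice < 0.6:
        return kb_dsl.Not(random_expr(rng, names, depth + 1))
    ctor = kb_dsl.And if choice < 0.8 else kb_dsl.Or
    k = rng.randint(2, 3)
    return ctor(tuple(random_expr(rng, names, depth + 1) for _ in range(k)))


def random_kb(rng: random.Random, max_inputs: int = 12,
              max_rules: int = 20, max_comments: int = 20
              ) -> kb_dsl.KnowledgeBase:
    """A runnable random KB: rule conditions only read inputs or targets
    of earlier rules, so single-pass semantics are well defined."""
    n_inputs = rng.randint(1, max_inputs)
    inputs = [f"in{i}" for i in range(n_inputs)]
    locations = [f"Loc{i}" for i in range(rng.randint(1, 4))]
    readable = list(inputs)
    rules = []
    for r in range(rng.randint(0, max_rules)):
        condition = random_expr(rng, readable)
        n_assign = rng.randint(1, 2)
        targets = rng.sample([f"d{r}_{j}" for j in range(3)], n_assign)
        assignments = tuple((t, rng.random() < 0.7) for t in targets)
        rules.append(kb_dsl.Rule(condition, assignments))
        readable.extend(targets)
    comments = []
    for c in range(rng.randint(0, max_comments)):
        routes = tuple(
            kb_dsl.Route(random_expr(rng, readable),
                         kb_dsl.Placement(rng.choice(locations),
                                          rng.randint(0, 9)))
            for _ in range(rng.randint(1, 3)))
        comments.append(kb_dsl.ConditionalComment(
            f"c{c}", routes, f"text of comment {c} with \"quotes\"\nand "
                             f"a second line"))
    return kb_dsl.KnowledgeBase(
        rules=tuple(rules), comments=tuple(comments),
        declared_inputs=frozenset(inputs), locations=tuple(locations))
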