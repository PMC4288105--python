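"""Parser, validator, and compiler of the KB language."""

import random

import pytest
from hypothesis import given, strategies as st

from conftest import BOX1_SOURCE, BOX2_SOURCE, BOX_INPUTS, BOX_LOCATIONS, \
    random_kb
from neurocds import kb_dsl
from neurocds.kb_dsl import (
    And, CompileError, ConditionalComment, Diagnostic, KBSyntaxError,
    KnowledgeBase, Not, Or, Placement, Route, Rule, VarRef,
    compile_kb, expr_vars, parse_kb, pretty_print, validate_kb,
)


class TestParsing:
    def test_simple_if_then_rule(self):
        """The amitriptyline/nortriptyline → TCA derivation rule parses to
        a single Or-guarded assignment."""
        kb = parse_kb(BOX1_SOURCE)
        assert kb.rules == (Rule(
            condition=Or((VarRef("amitriptyline_tx"),
                          VarRef("nortriptyline_tx"))),
            assignments=(("tca_tx", True),)),)
        assert kb.comments == ()

    def test_conditional_comment_two_routes(self):
        """A comment can target two screen locations, each with its own
        condition and sort order."""
        kb = parse_kb(BOX2_SOURCE)
        (comment,) = kb.comments
        assert comment.name == "TCA_depression"
        assert comment.routes == (
            Route(And((VarRef("tca_tx"), VarRef("depression_hx"))),
                  Placement("Recommendations", 7)),
            Route(VarRef("depression_hx"), Placement("TCA_comments", 5)),
        )
        assert comment.text.startswith(
            "The presence of depression is not required")

    def test_empty_document(self):
        kb = parse_kb("")
        assert kb.rules == () and kb.comments == ()
        assert parse_kb("# only a comment line\n").rules == ()

    def test_multiple_assignments_attach_to_one_rule(self):
        kb = parse_kb("if (a) x = true; y = false;\nif (b) z = true;")
        assert len(kb.rules) == 2
        assert kb.rules[0].assignments == (("x", True), ("y", False))
        assert kb.rules[1].assignments == (("z", True),)

    @pytest.mark.parametrize("src", [
        "if (a || b) t = true;",
        "if (a | b) t = true;",
    ])
    def test_or_spellings_equivalent(self, src):
        assert parse_kb(src).rules[0].condition == Or((VarRef("a"),
                                                       VarRef("b")))

    @pytest.mark.parametrize("src", [
        "if (a && b) t = true;",
        "if (a & b) t = true;",
    ])
    def test_and_spellings_equivalent(self, src):
        assert parse_kb(src).rules[0].condition == And((VarRef("a"),
                                                        VarRef("b")))

    def test_precedence_not_over_and_over_or(self):
        kb = parse_kb("if (!a & b | c) t = true;")
        assert kb.rules[0].condition == Or((
            And((Not(VarRef("a")), VarRef("b"))), VarRef("c")))

    def test_parentheses_group(self):
        kb = parse_kb("if (!(a | b) & c) t = true;")
        assert kb.rules[0].condition == And((
            Not(Or((VarRef("a"), VarRef("b")))), VarRef("c")))

    def test_text_string_spans_lines_and_escapes_quotes(self):
        src = ('Comment c { Condition: a; Where: L (order: 0); '
               'Text: "line one\nline \\"two\\"" }')
        (comment,) = parse_kb(src).comments
        assert comment.text == 'line one\nline "two"'

    def test_syntax_error_reports_line_and_column(self):
        with pytest.raises(KBSyntaxError) as err:
            parse_kb("if (a)\n  t = maybe;")
        assert err.value.line == 2
        assert err.value.token == "maybe"

    def test_duplicate_comment_name_is_named_diagnostic(self):
        src = ('Comment dup { Condition: a; Where: L (order: 0); Text: "x" }\n'
               'Comment dup { Condition: b; Where: L (order: 1); Text: "y" }')
        with pytest.raises(KBSyntaxError, match="duplicate comment name 'dup'"):
            parse_kb(src)

    def test_unterminated_text_string(self):
        with pytest.raises(KBSyntaxError, match="unterminated Text string"):
            parse_kb('Comment c { Condition: a; Where: L (order: 0); '
                     'Text: "never closed }')

    def test_duplicate_assignment_target_rejected(self):
        with pytest.raises(KBSyntaxError, match="duplicate assignment"):
            parse_kb("if (a) t = true; t = false;")

    def test_declaration_order_preserved(self):
        src = ("if (a) r1 = true;\n"
               'Comment c1 { Condition: a; Where: L (order: 0); Text: "1" }\n'
               "if (b) r2 = true;\n"
               'Comment c2 { Condition: b; Where: L (order: 0); Text: "2" }')
        kb = parse_kb(src)
        assert [r.assignments[0][0] for r in kb.rules] == ["r1", "r2"]
        assert [c.name for c in kb.comments] == ["c1", "c2"]


class TestRoundTrip:
    @given(st.integers(0, 10_000))
    def test_parse_pretty_print_parse_is_identity(self, seed):
        """Pretty-printing any generated KB and re-parsing recovers a
        structurally equal KB."""
        kb = random_kb(random.Random(seed))
        reparsed = parse_kb(pretty_print(kb),
                            declared_inputs=kb.declared_inputs,
                            locations=kb.locations)
        assert reparsed.rules == kb.rules
        assert reparsed.comments == kb.comments

    def test_box_sources_round_trip(self, box_kb):
        reparsed = parse_kb(pretty_print(box_kb),
                            declared_inputs=box_kb.declared_inputs,
                            locations=box_kb.locations)
        assert reparsed.rules == box_kb.rules
        assert reparsed.comments == box_kb.comments


class TestValidation:
    def test_runnable_kb_has_no_diagnostics(self, box_kb):
        assert validate_kb(box_kb) == []

    def test_undefined_variable(self):
        kb = parse_kb("if (tca_tx) flag = true;", declared_inputs=[],
                      locations=[])
        diags = validate_kb(kb)
        # oracle: referenced minus (inputs ∪ assigned) = {tca_tx}
        assert [d.code for d in diags] == ["undefined_variable"]
        assert "tca_tx" in diags[0].message

    def test_unknown_location(self):
        kb = parse_kb(BOX2_SOURCE, declared_inputs=["tca_tx",
                                                    "depression_hx"],
                      locations=["TCA_comments"])  # registry lacks one
        codes = [d.code for d in validate_kb(kb)]
        assert codes == ["unknown_location"]
        assert "Recommendations" in validate_kb(kb)[0].message

    def test_use_before_assignment(self):
        src = "if (late) early = true;\nif (a) late = true;"
        kb = parse_kb(src, declared_inputs=["a"], locations=[])
        assert "use_before_assignment" in [d.code for d in validate_kb(kb)]

    def test_input_reassigned(self):
        kb = parse_kb("if (a) b = true;", declared_inputs=["a", "b"],
                      locations=[])
        assert "input_reassigned" in [d.code for d in validate_kb(kb)]

    def test_unreachable_route_is_nonblocking(self):
        src = ('Comment c { Condition: ghost; Where: L (order: 0); '
               'Text: "x" }')
        kb = parse_kb(src, declared_inputs=[], locations=["L"])
        diags = validate_kb(kb)
        codes = {d.code for d in diags}
        assert "undefined_variable" in codes
        assert "unreachable_route" in codes
        nonblocking = [d for d in diags if d.code == "unreachable_route"]
        assert all(not d.blocking for d in nonblocking)


class TestCompilation:
    def test_single_rule_plan(self):
        kb = parse_kb(BOX1_SOURCE,
                      declared_inputs=["amitriptyline_tx",
                                       "nortriptyline_tx"])
        plan = compile_kb(kb)
        assert sum(1 for s in plan.steps if s.kind == "rule") == 1

    def test_step_counts_preserved(self):
        rng = random.Random(5)
        kb = random_kb(rng, max_rules=3, max_comments=2)
        plan = compile_kb(kb)
        assert sum(1 for s in plan.steps if s.kind == "rule") == len(kb.rules)
        assert sum(1 for s in plan.steps if s.kind == "route") == \
            sum(len(c.routes) for c in kb.comments)
        # rule steps strictly precede route steps
        kinds = [s.kind for s in plan.steps]
        assert kinds == sorted(kinds, key=lambda k: k != "rule")

    def test_compilation_deterministic(self, box_kb):
        assert compile_kb(box_kb).serialize() == compile_kb(box_kb).serialize()

    def test_blocking_diagnostics_refuse_compilation(self):
        kb = parse_kb("if (nowhere) x = true;", declared_inputs=[])
        with pytest.raises(CompileError, match="nowhere"):
            compile_kb(kb)


def test_expr_vars_is_referenced_name_set():
    expr = Or((And((VarRef("a"), Not(VarRef("b")))), VarRef("a")))
    assert expr_vars(expr) == {"a", "b"}
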