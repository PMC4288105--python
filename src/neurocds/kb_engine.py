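"""Evaluation engine: run a compiled plan against a patient FactSet.

Semantics mirror straight-line generated code: rule steps execute once, in
declaration order, and may overwrite earlier targets (last write wins);
comment routes are then checked against the post-rule bindings.  Within
each location, placed comments sort ascending by their ``order`` key, with
ties broken stably by KB declaration order.  A missing input binding
defaults to false with a logged warning — absence of evidence in the chart
reads as absence of the finding.

Overriding a fact (the clinician checking or unchecking a comorbidity
checkbox) is a pure re-evaluation: the original FactSet is untouched and
the override carries ``provenance='override'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

from neurocds.kb_dsl import (
    EvaluationPlan,
    KnowledgeBase,
    eval_expr,
    run_program,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Fact", "Demographics", "FactSet", "PlacedComment", "EvaluationResult",
    "EvaluationError", "evaluate", "override_fact", "truth_table_reference",
]

PROVENANCES = ("extracted", "override", "derived")


@dataclass(frozen=True)
class Fact:
    value: bool
    provenance: str = "extracted"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class Demographics:
    name: str = ""
    age: int = 0
    sex: str = ""


@dataclass(frozen=True)
class FactSet:
    """Named boolean variables with provenance, plus demographics."""

    bindings: dict[str, Fact] = field(default_factory=dict)
    demographics: Demographics = field(default_factory=Demographics)

    def with_fact(self, name: str, value: bool,
                  provenance: str = "extracted") -> "FactSet":
        new = dict(self.bindings)
        new[name] = Fact(value, provenance)
        return replace(self, bindings=new)

    def value(self, name: str) -> bool:
        return self.bindings[name].value

    def values(self) -> dict[str, bool]:
        return {k: f.value for k, f in self.bindings.items()}


@dataclass(frozen=True)
class PlacedComment:
    comment_name: str
    location: str
    order: int
    text: str


@dataclass(frozen=True)
class EvaluationResult:
    facts: FactSet
    placements: dict[str, tuple[PlacedComment, ...]]

    def at(self, location: str) -> tuple[PlacedComment, ...]:
        return self.placements.get(location, ())


class EvaluationError(Exception):
    """An expression referenced a variable with no binding and no default."""


def _initial_bindings(plan: EvaluationPlan, facts: FactSet) -> dict[str, bool]:
    bindings = {name: fact.value for name, fact in facts.bindings.items()}
    for name in plan.declared_inputs:
        if name not in bindings:
            logger.warning(
                "input %r has no binding; defaulting to false", name)
            bindings[name] = False
    return bindings


def _collect(plan: EvaluationPlan, facts: FactSet,
             bindings: dict[str, bool]) -> EvaluationResult:
    # run rule steps in plan order, then route checks
    for step in plan.steps:
        if step.kind != "rule":
            continue
        try:
            fired = run_program(step.program, bindings)
        except KeyError as exc:
            raise EvaluationError(
                f"no binding for variable {exc.args[0]!r}") from None
        if fired:
            for target, value in step.assignments:
                bindings[target] = value
        else:
            # an unfired rule still defines its targets (as false) unless
            # a prior step set them
            for target, _ in step.assignments:
                bindings.setdefault(target, False)

    raw: dict[str, list[PlacedComment]] = {loc: [] for loc in plan.locations}
    seen: set[tuple[str, str]] = set()  # (comment, location) dedup
    for step in plan.steps:
        if step.kind != "route":
            continue
        try:
            fired = run_program(step.program, bindings)
        except KeyError as exc:
            raise EvaluationError(
                f"no binding for variable {exc.args[0]!r}") from None
        if fired and (step.comment_name, step.location) not in seen:
            seen.add((step.comment_name, step.location))
            raw.setdefault(step.location, []).append(PlacedComment(
                step.comment_name, step.location, step.order, step.text))

    placements = {
        loc: tuple(sorted(items, key=lambda p: p.order))  # stable sort
        for loc, items in raw.items()
    }

    final = FactSet(bindings=dict(facts.bindings),
                    demographics=facts.demographics)
    out_bindings = dict(final.bindings)
    for name in plan.derived_vars:
        out_bindings[name] = Fact(bindings.get(name, False), "derived")
    final = replace(final, bindings=out_bindings)
    return EvaluationResult(facts=final, placements=placements)


def evaluate(plan: EvaluationPlan, facts: FactSet) -> EvaluationResult:
    """Run the compiled plan: rules in declaration order, then comment
    routing, deterministically for fixed inputs."""
    bindings = _initial_bindings(plan, facts)
    return _collect(plan, facts, bindings)


def override_fact(plan: EvaluationPlan, facts: FactSet, var: str,
                  value: bool) -> EvaluationResult:
    """Re-evaluate with one input changed by the clinician.

    Refuses to override a derived variable, naming it; the original
    FactSet is not modified.
    """
    if var in plan.derived_vars:
        raise ValueError(
            f"{var!r} is derived by a rule and cannot be overridden")
    if var not in plan.declared_inputs:
        raise ValueError(f"{var!r} is not a declared input")
    logger.info("override %s=%s; re-evaluating", var, value)
    return evaluate(plan, facts.with_fact(var, value, provenance="override"))


def truth_table_reference(kb: KnowledgeBase, facts: FactSet,
                          declared_inputs: Optional[set[str]] = None
                          ) -> EvaluationResult:
    """Direct AST interpretation, bypassing compilation.

    Independent reference implementation used to cross-check
    ``evaluate(compile_kb(kb), facts)``; intended for small KBs
    (exhaustive truth-table checks need ≤ 16 inputs).
    """
    inputs = set(kb.declared_inputs if declared_inputs is None
                 else declared_inputs)
    bindings = {name: fact.value for name, fact in facts.bindings.items()}
    for name in inputs:
        bindings.setdefault(name, False)

    for rule in kb.rules:
        try:
            fired = eval_expr(rule.condition, bindings)
        except KeyError as exc:
            raise EvaluationError(
                f"no binding for variable {exc.args[0]!r}") from None
        for target, value in rule.assignments:
            if fired:
                bindings[target] = value
            else:
                bindings.setdefault(target, False)

    raw: dict[str, list[PlacedComment]] = {loc: [] for loc in kb.locations}
    seen: set[tuple[str, str]] = set()
    for comment in kb.comments:
        for route in comment.routes:
            try:
                fired = eval_expr(route.condition, bindings)
            except KeyError as exc:
                raise EvaluationError(
                    f"no binding for variable {exc.args[0]!r}") from None
            key = (comment.name, route.placement.location)
            if fired and key not in seen:
                seen.add(key)
                raw.setdefault(route.placement.location, []).append(
                    PlacedComment(comment.name, route.placement.location,
                                  route.placement.order, comment.text))

    placements = {loc: tuple(sorted(items, key=lambda p: p.order))
                  for loc, items in raw.items()}

    out_bindings = dict(facts.bindings)
    for name in kb.derived_vars():
        out_bindings[name] = Fact(bindings.get(name, False), "derived")
    final = FactSet(bindings=out_bindings, demographics=facts.demographics)
    return EvaluationResult(facts=final, placements=placements)
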