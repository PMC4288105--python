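"""Knowledge-base language: AST, parser, validator, and plan compiler.

The KB language has two statement forms.  A derivation rule::

    if (amitriptyline_tx || nortriptyline_tx)
        tca_tx = true;

assigns boolean literals to derived variables when its condition holds.
A conditional comment::

    Comment TCA_depression {
        Condition: tca_tx & depression_hx; Where: Recommendations (order: 7);
        Condition: depression_hx;          Where: TCA_comments (order: 5);
        Text: "The presence of depression is not required ..."
    }

routes one block of text to one or more named interface locations, each
under its own condition and with its own sort order.  A single comment may
therefore appear in several screen locations, sorted differently in each.

Expressions are pure boolean: ``!`` is NOT, ``&``/``&&`` are AND,
``|``/``||`` are OR, precedence NOT > AND > OR, parentheses group.
Identifiers are ``[A-Za-z_][A-Za-z0-9_]*`` and case-sensitive.  ``#``
starts a line comment.  Text strings are double-quoted, may span lines,
and escape an embedded quote as ``\\"``.

Compilation lowers every condition to a postfix (stack-machine) program;
the resulting :class:`EvaluationPlan` lists rule steps first, then comment
route checks, in declaration order.  The plan is deliberately a different
execution path from direct AST interpretation so the two can cross-check
each other.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Union

__all__ = [
    "VarRef", "Not", "And", "Or", "BoolExpr",
    "Rule", "Placement", "Route", "ConditionalComment", "KnowledgeBase",
    "Diagnostic", "KBSyntaxError",
    "parse_kb", "pretty_print", "validate_kb", "compile_kb",
    "EvaluationPlan", "PlanStep", "expr_vars", "eval_expr",
]

IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarRef:
    name: str


@dataclass(frozen=True)
class Not:
    operand: "BoolExpr"


@dataclass(frozen=True)
class And:
    operands: tuple["BoolExpr", ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise ValueError("And requires at least two operands")


@dataclass(frozen=True)
class Or:
    operands: tuple["BoolExpr", ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise ValueError("Or requires at least two operands")


BoolExpr = Union[VarRef, Not, And, Or]


@dataclass(frozen=True)
class Rule:
    """``if (<condition>) <target> = <literal>; ...`` — one or more
    assignments guarded by one condition."""

    condition: BoolExpr
    assignments: tuple[tuple[str, bool], ...]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("Rule requires at least one assignment")
        targets = [t for t, _ in self.assignments]
        if len(set(targets)) != len(targets):
            raise ValueError("Rule assigns the same target twice")


@dataclass(frozen=True)
class Placement:
    """A target interface location plus its sort key within that location."""

    location: str
    order: int

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")


@dataclass(frozen=True)
class Route:
    condition: BoolExpr
    placement: Placement


@dataclass(frozen=True)
class ConditionalComment:
    name: str
    routes: tuple[Route, ...]
    text: str

    def __post_init__(self) -> None:
        if not self.routes:
            raise ValueError("ConditionalComment requires at least one route")


@dataclass(frozen=True)
class KnowledgeBase:
    """Parsed KB: rules and comments in declaration order, plus the
    location registry and declared-input set supplied by configuration."""

    rules: tuple[Rule, ...] = ()
    comments: tuple[ConditionalComment, ...] = ()
    declared_inputs: frozenset[str] = frozenset()
    locations: tuple[str, ...] = ()

    def derived_vars(self) -> list[str]:
        """Rule targets in first-assignment order."""
        seen: dict[str, None] = {}
        for rule in self.rules:
            for target, _ in rule.assignments:
                seen.setdefault(target, None)
        return list(seen)

    def referenced_vars(self) -> set[str]:
        names: set[str] = set()
        for rule in self.rules:
            names |= expr_vars(rule.condition)
            names |= {t for t, _ in rule.assignments}
        for comment in self.comments:
            for route in comment.routes:
                names |= expr_vars(route.condition)
        return names


def expr_vars(expr: BoolExpr) -> set[str]:
    """The finite set of variable names an expression reads."""
    if isinstance(expr, VarRef):
        return {expr.name}
    if isinstance(expr, Not):
        return expr_vars(expr.operand)
    out: set[str] = set()
    for op in expr.operands:
        out |= expr_vars(op)
    return out


def eval_expr(expr: BoolExpr, bindings: dict[str, bool]) -> bool:
    """Direct recursive interpretation of an expression AST."""
    if isinstance(expr, VarRef):
        return bindings[expr.name]
    if isinstance(expr, Not):
        return not eval_expr(expr.operand, bindings)
    if isinstance(expr, And):
        return all(eval_expr(op, bindings) for op in expr.operands)
    return any(eval_expr(op, bindings) for op in expr.operands)


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Token:
    kind: str          # IDENT, STRING, INT, or a literal punctuation kind
    value: str
    line: int
    col: int


class KBSyntaxError(Exception):
    """Syntax error with 1-based line/column and the offending token text."""

    def __init__(self, message: str, line: int, col: int, token: str = "") -> None:
        self.message = message
        self.line = line
        self.col = col
        self.token = token
        where = f"{line}:{col}"
        tok = f" near {token!r}" if token else ""
        super().__init__(f"{where}: {message}{tok}")


_PUNCT = ("||", "&&", "(", ")", "{", "}", ";", ":", "=", "!", "&", "|")

_KEYWORDS = {"if", "Comment", "Condition", "Where", "Text", "order", "true", "false"}


def _tokenize(source: str) -> Iterator[Token]:
    i, line, col = 0, 1, 1
    n = len(source)
    while i < n:
        ch = source[i]
        if ch == "\n":
            i += 1
            line += 1
            col = 1
            continue
        if ch in " \t\r":
            i += 1
            col += 1
            continue
        if ch == "#":
            while i < n and source[i] != "\n":
                i += 1
            continue
        if ch == '"':
            start_line, start_col = line, col
            i += 1
            col += 1
            parts: list[str] = []
            while True:
                if i >= n:
                    raise KBSyntaxError(
                        "unterminated Text string", start_line, start_col, '"')
                c = source[i]
                if c == "\\" and i + 1 < n and source[i + 1] == '"':
                    parts.append('"')
                    i += 2
                    col += 2
                    continue
                if c == '"':
                    i += 1
                    col += 1
                    break
                if c == "\n":
                    line += 1
                    col = 1
                else:
                    col += 1
                parts.append(c)
                i += 1
            yield Token("STRING", "".join(parts), start_line, start_col)
            continue
        if ch.isdigit():
            start_col = col
            j = i
            while j < n and source[j].isdigit():
                j += 1
            yield Token("INT", source[i:j], line, start_col)
            col += j - i
            i = j
            continue
        if ch.isalpha() or ch == "_":
            start_col = col
            j = i
            while j < n and (source[j].isalnum() or source[j] == "_"):
                j += 1
            word = source[i:j]
            kind = word if word in _KEYWORDS else "IDENT"
            yield Token(kind, word, line, start_col)
            col += j - i
            i = j
            continue
        matched = False
        for punct in _PUNCT:
            if source.startswith(punct, i):
                yield Token(punct, punct, line, col)
                i += len(punct)
                col += len(punct)
                matched = True
                break
        if not matched:
            raise KBSyntaxError("unexpected character", line, col, ch)
    yield Token("EOF", "", line, col)


# ---------------------------------------------------------------------------
# Parser (recursive descent)
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, source: str) -> None:
        self.tokens = list(_tokenize(source))
        self.pos = 0

    @property
    def cur(self) -> Token:
        return self.tokens[self.pos]

    def _advance(self) -> Token:
        tok = self.cur
        self.pos += 1
        return tok

    def _expect(self, kind: str) -> Token:
        tok = self.cur
        if tok.kind != kind:
            raise KBSyntaxError(
                f"expected {kind!r}", tok.line, tok.col, tok.value or "<eof>")
        return self._advance()

    def _ident(self) -> Token:
        tok = self.cur
        # keywords other than the boolean literals are usable as plain
        # identifiers only where the grammar is unambiguous; reject here
        if tok.kind != "IDENT":
            raise KBSyntaxError(
                "expected identifier", tok.line, tok.col, tok.value or "<eof>")
        return self._advance()

    # expression grammar: or > and > not > atom
    def parse_expr(self) -> BoolExpr:
        return self._parse_or()

    def _parse_or(self) -> BoolExpr:
        operands = [self._parse_and()]
        while self.cur.kind in ("||", "|"):
            self._advance()
            operands.append(self._parse_and())
        return operands[0] if len(operands) == 1 else Or(tuple(operands))

    def _parse_and(self) -> BoolExpr:
        operands = [self._parse_not()]
        while self.cur.kind in ("&&", "&"):
            self._advance()
            operands.append(self._parse_not())
        return operands[0] if len(operands) == 1 else And(tuple(operands))

    def _parse_not(self) -> BoolExpr:
        if self.cur.kind == "!":
            self._advance()
            return Not(self._parse_not())
        return self._parse_atom()

    def _parse_atom(self) -> BoolExpr:
        tok = self.cur
        if tok.kind == "(":
            self._advance()
            inner = self.parse_expr()
            self._expect(")")
            return inner
        if tok.kind == "IDENT":
            self._advance()
            return VarRef(tok.value)
        raise KBSyntaxError(
            "expected identifier or '('", tok.line, tok.col,
            tok.value or "<eof>")

    def _parse_bool_literal(self) -> bool:
        tok = self.cur
        if tok.kind not in ("true", "false"):
            raise KBSyntaxError(
                "expected 'true' or 'false'", tok.line, tok.col,
                tok.value or "<eof>")
        self._advance()
        return tok.kind == "true"

    def _parse_rule(self) -> Rule:
        self._expect("if")
        self._expect("(")
        condition = self.parse_expr()
        self._expect(")")
        assignments: list[tuple[str, bool]] = []
        targets_seen: set[str] = set()
        while True:
            tok = self._ident()
            self._expect("=")
            value = self._parse_bool_literal()
            self._expect(";")
            if tok.value in targets_seen:
                raise KBSyntaxError(
                    f"duplicate assignment target {tok.value!r} in one rule",
                    tok.line, tok.col, tok.value)
            targets_seen.add(tok.value)
            assignments.append((tok.value, value))
            # assignments bind to the rule until the next statement begins
            if self.cur.kind != "IDENT":
                break
        return Rule(condition, tuple(assignments))

    def _parse_comment(self) -> ConditionalComment:
        self._expect("Comment")
        name_tok = self._ident()
        self._expect("{")
        routes: list[Route] = []
        while self.cur.kind == "Condition":
            self._advance()
            self._expect(":")
            condition = self.parse_expr()
            self._expect(";")
            self._expect("Where")
            self._expect(":")
            loc_tok = self._ident()
            self._expect("(")
            self._expect("order")
            self._expect(":")
            order_tok = self._expect("INT")
            self._expect(")")
            self._expect(";")
            routes.append(Route(condition,
                                Placement(loc_tok.value, int(order_tok.value))))
        if not routes:
            tok = self.cur
            raise KBSyntaxError(
                "comment block requires at least one Condition/Where route",
                tok.line, tok.col, tok.value or "<eof>")
        self._expect("Text")
        self._expect(":")
        text_tok = self._expect("STRING")
        self._expect("}")
        return ConditionalComment(name_tok.value, tuple(routes), text_tok.value)

    def parse_document(self) -> tuple[tuple[Rule, ...],
                                      tuple[ConditionalComment, ...]]:
        rules: list[Rule] = []
        comments: list[ConditionalComment] = []
        names: dict[str, Token] = {}
        while self.cur.kind != "EOF":
            if self.cur.kind == "if":
                rules.append(self._parse_rule())
            elif self.cur.kind == "Comment":
                name_tok = self.tokens[self.pos + 1]
                comment = self._parse_comment()
                if comment.name in names:
                    raise KBSyntaxError(
                        f"duplicate comment name {comment.name!r}",
                        name_tok.line, name_tok.col, comment.name)
                names[comment.name] = name_tok
                comments.append(comment)
            else:
                tok = self.cur
                raise KBSyntaxError(
                    "expected 'if' or 'Comment'", tok.line, tok.col,
                    tok.value or "<eof>")
        return tuple(rules), tuple(comments)


def parse_kb(source: str,
             declared_inputs: Sequence[str] = (),
             locations: Sequence[str] = ()) -> KnowledgeBase:
    """Parse a KB document into a :class:`KnowledgeBase`.

    ``declared_inputs`` and ``locations`` come from configuration rather
    than from the KB file itself (the extraction layer publishes the input
    variable list; the report layout publishes the location registry).

    Raises :class:`KBSyntaxError` with line/column on malformed input,
    duplicate comment names, or unterminated Text strings.
    """
    rules, comments = _Parser(source).parse_document()
    return KnowledgeBase(rules=rules, comments=comments,
                         declared_inputs=frozenset(declared_inputs),
                         locations=tuple(locations))


# ---------------------------------------------------------------------------
# Pretty printer (round-trips through parse_kb)
# ---------------------------------------------------------------------------

def _fmt_expr(expr: BoolExpr, parent: str = "or") -> str:
    # precedence levels: or < and < not/atom; parenthesize when a looser
    # construct appears under a tighter one
    if isinstance(expr, VarRef):
        return expr.name
    if isinstance(expr, Not):
        return "!" + _fmt_expr(expr.operand, "not")
    if isinstance(expr, And):
        body = " & ".join(_fmt_expr(op, "and") for op in expr.operands)
        # parenthesize under Not, and under And so nesting round-trips
        # (the parser would otherwise flatten a & (b & c) into a & b & c)
        return f"({body})" if parent in ("and", "not") else body
    body = " || ".join(_fmt_expr(op, "and") for op in expr.operands)
    return f"({body})" if parent in ("and", "not") else body


def _quote(text: str) -> str:
    return '"' + text.replace('"', '\\"') + '"'


def pretty_print(kb: KnowledgeBase) -> str:
    """Canonical source text; ``parse_kb(pretty_print(kb))`` is structurally
    equal to ``kb`` up to operator spelling (``&``/``&&``, ``|``/``||``)."""
    lines: list[str] = []
    for rule in kb.rules:
        lines.append(f"if ({_fmt_expr(rule.condition)})")
        for target, value in rule.assignments:
            lines.append(f"    {target} = {'true' if value else 'false'};")
    for comment in kb.comments:
        lines.append(f"Comment {comment.name} {{")
        for route in comment.routes:
            lines.append(
                f"    Condition: {_fmt_expr(route.condition)}; "
                f"Where: {route.placement.location} "
                f"(order: {route.placement.order});")
        lines.append(f"    Text: {_quote(comment.text)}")
        lines.append("}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    code: str        # undefined_variable | use_before_assignment |
                     # unknown_location | unreachable_route | input_reassigned
    message: str
    blocking: bool = True

    def format(self, filename: str = "<kb>") -> str:
        sev = "error" if self.blocking else "warning"
        return f"{filename}: {sev}: [{self.code}] {self.message}"


def validate_kb(kb: KnowledgeBase,
                declared_inputs: Optional[set[str]] = None) -> list[Diagnostic]:
    """Check a parsed KB against the declared-input set and location
    registry.  An empty return means the KB is runnable.

    Diagnostics cover: variables no rule assigns and no input declares;
    variables read by a step earlier than the step that assigns them;
    routes to locations absent from the registry; routes whose condition
    reads a variable nothing can set; inputs that are also rule targets.
    """
    inputs = set(kb.declared_inputs if declared_inputs is None
                 else declared_inputs)
    diags: list[Diagnostic] = []

    assigned: set[str] = set()
    for rule in kb.rules:
        assigned |= {t for t, _ in rule.assignments}
    settable = inputs | assigned

    for target in sorted(assigned & inputs):
        diags.append(Diagnostic(
            "input_reassigned",
            f"variable {target!r} is both a declared input and a rule target"))

    # undefined variables anywhere
    for name in sorted(kb.referenced_vars() - settable - assigned):
        diags.append(Diagnostic(
            "undefined_variable",
            f"variable {name!r} is neither a declared input "
            f"nor assigned by any rule"))

    # use before assignment, in single-pass declaration order
    assigned_so_far: set[str] = set()
    for idx, rule in enumerate(kb.rules):
        for name in sorted(expr_vars(rule.condition)):
            if name in assigned and name not in assigned_so_far \
                    and name not in inputs:
                diags.append(Diagnostic(
                    "use_before_assignment",
                    f"rule {idx + 1} reads {name!r} before any rule "
                    f"assigns it"))
        assigned_so_far |= {t for t, _ in rule.assignments}

    registry = set(kb.locations)
    for comment in kb.comments:
        for route in comment.routes:
            loc = route.placement.location
            if loc not in registry:
                diags.append(Diagnostic(
                    "unknown_location",
                    f"comment {comment.name!r} routes to unknown "
                    f"location {loc!r}"))
            dead = sorted(expr_vars(route.condition) - settable)
            if dead:
                diags.append(Diagnostic(
                    "unreachable_route",
                    f"comment {comment.name!r} has a route reading "
                    f"{dead} which nothing can set", blocking=False))
    return diags


# ---------------------------------------------------------------------------
# Compilation to a stack-machine plan
# ---------------------------------------------------------------------------

# postfix instruction opcodes
LOAD, NOT_OP, AND_OP, OR_OP = "LOAD", "NOT", "AND", "OR"


def _compile_expr(expr: BoolExpr, out: list[tuple[str, object]]) -> None:
    if isinstance(expr, VarRef):
        out.append((LOAD, expr.name))
    elif isinstance(expr, Not):
        _compile_expr(expr.operand, out)
        out.append((NOT_OP, None))
    elif isinstance(expr, And):
        _compile_expr(expr.operands[0], out)
        for op in expr.operands[1:]:
            _compile_expr(op, out)
            out.append((AND_OP, None))
    else:
        _compile_expr(expr.operands[0], out)
        for op in expr.operands[1:]:
            _compile_expr(op, out)
            out.append((OR_OP, None))


def run_program(program: tuple[tuple[str, object], ...],
                bindings: dict[str, bool]) -> bool:
    """Execute a postfix condition program against variable bindings."""
    stack: list[bool] = []
    for opcode, arg in program:
        if opcode == LOAD:
            stack.append(bindings[arg])  # type: ignore[index]
        elif opcode == NOT_OP:
            stack.append(not stack.pop())
        elif opcode == AND_OP:
            b, a = stack.pop(), stack.pop()
            stack.append(a and b)
        else:
            b, a = stack.pop(), stack.pop()
            stack.append(a or b)
    return stack[0]


@dataclass(frozen=True)
class PlanStep:
    """One executable step: a rule ('rule') or one comment route ('route')."""

    kind: str
    program: tuple[tuple[str, object], ...]
    # rule: assignments applied when condition is true
    assignments: tuple[tuple[str, bool], ...] = ()
    # route: placement emitted when condition is true
    comment_name: str = ""
    location: str = ""
    order: int = 0
    text: str = ""
    declaration_index: int = 0


@dataclass(frozen=True)
class EvaluationPlan:
    """Ordered executable steps: every rule in declaration order, then
    every comment route in declaration order.  Immutable once built."""

    steps: tuple[PlanStep, ...]
    declared_inputs: frozenset[str]
    locations: tuple[str, ...]
    derived_vars: tuple[str, ...]

    def serialize(self) -> str:
        """Deterministic text form; identical KBs compile to identical
        serializations."""
        lines: list[str] = []
        for step in self.steps:
            prog = " ".join(op if arg is None else f"{op}:{arg}"
                            for op, arg in step.program)
            if step.kind == "rule":
                assigns = " ".join(
                    f"{t}={'true' if v else 'false'}"
                    for t, v in step.assignments)
                lines.append(f"RULE [{prog}] -> {assigns}")
            else:
                lines.append(
                    f"ROUTE {step.comment_name}#{step.declaration_index} "
                    f"[{prog}] -> {step.location}@{step.order}")
        lines.append("INPUTS " + ",".join(sorted(self.declared_inputs)))
        lines.append("LOCATIONS " + ",".join(self.locations))
        return "\n".join(lines) + "\n"


class CompileError(Exception):
    """Raised when a KB with blocking diagnostics is compiled."""

    def __init__(self, diagnostics: list[Diagnostic]) -> None:
        self.diagnostics = diagnostics
        super().__init__(
            "KB has blocking diagnostics:\n"
            + "\n".join(d.format() for d in diagnostics))


def compile_kb(kb: KnowledgeBase,
               declared_inputs: Optional[set[str]] = None) -> EvaluationPlan:
    """Lower a validated KB into an :class:`EvaluationPlan`.

    Refuses (``CompileError``) if :func:`validate_kb` reports blocking
    diagnostics.  Compilation is deterministic: the same KB always yields
    a byte-identical :meth:`EvaluationPlan.serialize` output.
    """
    blocking = [d for d in validate_kb(kb, declared_inputs) if d.blocking]
    if blocking:
        raise CompileError(blocking)
    inputs = frozenset(kb.declared_inputs if declared_inputs is None
                       else declared_inputs)
    steps: list[PlanStep] = []
    for rule in kb.rules:
        program: list[tuple[str, object]] = []
        _compile_expr(rule.condition, program)
        steps.append(PlanStep(kind="rule", program=tuple(program),
                              assignments=rule.assignments))
    for ci, comment in enumerate(kb.comments):
        for route in comment.routes:
            program = []
            _compile_expr(route.condition, program)
            steps.append(PlanStep(
                kind="route", program=tuple(program),
                comment_name=comment.name,
                location=route.placement.location,
                order=route.placement.order,
                text=comment.text,
                declaration_index=ci))
    return EvaluationPlan(steps=tuple(steps), declared_inputs=inputs,
                          locations=tuple(kb.locations),
                          derived_vars=tuple(kb.derived_vars()))
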