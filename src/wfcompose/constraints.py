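"""Natural-language constraint templates over finite tool traces.

Workflow specifications restrict candidate pipelines with five template
forms, each interpreted over the finite sequence of tools in a pipeline:

====================  ===============================================
template              trace semantics
====================  ===============================================
``use <A>``                       some position matches A
``do not use <A>``                no position matches A
``use <A> only after <B>``        every position matching A is strictly
                                  preceded by some position matching B
``do not use <A> more than once`` at most one position matches A
``do not use <A> directly after <A>``  no two consecutive positions match A
====================  ===============================================

The empty trace satisfies every form except ``use``.  ``only after`` is the
weak reading: B need not occur at all when A never occurs, and B anywhere
before A suffices (not necessarily immediately before).

Fillers (*atoms*) are either concrete tool names or operation-branch
concepts; an operation atom matches a tool when one of the tool's annotated
operations is a descendant-or-equal of the atom's concept, so constraints
can address whole classes of tools ("peptide identification") rather than
instances.

Every constraint also compiles to a small deterministic finite-state
*monitor* whose acceptance on any trace equals the declarative semantics;
the synthesis search runs the product of these monitors and prunes branches
that enter a reject sink.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .errors import (ConstraintSemanticError, ConstraintSyntaxError,
                     LookupError_)
from .ontology import CURIE_RE, Taxonomy

if TYPE_CHECKING:  # pragma: no cover
    from .domain import DomainModel, ToolAnnotation

FORMS = ("USE", "AVOID", "ONLY_AFTER", "AT_MOST_ONCE", "NO_IMMEDIATE_REPEAT")


@dataclass(frozen=True)
class Atom:
    """A constraint filler: a concrete tool or an operation class."""

    kind: str  # "tool" | "operation"
    ref: str   # tool name or operation curie

    def __post_init__(self):
        if self.kind not in ("tool", "operation"):
            raise ConstraintSemanticError(f"bad atom kind {self.kind!r}")


@dataclass(frozen=True)
class Constraint:
    """One instance of the five template forms."""

    form: str
    atoms: tuple[Atom, ...]

    def __post_init__(self):
        if self.form not in FORMS:
            raise ConstraintSyntaxError(f"unknown constraint form {self.form}")
        arity = 2 if self.form == "ONLY_AFTER" else 1
        if len(self.atoms) != arity:
            raise ConstraintSyntaxError(
                f"{self.form} takes {arity} atom(s), got {len(self.atoms)}")


def atom_matches(atom: Atom, tool: "ToolAnnotation",
                 taxonomy: Taxonomy) -> bool:
    """Does ``tool`` instantiate ``atom``?

    Tool atoms require exact name equality; operation atoms hold when some
    annotated operation of the tool is subsumed by the atom's concept.
    """
    if atom.kind == "tool":
        return tool.name == atom.ref
    return any(taxonomy.is_subsumed(op, atom.ref)
               for op in tool.operation_ids)


# -- parsing -------------------------------------------------------------

_TEMPLATES = (
    # order matters: longer templates first
    ("ONLY_AFTER", re.compile(
        r"^use\s+(?P<a>.+?)\s+only\s+after\s+(?P<b>.+)$", re.IGNORECASE)),
    ("NO_IMMEDIATE_REPEAT", re.compile(
        r"^do\s+not\s+use\s+(?P<a>.+?)\s+directly\s+after\s+(?P<b>.+)$",
        re.IGNORECASE)),
    ("AT_MOST_ONCE", re.compile(
        r"^do\s+not\s+use\s+(?P<a>.+?)\s+more\s+than\s+once$", re.IGNORECASE)),
    ("AVOID", re.compile(r"^do\s+not\s+use\s+(?P<a>.+)$", re.IGNORECASE)),
    ("USE", re.compile(r"^use\s+(?P<a>.+)$", re.IGNORECASE)),
)


def _resolve_atom(text: str, model: "DomainModel") -> Atom:
    """Resolve a filler as a tool name, an operation curie, or a label."""
    text = text.strip()
    if text in model.tools:
        return Atom("tool", text)
    if CURIE_RE.match(text):
        concept = model.taxonomy.concepts.get(text)
        if concept is None:
            raise ConstraintSemanticError(
                f"constraint filler {text!r} does not resolve in the "
                f"taxonomy")
        if concept.branch != "operation":
            raise ConstraintSemanticError(
                f"constraint filler {text!r} is a {concept.branch} concept; "
                f"only tools and operations may be used")
        return Atom("operation", text)
    # fall back to an unambiguous operation label
    try:
        return Atom("operation",
                    model.taxonomy.resolve_label(text, branch="operation"))
    except LookupError_:
        raise ConstraintSemanticError(
            f"constraint filler {text!r} is neither a tool name, an "
            f"operation curie, nor an unambiguous operation label") from None


def parse_constraint(text: str, model: "DomainModel") -> Constraint:
    """Parse one template string against a domain model."""
    stripped = text.strip()
    for form, pattern in _TEMPLATES:
        m = pattern.match(stripped)
        if m is None:
            continue
        if form == "NO_IMMEDIATE_REPEAT":
            a, b = m.group("a"), m.group("b")
            if a.strip() != b.strip():
                raise ConstraintSyntaxError(
                    f"{text!r}: 'directly after' is only supported with the "
                    f"same filler twice (non-repetition)")
            return Constraint(form, (_resolve_atom(a, model),))
        if form == "ONLY_AFTER":
            return Constraint(form, (_resolve_atom(m.group("a"), model),
                                     _resolve_atom(m.group("b"), model)))
        return Constraint(form, (_resolve_atom(m.group("a"), model),))
    raise ConstraintSyntaxError(
        f"{text!r} matches none of the five templates "
        f"(use A | do not use A | use A only after B | "
        f"do not use A more than once | do not use A directly after A)")


def constraint_to_text(constraint: Constraint) -> str:
    """Inverse of :func:`parse_constraint` (canonical spelling)."""
    refs = [a.ref for a in constraint.atoms]
    if constraint.form == "USE":
        return f"use {refs[0]}"
    if constraint.form == "AVOID":
        return f"do not use {refs[0]}"
    if constraint.form == "ONLY_AFTER":
        return f"use {refs[0]} only after {refs[1]}"
    if constraint.form == "AT_MOST_ONCE":
        return f"do not use {refs[0]} more than once"
    return f"do not use {refs[0]} directly after {refs[0]}"


# -- declarative evaluation ---------------------------------------------

def evaluate_trace(constraint: Constraint, trace, model: "DomainModel",
                   ) -> bool:
    """Evaluate ``constraint`` on a finite sequence of tool names."""
    tax = model.taxonomy
    hits = [tuple(atom_matches(a, model.tool(name), tax)
                  for a in constraint.atoms)
            for name in trace]
    form = constraint.form
    if form == "USE":
        return any(h[0] for h in hits)
    if form == "AVOID":
        return not any(h[0] for h in hits)
    if form == "AT_MOST_ONCE":
        return sum(h[0] for h in hits) <= 1
    if form == "NO_IMMEDIATE_REPEAT":
        return not any(hits[i][0] and hits[i + 1][0]
                       for i in range(len(hits) - 1))
    # ONLY_AFTER(A, B): every A strictly preceded by some B
    seen_b = False
    for a_hit, b_hit in hits:
        if a_hit and not seen_b:
            return False
        if b_hit:
            seen_b = True
    return True


# -- monitors ------------------------------------------------------------

class ConstraintMonitor:
    """Deterministic, total finite-state acceptor equivalent to a constraint.

    States are small integers.  ``step`` consumes the atom truth-vector of
    one trace position.  ``reject_sink`` states can never recover and are
    pruned during synthesis; a non-accepting, non-sink state (the initial
    state of USE) may still be completed to acceptance.
    """

    def __init__(self, constraint: Constraint):
        self.constraint = constraint
        self.initial = 0
        form = constraint.form
        if form in ("USE", "AVOID"):
            self.n_states = 2
        else:
            self.n_states = 3

    def step(self, state: int, hit: tuple[bool, ...]) -> int:
        form = self.constraint.form
        a = hit[0]
        if form == "USE":
            return 1 if (state == 1 or a) else 0
        if form == "AVOID":
            return 1 if (state == 1 or a) else 0  # 1 = reject sink
        if form == "AT_MOST_ONCE":
            if state == 2:
                return 2
            if a:
                return state + 1  # 0 -> 1 -> 2 (sink)
            return state
        if form == "NO_IMMEDIATE_REPEAT":
            if state == 2:
                return 2
            if a:
                return 2 if state == 1 else 1
            return 0
        # ONLY_AFTER: 0 = no B yet, 1 = B seen, 2 = reject sink
        b = hit[1]
        if state == 2:
            return 2
        if state == 0 and a:
            return 2
        if b:
            return 1
        return state

    def is_accepting(self, state: int) -> bool:
        form = self.constraint.form
        if form == "USE":
            return state == 1
        if form == "AVOID":
            return state == 0
        return state != 2

    def is_reject_sink(self, state: int) -> bool:
        form = self.constraint.form
        if form == "USE":
            return False
        if form == "AVOID":
            return state == 1
        return state == 2

    def accepts(self, trace, model: "DomainModel") -> bool:
        """Run the monitor over a full trace of tool names."""
        tax = model.taxonomy
        state = self.initial
        for name in trace:
            hit = tuple(atom_matches(a, model.tool(name), tax)
                        for a in self.constraint.atoms)
            state = self.step(state, hit)
        return self.is_accepting(state)


def compile_monitor(constraint: Constraint) -> ConstraintMonitor:
    """Build the executable monitor for a constraint."""
    return ConstraintMonitor(constraint)
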