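"""Bounded enumeration of constraint-satisfying linear tool pipelines.

Given a domain model and a workflow specification (initial data state, goal
data/format class, temporal constraints, length bound), ``synthesize``
returns *every* pipeline of length at most the bound whose

* steps are type-compatible (each tool accepts the flowing data item and
  emits one of its declared output formats),
* final state satisfies the goal under subsumption, and
* tool sequence satisfies all specification and global constraints.

Search strategy
---------------
The search is breadth-first over the product of the concrete data state and
the joint constraint-monitor state, layered by pipeline length.  Product
states are deduplicated within each layer, so the number of expanded nodes
is bounded by ``|reachable data states| x prod(monitor sizes) x bound``;
branches whose monitor vector contains a reject sink are cut immediately.
Individual solutions (which may vastly outnumber product states) are then
recovered by walking the layered transition graph, and counted in closed
form by dynamic programming where only counts are needed.

Solutions are *state-annotated paths*: the same tool sequence routed
through different intermediate formats yields distinct solutions, matching
a path count over graphs whose nodes are concrete data items.  Callers who
want distinct tool sequences can deduplicate via
:meth:`SolutionSet.tool_sequences`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .constraints import (Constraint, atom_matches, compile_monitor,
                          constraint_to_text, evaluate_trace, parse_constraint)
from .domain import DataState, DomainModel, compatible, successors
from .errors import ValidationError
from .ontology import FORMAT_ROOT

MODES = ("shortest_only", "up_to_bound")


@dataclass(frozen=True)
class WorkflowSpec:
    """Declarative pipeline specification.

    ``goal_format_id`` is class-level; the format-branch root means "any
    format".  ``mode`` selects between returning only the first (shortest)
    non-empty solution length and everything up to ``max_length``.
    """

    initial: DataState
    goal_data_id: str
    goal_format_id: str = FORMAT_ROOT
    constraints: tuple[Constraint, ...] = ()
    max_length: int = 4
    mode: str = "shortest_only"

    def validate(self, model: DomainModel) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.max_length < 1:
            raise ValidationError("max_length must be >= 1")
        tax = model.taxonomy
        self.initial.validate(tax)
        if self.goal_data_id not in tax:
            raise ValidationError(
                f"unknown goal data concept {self.goal_data_id}")
        if tax.get(self.goal_data_id).branch != "data":
            raise ValidationError(
                f"goal data concept {self.goal_data_id} is not in the "
                f"data branch")
        if self.goal_format_id not in tax:
            raise ValidationError(
                f"unknown goal format concept {self.goal_format_id}")
        if tax.get(self.goal_format_id).branch != "format":
            raise ValidationError(
                f"goal format concept {self.goal_format_id} is not in the "
                f"format branch")


@dataclass(frozen=True)
class Solution:
    """A state-annotated pipeline: n tools and n+1 data states."""

    tools: tuple[str, ...]
    states: tuple[DataState, ...]

    def __post_init__(self):
        if len(self.states) != len(self.tools) + 1:
            raise ValidationError(
                "solution must carry one state per step plus the initial "
                "state")

    def __len__(self) -> int:
        return len(self.tools)

    def sort_key(self):
        return (len(self.tools), self.tools,
                tuple(s.format_id for s in self.states),
                tuple(s.data_id for s in self.states))


@dataclass
class SolutionSet:
    """All solutions of a synthesis run, in deterministic order."""

    spec: WorkflowSpec
    solutions: tuple[Solution, ...]
    explored_nodes: int
    searched_depth: int

    def __post_init__(self):
        ordered = sorted(self.solutions, key=Solution.sort_key)
        if len(set(ordered)) != len(ordered):
            raise ValidationError("duplicate solutions in solution set")
        self.solutions = tuple(ordered)

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self) -> Iterator[Solution]:
        return iter(self.solutions)

    def counts_by_length(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.solutions:
            out[len(s)] = out.get(len(s), 0) + 1
        return out

    def tool_sequences(self) -> tuple[tuple[str, ...], ...]:
        """Distinct tool sequences, ignoring intermediate-format routing."""
        return tuple(sorted({s.tools for s in self.solutions},
                            key=lambda t: (len(t), t)))

    def of_length(self, n: int) -> tuple[Solution, ...]:
        return tuple(s for s in self.solutions if len(s) == n)


# -- layered product search ---------------------------------------------

class _Search:
    """Layered BFS over (DataState, monitor-state vector)."""

    def __init__(self, model: DomainModel, spec: WorkflowSpec):
        self.model = model
        self.spec = spec
        self.constraints = tuple(spec.constraints) + tuple(
            model.global_constraints)
        self.monitors = tuple(compile_monitor(c) for c in self.constraints)
        self._hit_cache: dict[str, tuple[tuple[bool, ...], ...]] = {}
        root = (spec.initial, tuple(m.initial for m in self.monitors))
        # layers[l]: set of product nodes reachable by length-l pipelines
        self.layers: list[set] = [{root}]
        # edges[l]: node -> sorted list of (tool, next_node), l -> l+1
        self.edges: list[dict] = []
        self.explored = 0

    def _tool_hits(self, name: str) -> tuple[tuple[bool, ...], ...]:
        hits = self._hit_cache.get(name)
        if hits is None:
            tool = self.model.tool(name)
            hits = tuple(
                tuple(atom_matches(a, tool, self.model.taxonomy)
                      for a in c.atoms)
                for c in self.constraints)
            self._hit_cache[name] = hits
        return hits

    def _is_goal(self, node) -> bool:
        state, mstates = node
        tax = self.model.taxonomy
        if not tax.is_subsumed(state.data_id, self.spec.goal_data_id):
            return False
        if not tax.is_subsumed(state.format_id, self.spec.goal_format_id):
            return False
        return all(m.is_accepting(s)
                   for m, s in zip(self.monitors, mstates))

    def extend(self) -> None:
        """Expand one more layer."""
        frontier = self.layers[-1]
        nxt: set = set()
        edge_map: dict = {}
        for node in sorted(frontier,
                           key=lambda n: (n[0], n[1])):
            state, mstates = node
            self.explored += 1
            outs = []
            for tool_name, succ_state in successors(self.model, state):
                hits = self._tool_hits(tool_name)
                new_mstates = tuple(
                    m.step(s, h)
                    for m, s, h in zip(self.monitors, mstates, hits))
                if any(m.is_reject_sink(s)
                       for m, s in zip(self.monitors, new_mstates)):
                    continue
                succ = (succ_state, new_mstates)
                outs.append((tool_name, succ))
                nxt.add(succ)
            edge_map[node] = outs
        self.edges.append(edge_map)
        self.layers.append(nxt)

    def goal_nodes(self, length: int):
        return sorted((n for n in self.layers[length] if self._is_goal(n)),
                      key=lambda n: (n[0], n[1]))

    def count_paths(self, length: int) -> int:
        """DP count of root-to-goal paths of exactly ``length`` steps."""
        goal = set(self.goal_nodes(length))
        if not goal:
            return 0
        back = {n: 1 for n in goal}
        for l in range(length - 1, -1, -1):
            nxt_back = back
            back = {}
            for node, outs in self.edges[l].items():
                total = sum(nxt_back.get(succ, 0) for _, succ in outs)
                if total:
                    back[node] = total
        root = next(iter(self.layers[0]))
        return back.get(root, 0)

    def enumerate(self, length: int) -> list[Solution]:
        """All root-to-goal paths of exactly ``length`` steps."""
        goal = set(self.goal_nodes(length))
        if not goal:
            return []
        # prune to nodes that can still reach a goal node
        alive: list[set] = [set() for _ in range(length + 1)]
        alive[length] = goal
        for l in range(length - 1, -1, -1):
            for node, outs in self.edges[l].items():
                if any(succ in alive[l + 1] for _, succ in outs):
                    alive[l].add(node)
        root = next(iter(self.layers[0]))
        if root not in alive[0]:
            return []
        sols: list[Solution] = []
        tools: list[str] = []
        states: list[DataState] = [root[0]]

        def walk(node, depth: int) -> None:
            if depth == length:
                sols.append(Solution(tuple(tools), tuple(states)))
                return
            for tool_name, succ in self.edges[depth][node]:
                if succ not in alive[depth + 1]:
                    continue
                tools.append(tool_name)
                states.append(succ[0])
                walk(succ, depth + 1)
                tools.pop()
                states.pop()

        walk(root, 0)
        return sols


def synthesize(model: DomainModel, spec: WorkflowSpec) -> SolutionSet:
    """Enumerate all solutions of ``spec`` against ``model``.

    In ``shortest_only`` mode the returned set contains only solutions of
    the smallest length (possibly zero) at which any exist; in
    ``up_to_bound`` mode, all lengths up to ``spec.max_length``.  An
    unreachable goal yields an empty set whose ``searched_depth`` reports
    how far the search ran.
    """
    spec.validate(model)
    search = _Search(model, spec)
    solutions: list[Solution] = []
    found_at: int | None = None
    for length in range(0, spec.max_length + 1):
        if length > 0:
            search.extend()
        layer_solutions = search.enumerate(length)
        if layer_solutions:
            found_at = length if found_at is None else found_at
            solutions.extend(layer_solutions)
            if spec.mode == "shortest_only":
                break
    return SolutionSet(spec=spec, solutions=tuple(solutions),
                       explored_nodes=search.explored,
                       searched_depth=min(len(search.layers) - 1,
                                          spec.max_length))


def find_min_length(model: DomainModel, spec: WorkflowSpec,
                    cap: int) -> int | None:
    """Smallest pipeline length up to ``cap`` admitting a solution."""
    if cap < 1:
        raise ValidationError("cap must be >= 1")
    probe = WorkflowSpec(initial=spec.initial,
                         goal_data_id=spec.goal_data_id,
                         goal_format_id=spec.goal_format_id,
                         constraints=spec.constraints,
                         max_length=cap,
                         mode="shortest_only")
    probe.validate(model)
    search = _Search(model, probe)
    for length in range(0, cap + 1):
        if length > 0:
            search.extend()
        if search.count_paths(length):
            return length
    return None


# -- independent validation ---------------------------------------------

def validate_solution(model: DomainModel, spec: WorkflowSpec,
                      candidate: Solution) -> tuple[bool, list[str]]:
    """Check every solution invariant; return (ok, violation report).

    Used by tests and the CLI as an independent checker: it never consults
    the search machinery, only the declarative definitions.
    """
    report: list[str] = []
    tax = model.taxonomy
    if len(candidate.states) != len(candidate.tools) + 1:
        return False, ["malformed solution: state/tool count mismatch"]
    if candidate.states[0] != spec.initial:
        report.append(
            f"initial state {candidate.states[0]} differs from the "
            f"specification input {spec.initial}")
    if len(candidate) > spec.max_length:
        report.append(
            f"length {len(candidate)} exceeds the bound {spec.max_length}")
    for i, name in enumerate(candidate.tools):
        if name not in model:
            report.append(f"step {i + 1}: unknown tool {name!r}")
            continue
        tool = model.tool(name)
        if not compatible(tool, candidate.states[i], tax):
            report.append(
                f"step {i + 1}: {name} cannot consume "
                f"{candidate.states[i]}")
        succ = candidate.states[i + 1]
        if succ.data_id != tool.output.data_id or \
                succ.format_id not in tool.output.format_ids:
            report.append(
                f"step {i + 1}: {succ} is not a declared output state "
                f"of {name}")
    final = candidate.states[-1]
    if not (tax.is_subsumed(final.data_id, spec.goal_data_id)
            and tax.is_subsumed(final.format_id, spec.goal_format_id)):
        report.append(
            f"final state {final} does not satisfy the goal "
            f"({spec.goal_data_id} in {spec.goal_format_id})")
    if all(name in model for name in candidate.tools):
        for c in tuple(spec.constraints) + tuple(model.global_constraints):
            if not evaluate_trace(c, candidate.tools, model):
                report.append(
                    f"constraint violated: {constraint_to_text(c)}")
    return (not report), report


def annotate_tool_sequence(model: DomainModel, spec: WorkflowSpec,
                           tools: tuple[str, ...] | list[str],
                           ) -> list[Solution]:
    """All state annotations lifting a bare tool sequence to solutions.

    Returns every structurally consistent assignment of intermediate states
    (the constraint and goal checks are left to
    :func:`validate_solution`).  Empty when the sequence is not
    type-compatible from the specification input.
    """
    lifts: list[Solution] = []

    def walk(i: int, states: list[DataState]) -> None:
        if i == len(tools):
            lifts.append(Solution(tuple(tools), tuple(states)))
            return
        tool = model.tool(tools[i])
        if not compatible(tool, states[-1], model.taxonomy):
            return
        for f in sorted(tool.output.format_ids):
            walk(i + 1, states + [DataState(tool.output.data_id, f)])

    walk(0, [spec.initial])
    return lifts


# -- specification files -------------------------------------------------

def load_spec(path: str | Path, model: DomainModel) -> WorkflowSpec:
    """Read a specification JSON file.

    Fields: ``input {data, format}``, ``output {data, format}``,
    ``constraints`` (template strings), ``max_length``, ``mode``.
    """
    p = Path(path)
    try:
        doc = json.loads(p.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{p}: invalid JSON: {exc}") from None
    for key in ("input", "output"):
        if key not in doc or "data" not in doc[key]:
            raise ValidationError(f"{p}: missing {key}.data")
    spec = WorkflowSpec(
        initial=DataState(doc["input"]["data"], doc["input"]["format"]),
        goal_data_id=doc["output"]["data"],
        goal_format_id=doc["output"].get("format", FORMAT_ROOT),
        constraints=tuple(parse_constraint(t, model)
                          for t in doc.get("constraints", [])),
        max_length=int(doc.get("max_length", 4)),
        mode=doc.get("mode", "shortest_only"),
    )
    spec.validate(model)
    return spec


def save_spec(spec: WorkflowSpec, path: str | Path) -> None:
    doc = {
        "input": {"data": spec.initial.data_id,
                  "format": spec.initial.format_id},
        "output": {"data": spec.goal_data_id,
                   "format": spec.goal_format_id},
        "constraints": [constraint_to_text(c) for c in spec.constraints],
        "max_length": spec.max_length,
        "mode": spec.mode,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
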