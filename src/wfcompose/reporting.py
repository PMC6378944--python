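"""Automata-like solution graphs and tabular exports.

A fixed-length set of solutions merges naturally into a layered directed
graph whose nodes are concrete data items (EDAM Data + Format) at a given
step index and whose edges are labelled with tool names.  Every
input-to-output path through the merged graph is a valid workflow, and the
number of such paths equals the number of solutions — merging is per step
index precisely so that this identity holds (merging equal data states
reached at different depths could create spurious paths).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .domain import DataState, DomainModel
from .errors import ValidationError
from .synthesis import Solution, SolutionSet


@dataclass(frozen=True)
class GraphNode:
    """A data item at a fixed step index (or a per-solution copy)."""

    step: int
    state: DataState
    solution_index: int | None = None  # None in merged graphs

    def sort_key(self):
        return (self.step,
                -1 if self.solution_index is None else self.solution_index,
                self.state)


class SolutionGraph:
    """Directed multigraph over :class:`GraphNode` with tool-labelled edges."""

    def __init__(self, graph: nx.MultiDiGraph, length: int,
                 input_nodes: tuple[GraphNode, ...],
                 output_nodes: tuple[GraphNode, ...]):
        self.graph = graph
        self.length = length
        self.input_nodes = input_nodes
        self.output_nodes = output_nodes

    def count_paths(self) -> int:
        """Input-to-output path count by dynamic programming over layers."""
        back = {n: 1 for n in self.output_nodes}
        for step in range(self.length - 1, -1, -1):
            nxt = back
            back = {}
            for u, v, _key in self.graph.edges(keys=True):
                if u.step == step and v in nxt:
                    back[u] = back.get(u, 0) + nxt[v]
        return sum(back.get(n, 0) for n in self.input_nodes)

    def paths(self):
        """Yield every input-to-output path as a :class:`Solution`."""
        adj: dict[GraphNode, list[tuple[str, GraphNode]]] = {}
        for u, v, key in sorted(self.graph.edges(keys=True),
                                key=lambda e: (e[0].sort_key(), e[2],
                                               e[1].sort_key())):
            adj.setdefault(u, []).append((key, v))

        def walk(node, tools, states):
            if node.step == self.length:
                if node in self.output_nodes:
                    yield Solution(tuple(tools), tuple(states))
                return
            for tool, succ in adj.get(node, []):
                yield from walk(succ, tools + [tool],
                                states + [succ.state])

        for start in self.input_nodes:
            yield from walk(start, [], [start.state])


def build_solution_graph(solutions: SolutionSet,
                         merge: bool = True) -> SolutionGraph:
    """Merge (or chain) a solution set into a :class:`SolutionGraph`.

    ``merge=True`` requires all solutions to share one length and collapses
    nodes with identical data state at the same step index; ``merge=False``
    keeps one disjoint chain per solution.
    """
    if not len(solutions):
        raise ValidationError("cannot build a graph from an empty "
                              "solution set")
    lengths = sorted({len(s) for s in solutions})
    if merge and len(lengths) > 1:
        raise ValidationError(
            f"merged graphs need solutions of uniform length, got lengths "
            f"{lengths}; filter the set (e.g. SolutionSet.of_length) first")
    length = lengths[-1]
    g: nx.MultiDiGraph = nx.MultiDiGraph()
    inputs: set[GraphNode] = set()
    outputs: set[GraphNode] = set()
    for idx, sol in enumerate(solutions):
        tag = None if merge else idx
        nodes = [GraphNode(i, st, tag)
                 for i, st in enumerate(sol.states)]
        for n in nodes:
            g.add_node(n)
        for i, tool in enumerate(sol.tools):
            # multigraph key = tool name; parallel same-tool edges collapse
            g.add_edge(nodes[i], nodes[i + 1], key=tool)
        inputs.add(nodes[0])
        outputs.add(nodes[-1])
    return SolutionGraph(
        g, length,
        tuple(sorted(inputs, key=GraphNode.sort_key)),
        tuple(sorted(outputs, key=GraphNode.sort_key)))


# -- DOT -----------------------------------------------------------------

def _node_id(node: GraphNode) -> str:
    sol = "" if node.solution_index is None else f"s{node.solution_index}_"
    data = node.state.data_id.replace(":", "_")
    fmt = node.state.format_id.replace(":", "_")
    return f"{sol}step{node.step}_{data}_{fmt}"


def to_dot(graph: SolutionGraph, model: DomainModel | None = None) -> str:
    """Deterministic DOT serialisation.

    Node labels show the data and format terms (preferred labels when a
    domain model is supplied, curies otherwise); edge labels show tools.
    """
    def term(curie: str) -> str:
        if model is not None and curie in model.taxonomy:
            return model.taxonomy.get(curie).label
        return curie

    lines = ["digraph solutions {", "  rankdir=LR;",
             "  node [shape=box];"]
    for node in sorted(graph.graph.nodes, key=GraphNode.sort_key):
        shape = ""
        if node in graph.input_nodes:
            shape = ", shape=ellipse, peripheries=2"
        elif node in graph.output_nodes:
            shape = ", shape=ellipse"
        label = f"{term(node.state.data_id)}\\n{term(node.state.format_id)}"
        lines.append(f'  {_node_id(node)} [label="{label}"{shape}];')
    for u, v, key in sorted(graph.graph.edges(keys=True),
                            key=lambda e: (e[0].sort_key(), e[1].sort_key(),
                                           e[2])):
        lines.append(f'  {_node_id(u)} -> {_node_id(v)} [label="{key}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


# -- tables and skeletons ------------------------------------------------

TABLE_HEADER = "length\ttools\tformats"


def solutions_to_table(solutions: SolutionSet) -> str:
    """One TSV row per solution: length, tool chain, format chain."""
    rows = [TABLE_HEADER]
    for s in solutions:
        rows.append("\t".join((
            str(len(s)),
            " -> ".join(s.tools),
            " -> ".join(st.format_id for st in s.states),
        )))
    return "\n".join(rows) + "\n"


def export_skeleton(solution: Solution,
                    model: DomainModel | None = None) -> str:
    """Placeholder command list for a solution.

    One line per tool with the surrounding data formats as comments.  The
    skeleton is explicitly not executable: tool parameters must be supplied
    by the user.
    """
    def term(curie: str) -> str:
        if model is not None and curie in model.taxonomy:
            return model.taxonomy.get(curie).label
        return curie

    lines = [
        "#!/bin/sh",
        "# Workflow skeleton - NOT executable as-is: fill in tool paths,",
        "# parameters and file names before running.",
    ]
    for i, tool in enumerate(solution.tools):
        src = solution.states[i]
        dst = solution.states[i + 1]
        lines.append(
            f"# step {i + 1}: {term(src.format_id)} -> "
            f"{term(dst.format_id)} ({term(dst.data_id)})")
        lines.append(f"{tool} <INPUT_{i}> <OUTPUT_{i + 1}>  # TODO: "
                     f"parameters")
    return "\n".join(lines) + "\n"
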