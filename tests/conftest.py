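"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from wfcompose import fixtures
from wfcompose.constraints import Atom, Constraint, evaluate_trace
from wfcompose.domain import DataState, DomainModel, compatible
from wfcompose.synthesis import Solution, WorkflowSpec


@pytest.fixture(scope="session")
def taxonomy():
    return fixtures.paper_taxonomy()


@pytest.fixture(scope="session")
def model(taxonomy):
    return fixtures.paper_domain(taxonomy)


@pytest.fixture(scope="session")
def specs(model):
    return {uc: fixtures.paper_spec(uc, model) for uc in (1, 2, 3, 4)}


# -- brute-force synthesis oracle ----------------------------------------

def brute_force_solutions(model: DomainModel,
                          spec: WorkflowSpec) -> list[Solution]:
    """Enumerate all tool/state sequences up to the bound and filter by the
    declarative solution invariants.  Independent of the product-automaton
    search: no monitors, no layering, no deduplication."""
    tax = model.taxonomy
    constraints = tuple(spec.constraints) + tuple(model.global_constraints)

    def is_goal(state: DataState) -> bool:
        return (tax.is_subsumed(state.data_id, spec.goal_data_id)
                and tax.is_subsumed(state.format_id, spec.goal_format_id))

    found: list[Solution] = []

    def rec(tools: list[str], states: list[DataState]) -> None:
        if is_goal(states[-1]) and all(
                evaluate_trace(c, tools, model) for c in constraints):
            found.append(Solution(tuple(tools), tuple(states)))
        if len(tools) == spec.max_length:
            return
        for name in sorted(model.tools):
            tool = model.tools[name]
            if not compatible(tool, states[-1], tax):
                continue
            for f in sorted(tool.output.format_ids):
                rec(tools + [name],
                    states + [DataState(tool.output.data_id, f)])

    rec([], [spec.initial])
    if spec.mode == "shortest_only" and found:
        shortest = min(len(s) for s in found)
        found = [s for s in found if len(s) == shortest]
    return sorted(found, key=Solution.sort_key)


# -- random constraint/spec helpers for property tests -------------------

def random_constraint(rng: random.Random, model: DomainModel) -> Constraint:
    ops = sorted(model.taxonomy.branch_concepts("operation"))
    tools = sorted(model.tools)
    atoms = ops + tools

    def atom() -> Atom:
        ref = rng.choice(atoms)
        return Atom("tool" if ref in model.tools else "operation", ref)

    form = rng.choice(("USE", "AVOID", "ONLY_AFTER", "AT_MOST_ONCE",
                       "NO_IMMEDIATE_REPEAT"))
    if form == "ONLY_AFTER":
        return Constraint(form, (atom(), atom()))
    return Constraint(form, (atom(),))


def random_spec(rng: random.Random, model: DomainModel,
                n_constraints: int = 2, max_length: int = 4,
                mode: str = "up_to_bound") -> WorkflowSpec:
    data = sorted(model.taxonomy.branch_concepts("data"))
    formats = sorted(model.taxonomy.branch_concepts("format"))
    return WorkflowSpec(
        initial=DataState(rng.choice(data), rng.choice(formats)),
        goal_data_id=rng.choice(data),
        goal_format_id=rng.choice(formats),
        constraints=tuple(random_constraint(rng, model)
                          for _ in range(rng.randint(0, n_constraints))),
        max_length=max_length,
        mode=mode,
    )
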