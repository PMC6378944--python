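"""Bounded synthesis: oracle equivalence, invariants, validation."""

import random

import pytest

from wfcompose.constraints import parse_constraint
from wfcompose.domain import (DataState, DomainModel, PortSpec,
                              ToolAnnotation)
from wfcompose.errors import ValidationError
from wfcompose.fixtures import RandomDomainConfig, random_domain
from wfcompose.reporting import solutions_to_table
from wfcompose.synthesis import (Solution, WorkflowSpec,
                                 annotate_tool_sequence, find_min_length,
                                 synthesize, validate_solution)

from conftest import brute_force_solutions, random_spec


def _spec(model, initial, goal_data, goal_format="format:1915",
          constraints=(), max_length=4, mode="up_to_bound"):
    return WorkflowSpec(
        initial=initial, goal_data_id=goal_data,
        goal_format_id=goal_format,
        constraints=tuple(parse_constraint(c, model) for c in constraints),
        max_length=max_length, mode=mode)


class TestDegenerateCases:
    def test_identity_goal_yields_empty_solution(self, model):
        spec = _spec(model, DataState("data:0943", "format:3712"),
                     "data:0943", mode="shortest_only")
        result = synthesize(model, spec)
        assert len(result) == 1
        assert result.solutions[0].tools == ()
        assert result.solutions[0].states == (spec.initial,)

    def test_single_tool_model(self, taxonomy):
        tool = ToolAnnotation(
            "conv", ("operation:0335",),
            PortSpec("data:0943", ("format:3712",)),
            PortSpec("data:0943", ("format:3244",)))
        m = DomainModel(taxonomy, [tool])
        spec = WorkflowSpec(DataState("data:0943", "format:3712"),
                            "data:0943", "format:3244", (), 3,
                            "shortest_only")
        result = synthesize(m, spec)
        assert [s.tools for s in result] == [("conv",)]

    def test_unreachable_goal_reports_depth_not_exception(self, model):
        spec = _spec(model, DataState("data:1506", "format:3475"),
                     "data:0943", max_length=3)
        result = synthesize(model, spec)
        assert len(result) == 0
        assert result.searched_depth == 3
        assert find_min_length(model, spec, 3) is None

    def test_invalid_spec_rejected(self, model):
        with pytest.raises(ValidationError, match="max_length"):
            synthesize(model, WorkflowSpec(
                DataState("data:0943", "format:3712"), "data:1506",
                max_length=0))


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["up_to_bound", "shortest_only"])
    def test_random_models_match_brute_force(self, mode):
        rng = random.Random(424242)
        nonempty = 0
        for seed in range(60):
            cfg = RandomDomainConfig(seed=seed, n_tools=rng.randint(2, 6),
                                     n_data=3, n_formats=3,
                                     max_formats_per_port=3)
            m = random_domain(cfg)
            spec = random_spec(rng, m, max_length=rng.randint(1, 4),
                               mode=mode)
            got = list(synthesize(m, spec))
            expected = brute_force_solutions(m, spec)
            assert got == expected, f"seed {seed}"
            nonempty += bool(expected)
        assert nonempty >= 5  # the sample must exercise non-trivial cases

    def test_fixture_use_cases_match_brute_force(self, model, specs):
        for uc in (1, 3, 4):
            got = list(synthesize(model, specs[uc]))
            assert got == brute_force_solutions(model, specs[uc])


class TestInvariants:
    def test_bound_monotonicity(self):
        rng = random.Random(99)
        for seed in range(25):
            m = random_domain(RandomDomainConfig(seed=seed, n_tools=4))
            spec3 = random_spec(rng, m, max_length=3)
            spec4 = WorkflowSpec(spec3.initial, spec3.goal_data_id,
                                 spec3.goal_format_id, spec3.constraints,
                                 4, "up_to_bound")
            assert set(synthesize(m, spec3)) <= set(synthesize(m, spec4))

    def test_constraint_anti_monotonicity(self, model, specs):
        base = specs[1]
        widened = WorkflowSpec(base.initial, base.goal_data_id,
                               base.goal_format_id, base.constraints[:-1],
                               4, "up_to_bound")
        narrowed = WorkflowSpec(base.initial, base.goal_data_id,
                                base.goal_format_id, base.constraints,
                                4, "up_to_bound")
        assert set(synthesize(model, narrowed)) <= \
            set(synthesize(model, widened))

    def test_determinism_byte_identical(self, model, specs):
        a = solutions_to_table(synthesize(model, specs[1]))
        b = solutions_to_table(synthesize(model, specs[1]))
        assert a.encode() == b.encode()

    def test_explored_nodes_bounded_by_product_automaton(self, model,
                                                         specs):
        for uc in (1, 2, 3, 4):
            spec = specs[uc]
            result = synthesize(model, spec)
            n_states = (len(model.taxonomy.branch_concepts("data"))
                        * len(model.taxonomy.branch_concepts("format")))
            product = 1
            from wfcompose.constraints import compile_monitor
            for c in tuple(spec.constraints) + tuple(
                    model.global_constraints):
                product *= compile_monitor(c).n_states
            assert result.explored_nodes <= n_states * product * \
                max(1, spec.max_length)


class TestValidateSolution:
    def test_listed_uc2_workflow_passes(self, model, specs):
        seq = ("msconvert", "Comet", "PeptideProphet", "ProteinProphet",
               "extract_protein_names", "GeneTrail2")
        lifts = annotate_tool_sequence(model, specs[2], seq)
        assert lifts
        assert any(validate_solution(model, specs[2], s)[0] for s in lifts)

    def test_swapped_prophets_fail_with_only_after(self, model, specs):
        good = next(s for s in annotate_tool_sequence(
            model, specs[2],
            ("msconvert", "Comet", "PeptideProphet", "ProteinProphet",
             "extract_protein_names", "GeneTrail2"))
            if validate_solution(model, specs[2], s)[0])
        tools = list(good.tools)
        tools[2], tools[3] = tools[3], tools[2]
        bad = Solution(tuple(tools), good.states)
        ok, report = validate_solution(model, specs[2], bad)
        assert not ok
        assert any("only after PeptideProphet" in line for line in report)

    def test_every_synthesized_solution_validates(self, model, specs):
        for uc in (1, 2, 3, 4):
            for sol in synthesize(model, specs[uc]):
                ok, report = validate_solution(model, specs[uc], sol)
                assert ok, report

    def test_wrong_state_chain_reported(self, model, specs):
        sol = next(iter(synthesize(model, specs[1])))
        broken = Solution(sol.tools,
                          sol.states[:-1] +
                          (DataState("data:2600", "format:3475"),))
        ok, report = validate_solution(model, specs[1], broken)
        assert not ok
        assert any("not a declared output state" in line for line in report)

    def test_annotation_lifts_recheck_compatibility(self, model, specs):
        # an incompatible sequence has no structural lift
        assert annotate_tool_sequence(
            model, specs[1], ("Comet", "PeptideProphet")) == []


class TestFindMinLength:
    def test_fixture_minimal_lengths(self, model, specs):
        assert find_min_length(model, specs[1], 6) == 4
        assert find_min_length(model, specs[2], 6) == 6
        assert find_min_length(model, specs[3], 4) == 4
        assert find_min_length(model, specs[4], 4) == 4

    def test_cap_below_min_gives_none(self, model, specs):
        assert find_min_length(model, specs[2], 5) is None

    def test_agrees_with_enumeration_on_random_models(self):
        rng = random.Random(5)
        for seed in range(30):
            m = random_domain(RandomDomainConfig(seed=seed, n_tools=5))
            spec = random_spec(rng, m, max_length=4)
            n = find_min_length(m, spec, 4)
            sols = synthesize(m, spec)
            lengths = sorted({len(s) for s in sols})
            if n is None:
                assert not lengths
            else:
                assert lengths and min(lengths) == n
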