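"""Model validation, target levels, unitary successors, enumeration,
dependency structure, and the model-definition file format."""

import random

import pytest

from feslogic.engine import (
    LogicalModel,
    NodeSpec,
    compile_successors,
    dependency_graph,
    enumerate_states,
    format_model,
    parse_expression,
    parse_model,
    subspace_size,
    successors,
    target_level,
    validate_model,
)
from feslogic.fes import load_packaged_model, packaged_model_text

from conftest import MEDIUM_CONDITION_FIXPOINT


def _model(*nodes):
    return LogicalModel("m", nodes)


def _rule(target, text):
    return (target, parse_expression(text))


# -- validation --------------------------------------------------------------


def test_wellformed_model_has_no_diagnostics(fes_model):
    assert validate_model(fes_model) == []


def test_unknown_node_reference_is_diagnosed():
    m = _model(NodeSpec("A", 1, rules=(_rule(1, "Foo"),)))
    diags = validate_model(m)
    assert len(diags) == 1 and "Foo" in diags[0]


def test_out_of_range_comparison_is_diagnosed():
    m = _model(
        NodeSpec("H2O2", 1),
        NodeSpec("A", 1, rules=(_rule(1, "H2O2=2"),)),
    )
    diags = validate_model(m)
    assert len(diags) == 1 and "H2O2" in diags[0] and "range" in diags[0]


def test_input_with_rules_and_duplicate_targets_diagnosed():
    m = _model(
        NodeSpec("I", 1, is_input=True, rules=(_rule(1, "I"),)),
        NodeSpec("A", 1, rules=(_rule(1, "I"), _rule(1, "!I"))),
    )
    diags = validate_model(m)
    assert any("input" in d for d in diags)
    assert any("duplicate target" in d for d in diags)


# -- target levels -----------------------------------------------------------


def _fes_state(model, **overrides):
    base = dict.fromkeys(model.names, 0)
    base.update(overrides)
    return model.state(base)


def test_holo_iscr_forms_when_apo_isc_present_without_peroxide(fes_model):
    s = _fes_state(fes_model, **{"IscR-A": 1, "Isc": 1, "H2O2": 0})
    assert target_level(fes_model, "IscR-H", s) == 1


def test_ryhb_fully_induced_without_fur(fes_model):
    s = _fes_state(fes_model, Fur=0)
    assert target_level(fes_model, "RyhB", s) == 2


def test_default_target_is_zero_when_no_rule_fires(fes_model):
    s = _fes_state(fes_model, **{"IscR-H": 1})
    assert target_level(fes_model, "NfuA", s) == 0


@pytest.mark.parametrize(
    "levels,expected",
    [
        # hand evaluation of the free-iron rules:
        # replete external iron, partial Fur -> import unrepressed, target 2
        (dict(Fe_ext=2, O2=1, Fur=1, RyhB=0, H2O2=0, OxyR=0), 2),
        # starvation + peroxide without OxyR -> sparing pushes toward 1
        (dict(Fe_ext=0, O2=1, Fur=0, RyhB=1, H2O2=1, OxyR=0), 1),
        # starvation, no stress, no full sparing -> decays to 0
        (dict(Fe_ext=0, O2=1, Fur=0, RyhB=1, H2O2=0, OxyR=0), 0),
        # medium iron, aerobic, full Fur repression, no sparing -> hold at 1
        (dict(Fe_ext=1, O2=1, Fur=2, RyhB=0, H2O2=0, OxyR=0), 1),
    ],
)
def test_free_iron_target_matches_hand_evaluation(fes_model, levels, expected):
    s = _fes_state(fes_model, **levels)
    assert target_level(fes_model, "Fe_free", s) == expected


# -- successors --------------------------------------------------------------


def test_fixpoint_has_no_successors(fes_model):
    s = fes_model.state(MEDIUM_CONDITION_FIXPOINT)
    assert successors(fes_model, s, {"Fe_ext": 1, "O2": 1}) == []


def test_multivalued_update_moves_one_step_toward_target(fes_model):
    # RyhB target is 2 when Fur=0, but a single transition raises it to 1
    s = _fes_state(fes_model, Fur=0, RyhB=0, Fe_ext=1, O2=1)
    succ = successors(fes_model, s, {"Fe_ext": 1, "O2": 1})
    i = fes_model.index("RyhB")
    ryhb_moves = [t for t in succ if t[i] != s[i]]
    assert len(ryhb_moves) == 1 and ryhb_moves[0][i] == 1


def test_inconsistent_state_and_clamp_rejected(fes_model):
    s = _fes_state(fes_model, Fe_ext=2)
    with pytest.raises(ValueError):
        successors(fes_model, s, {"Fe_ext": 1, "O2": 0})


def test_successor_count_matches_rule_reevaluation(fes_model):
    """Every free node whose target differs from its current level yields
    exactly one successor, differing in that node by one level."""
    rng = random.Random(7)
    clamp = {"Fe_ext": 1, "O2": 2}
    for _ in range(300):
        levels = {n: rng.randint(0, fes_model.max_level(n)) for n in fes_model.names}
        levels.update(clamp)
        s = fes_model.state(levels)
        succ = successors(fes_model, s, clamp)
        expected = [
            n
            for n in fes_model.internal
            if target_level(fes_model, n, s) != levels[n]
        ]
        assert len(succ) == len(expected)
        for t in succ:
            diff = [
                (n, s[fes_model.index(n)], t[fes_model.index(n)])
                for n in fes_model.names
                if s[fes_model.index(n)] != t[fes_model.index(n)]
            ]
            assert len(diff) == 1
            name, before, after = diff[0]
            assert abs(after - before) == 1 and name in expected
            assert name not in clamp


def test_compiled_successors_agree_with_reference(fes_model):
    rng = random.Random(11)
    clamp = {"Fe_ext": 0, "O2": 2}
    fast = compile_successors(fes_model, clamp)
    for _ in range(200):
        levels = {n: rng.randint(0, fes_model.max_level(n)) for n in fes_model.names}
        levels.update(clamp)
        s = fes_model.state(levels)
        assert fast(s) == successors(fes_model, s, clamp)


# -- enumeration -------------------------------------------------------------


def test_state_space_sizes(fes_model):
    # 7 ternary x 7 Boolean nodes
    assert subspace_size(fes_model) == 3**7 * 2**7 == 279936
    assert subspace_size(fes_model, {"Fe_ext": 0, "O2": 0}) == 3**5 * 2**7 == 31104


def test_enumeration_is_exact_and_duplicate_free():
    m = _model(
        NodeSpec("a", 2, is_input=True),
        NodeSpec("b", 1, rules=(_rule(1, "a"),)),
        NodeSpec("c", 2, rules=(_rule(1, "b"),)),
    )
    states = list(enumerate_states(m))
    assert len(states) == len(set(states)) == 3 * 2 * 3
    clamped = list(enumerate_states(m, {"a": 1}))
    assert len(clamped) == 6 and all(s[0] == 1 for s in clamped)


def test_unknown_clamp_names_rejected(fes_model):
    with pytest.raises(ValueError, match="unknown"):
        list(enumerate_states(fes_model, {"Foo": 1}))
    with pytest.raises(ValueError, match="unknown"):
        subspace_size(fes_model, {"Foo": 1})


def test_single_boolean_node_has_two_states():
    m = _model(NodeSpec("x", 1, rules=(_rule(1, "x"),)))
    assert list(enumerate_states(m)) == [(0,), (1,)]


# -- dependency structure ----------------------------------------------------


def test_regulator_sets_match_rule_texts(fes_model):
    edges = dependency_graph(fes_model)
    regs = lambda target: {e.regulator for e in edges if e.target == target}
    assert regs("NfuA") == {"IscR-H"}
    assert regs("Isc") == {"IscR-H", "RyhB", "Fe_free", "H2O2"}
    assert regs("Fe_free") == {"Fe_ext", "O2", "H2O2", "OxyR", "RyhB", "Fur"}
    assert regs("Fe_ext") == set()  # inputs have no incoming edges


def test_multithreshold_regulation_is_one_edge(fes_model):
    # RyhB acts on Fe_free at both thresholds (RyhB=2 and RyhB<2)
    edges = [
        e
        for e in dependency_graph(fes_model)
        if e.regulator == "RyhB" and e.target == "Fe_free"
    ]
    assert len(edges) == 1
    assert edges[0].thresholds == (2,)


def test_every_edge_regulator_appears_in_target_rules(fes_model):
    for edge in dependency_graph(fes_model):
        variables = set()
        for _, expr in fes_model.node(edge.target).rules:
            variables |= expr.variables()
        assert edge.regulator in variables


# -- model-definition file ----------------------------------------------------


def test_packaged_model_equals_constructor(fes_model):
    assert load_packaged_model() == fes_model


def test_model_file_round_trips_byte_identically(fes_model):
    text = packaged_model_text()
    assert format_model(parse_model(text)) == text
    assert format_model(fes_model) == text


def test_model_file_errors():
    with pytest.raises(ValueError):
        parse_model("node A max=1\n")  # missing header
    with pytest.raises(ValueError):
        parse_model("model m\n  1: A\n")  # rule outside node block
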