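"""Random multivalued logical networks and a brute-force attractor oracle.

The generator produces well-formed models from a seeded configuration, so
the dynamics engine can be validated on ensembles that owe nothing to the
biological model. The oracle finds attractors by exhaustive reachability
(per-state breadth-first closure) rather than strongly-connected-component
condensation, and evaluates rules through the interpreted path rather than
the compiled one, so a bug shared with the main pipeline cannot mask
itself.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .attractors import Attractor
from .engine import (
    And,
    Atom,
    Clamp,
    LogicalModel,
    NodeSpec,
    Or,
    enumerate_states,
    subspace_size,
    successors,
)

__all__ = [
    "GeneratorConfig",
    "random_model",
    "reachable_sets",
    "brute_force_attractors",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random-model ensemble.

    ``rule_density`` is the expected number of regulators per non-input
    node. The same config and seed always produce the identical model.
    """

    n_nodes: int
    ternary_fraction: float = 0.5
    n_inputs: int = 0
    rule_density: float = 1.5
    seed: int = 0


def _random_atom(rng: random.Random, var: str, max_level: int) -> Atom:
    kind = rng.choice(("ge", "ge", "eq", "lt"))
    if kind == "ge":
        return Atom(var, "ge", rng.randint(1, max_level))
    if kind == "eq":
        return Atom(var, "eq", rng.randint(0, max_level))
    return Atom(var, "lt", rng.randint(1, max_level))


def random_model(config: GeneratorConfig) -> LogicalModel:
    """Generate a well-formed random model.

    Non-input nodes get one rule per target level, each a disjunction of
    conjunctions of atoms over randomly drawn regulators (a normal form
    the text grammar round-trips). Raises on infeasible configurations.
    """
    if config.n_nodes < 1:
        raise ValueError("need at least one node")
    if config.n_inputs >= config.n_nodes:
        raise ValueError("need at least one non-input node")
    rng = random.Random(config.seed)
    names = [f"n{i:02d}" for i in range(config.n_nodes)]
    max_levels = {
        name: (2 if rng.random() < config.ternary_fraction else 1) for name in names
    }
    nodes = []
    for i, name in enumerate(names):
        if i < config.n_inputs:
            nodes.append(NodeSpec(name, max_levels[name], is_input=True))
            continue
        n_regs = max(1, min(config.n_nodes, round(rng.normalvariate(config.rule_density, 1.0))))
        regulators = rng.sample(names, n_regs)
        rules = []
        for target in range(1, max_levels[name] + 1):
            clauses = []
            for _ in range(rng.randint(1, 2)):
                atoms = []
                for _ in range(rng.randint(1, 2)):
                    var = rng.choice(regulators)
                    atoms.append(_random_atom(rng, var, max_levels[var]))
                clauses.append(atoms[0] if len(atoms) == 1 else And(*atoms))
            rules.append((target, clauses[0] if len(clauses) == 1 else Or(*clauses)))
        nodes.append(NodeSpec(name, max_levels[name], rules=tuple(rules)))
    return LogicalModel(f"random_seed{config.seed}", nodes)


def reachable_sets(model: LogicalModel, clamp: Clamp | None = None) -> dict:
    """Forward reachability closure of every state of the clamped
    subspace, by per-state breadth-first search over interpreted
    transitions (the state itself included)."""
    clamp = dict(clamp or {})
    adjacency = {
        state: successors(model, state, clamp)
        for state in enumerate_states(model, clamp)
    }
    closures: dict = {}
    for start in adjacency:
        seen = {start}
        frontier = [start]
        while frontier:
            nxt = []
            for s in frontier:
                for t in adjacency[s]:
                    if t not in seen:
                        seen.add(t)
                        nxt.append(t)
            frontier = nxt
        closures[start] = frozenset(seen)
    return closures


def brute_force_attractors(
    model: LogicalModel, clamp: Clamp | None = None, max_states: int = 10_000
) -> list:
    """Attractors by exhaustive reachability, independent of the terminal-
    SCC pipeline.

    A state belongs to an attractor iff every state it can reach can reach
    it back; the attractor is then exactly its reachability closure.
    Enforces a subspace limit since the closure computation is quadratic.
    """
    clamp = dict(clamp or {})
    n = subspace_size(model, clamp)
    if n > max_states:
        raise ValueError(f"subspace has {n} states, oracle limit is {max_states}")
    closures = reachable_sets(model, clamp)
    found = {}
    for state, reach in closures.items():
        if all(state in closures[t] for t in reach):
            found[reach] = Attractor(reach, model)
    return sorted(found.values(), key=lambda a: min(a.states))
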