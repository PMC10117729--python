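"""Asynchronous state transition graphs and attractor detection.

The state transition graph (STG) of a clamped subspace has one vertex per
state and one directed edge per unitary asynchronous transition. Attractors
are the terminal strongly connected components of the STG: once the
dynamics enters one it never leaves. A size-1 attractor is a stable state;
larger ones are cyclic (homeostatic oscillations).

Attractors are always computed over the *full* clamped subspace, never from
a chosen initial state, so the result is a property of the condition alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .engine import (
    Clamp,
    LogicalModel,
    compile_successors,
    enumerate_states,
    subspace_size,
    target_level,
)

__all__ = [
    "TransitionGraph",
    "Attractor",
    "NodeAsymptotics",
    "MultipleAttractorsError",
    "build_stg",
    "terminal_sccs",
    "condition_attractors",
    "condition_attractor",
    "summarize",
    "stable_states_direct",
]

#: refuse to materialize STGs above this many vertices
DEFAULT_MAX_STATES = 1_000_000


@dataclass
class TransitionGraph:
    """Full asynchronous STG of a clamped subspace."""

    model: LogicalModel
    clamp: dict
    graph: nx.DiGraph

    @property
    def n_states(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class Attractor:
    """Terminal strongly connected set of states."""

    states: frozenset
    model: LogicalModel

    @property
    def size(self) -> int:
        return len(self.states)

    @property
    def kind(self) -> str:
        return "stable_state" if self.size == 1 else "cyclic"

    @property
    def sorted_states(self) -> tuple:
        return tuple(sorted(self.states))

    def levels(self, node: str) -> set:
        """Set of levels the node takes across the attractor."""
        i = self.model.index(node)
        return {s[i] for s in self.states}


@dataclass(frozen=True)
class NodeAsymptotics:
    """Per-node summary of asymptotic behavior within one attractor.

    ``mean`` is the unweighted arithmetic mean over attractor states; for
    oscillating nodes it is the quantity shown by the published heatmaps.
    """

    min: int
    max: int
    mean: float
    is_oscillating: bool


class MultipleAttractorsError(ValueError):
    """Raised when a unique attractor was expected but several exist."""

    def __init__(self, attractors):
        self.attractors = list(attractors)
        super().__init__(f"{len(self.attractors)} attractors found, expected one")


def build_stg(
    model: LogicalModel,
    clamp: Clamp,
    max_states: int = DEFAULT_MAX_STATES,
) -> TransitionGraph:
    """Materialize the STG over the whole clamped subspace.

    Every input node should be clamped (rule-less nodes never move, so an
    unclamped input just multiplies the subspace by disconnected copies).
    """
    clamp = dict(clamp)
    n = subspace_size(model, clamp)
    if n > max_states:
        raise ValueError(
            f"clamped subspace has {n} states, above the safety limit {max_states}"
        )
    succ = compile_successors(model, clamp)
    graph = nx.DiGraph()
    graph.add_nodes_from(enumerate_states(model, clamp))
    graph.add_edges_from(
        (state, nxt) for state in graph for nxt in succ(state)
    )
    return TransitionGraph(model, clamp, graph)


def terminal_sccs(stg: TransitionGraph) -> list:
    """Attractors = terminal SCCs of the STG, ordered by their
    lexicographically smallest member state."""
    cond = nx.condensation(stg.graph)
    out = []
    for comp_id in cond.nodes:
        if cond.out_degree(comp_id) == 0:
            members = cond.nodes[comp_id]["members"]
            out.append(Attractor(frozenset(members), stg.model))
    out.sort(key=lambda a: min(a.states))
    return out


def condition_attractors(
    model: LogicalModel,
    inputs: Clamp,
    perturbation: Clamp | None = None,
    max_states: int = DEFAULT_MAX_STATES,
) -> list:
    """All attractors of the subspace clamped by inputs plus an optional
    perturbation clamp. Conflicting clamps on one node are an error."""
    clamp = dict(inputs)
    for name, lvl in (perturbation or {}).items():
        if name in clamp and clamp[name] != lvl:
            raise ValueError(f"conflicting clamps on {name!r}: {clamp[name]} vs {lvl}")
        clamp[name] = lvl
    missing = set(model.inputs) - set(clamp)
    if missing:
        raise ValueError(f"input nodes not clamped: {sorted(missing)}")
    return terminal_sccs(build_stg(model, clamp, max_states=max_states))


def condition_attractor(
    model: LogicalModel,
    inputs: Clamp,
    perturbation: Clamp | None = None,
    max_states: int = DEFAULT_MAX_STATES,
) -> Attractor:
    """The unique attractor of a condition; raises
    :class:`MultipleAttractorsError` (carrying all of them) otherwise."""
    found = condition_attractors(model, inputs, perturbation, max_states=max_states)
    if len(found) != 1:
        raise MultipleAttractorsError(found)
    return found[0]


def summarize(attractor: Attractor) -> dict:
    """Map node name -> :class:`NodeAsymptotics` over the attractor."""
    model = attractor.model
    states = attractor.sorted_states
    n = len(states)
    out = {}
    for i, node in enumerate(model.nodes):
        values = [s[i] for s in states]
        lo, hi = min(values), max(values)
        out[node.name] = NodeAsymptotics(lo, hi, sum(values) / n, lo < hi)
    return out


def stable_states_direct(model: LogicalModel, clamp: Clamp) -> list:
    """All stable states of the clamped subspace found by direct scan
    (target == current for every free node), without building the STG.
    Independent cross-check for the size-1 terminal SCCs."""
    clamp = dict(clamp)
    stable = []
    for state in enumerate_states(model, clamp):
        ok = True
        for node in model.nodes:
            if node.name in clamp or not node.rules:
                continue
            if target_level(model, node.name, state) != state[model.index(node.name)]:
                ok = False
                break
        if ok:
            stable.append(state)
    return stable
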