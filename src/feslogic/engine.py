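"""Generic multivalued logical models with unitary asynchronous dynamics.

A model is an ordered list of nodes. Each node carries a discrete activity
level in ``0..max_level`` and an ordered list of *target rules*
``(target_level, expression)``. Given a complete state, the target level of
a node is the target of the highest-level rule whose expression is
satisfied, or 0 when no rule fires. Under unitary asynchronous updating a
single node changes per transition, moving one level toward its target.

Input nodes carry no rules; their value is clamped to an environmental
level for the duration of a simulation. The same clamp mechanism expresses
genetic perturbations (knock-out = clamp to 0, ectopic expression = clamp
to a nonzero level).

States are plain tuples of ints in the model's node order, which makes
them hashable graph vertices and keeps full-subspace enumeration cheap.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping

__all__ = [
    "Atom",
    "Not",
    "And",
    "Or",
    "Expression",
    "NodeSpec",
    "LogicalModel",
    "State",
    "Clamp",
    "DependencyEdge",
    "parse_expression",
    "format_expression",
    "validate_model",
    "target_level",
    "satisfied_targets",
    "successors",
    "enumerate_states",
    "subspace_size",
    "dependency_graph",
    "parse_model",
    "format_model",
    "load_model",
    "save_model",
]

State = tuple  # levels in model node order
Clamp = Mapping[str, int]


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

_EQ, _LT, _GE = "eq", "lt", "ge"


@dataclass(frozen=True)
class Atom:
    """Comparison of one variable against a level.

    ``op`` is one of ``eq`` (==), ``lt`` (<), ``ge`` (>=). A bare variable
    in the text grammar means activity, i.e. ``ge 1``.
    """

    var: str
    op: str
    level: int

    def evaluate(self, get: Callable[[str], int]) -> bool:
        v = get(self.var)
        if self.op == _EQ:
            return v == self.level
        if self.op == _LT:
            return v < self.level
        return v >= self.level

    def variables(self) -> set:
        return {self.var}

    def _source(self, index: Mapping[str, int]) -> str:
        i = index[self.var]
        cmp = {"eq": "==", "lt": "<", "ge": ">="}[self.op]
        return f"s[{i}]{cmp}{self.level}"

    _prec = 4


@dataclass(frozen=True)
class Not:
    operand: "Expression"

    def evaluate(self, get: Callable[[str], int]) -> bool:
        return not self.operand.evaluate(get)

    def variables(self) -> set:
        return self.operand.variables()

    def _source(self, index: Mapping[str, int]) -> str:
        return f"(not {self.operand._source(index)})"

    _prec = 3


@dataclass(frozen=True)
class And:
    operands: tuple

    def __init__(self, *operands: "Expression"):
        object.__setattr__(self, "operands", tuple(operands))

    def evaluate(self, get: Callable[[str], int]) -> bool:
        return all(op.evaluate(get) for op in self.operands)

    def variables(self) -> set:
        out: set = set()
        for op in self.operands:
            out |= op.variables()
        return out

    def _source(self, index: Mapping[str, int]) -> str:
        return "(" + " and ".join(op._source(index) for op in self.operands) + ")"

    _prec = 2


@dataclass(frozen=True)
class Or:
    operands: tuple

    def __init__(self, *operands: "Expression"):
        object.__setattr__(self, "operands", tuple(operands))

    def evaluate(self, get: Callable[[str], int]) -> bool:
        return any(op.evaluate(get) for op in self.operands)

    def variables(self) -> set:
        out: set = set()
        for op in self.operands:
            out |= op.variables()
        return out

    def _source(self, index: Mapping[str, int]) -> str:
        return "(" + " or ".join(op._source(index) for op in self.operands) + ")"

    _prec = 1


Expression = Atom | Not | And | Or


def truthy(var: str) -> Atom:
    """Activity atom: true iff the variable is at level >= 1."""
    return Atom(var, _GE, 1)


# --- text grammar ----------------------------------------------------------
#
#   expr    := term ('|' term)*
#   term    := factor ('&' factor)*
#   factor  := '!' factor | '(' expr ')' | atom
#   atom    := NAME | NAME '=' INT | NAME '<' INT | NAME '>=' INT
#
# Names may contain hyphens (IscR-A, IscR-H); there is no arithmetic, so
# this is unambiguous.

_TOKEN = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_\-]*)|(?P<op>>=|=|<|!|&|\||\(|\))|(?P<int>\d+))"
)


def _tokenize(text: str) -> list:
    pos, tokens = 0, []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ValueError(f"cannot tokenize expression at {text[pos:]!r}")
        pos = m.end()
        if m.lastgroup == "name":
            tokens.append(("name", m.group("name")))
        elif m.lastgroup == "int":
            tokens.append(("int", int(m.group("int"))))
        else:
            tokens.append(("op", m.group("op")))
    return tokens


class _Parser:
    def __init__(self, tokens: list):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect_op(self, op: str):
        kind, val = self.take()
        if kind != "op" or val != op:
            raise ValueError(f"expected {op!r}, got {val!r}")

    def expr(self) -> Expression:
        terms = [self.term()]
        while self.peek() == ("op", "|"):
            self.take()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(*terms)

    def term(self) -> Expression:
        factors = [self.factor()]
        while self.peek() == ("op", "&"):
            self.take()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(*factors)

    def factor(self) -> Expression:
        kind, val = self.peek()
        if (kind, val) == ("op", "!"):
            self.take()
            return Not(self.factor())
        if (kind, val) == ("op", "("):
            self.take()
            inner = self.expr()
            self.expect_op(")")
            return inner
        if kind == "name":
            self.take()
            k2, v2 = self.peek()
            if k2 == "op" and v2 in ("=", "<", ">="):
                self.take()
                k3, v3 = self.take()
                if k3 != "int":
                    raise ValueError(f"expected level after {val}{v2}")
                op = {"=": _EQ, "<": _LT, ">=": _GE}[v2]
                return Atom(val, op, v3)
            return truthy(val)
        raise ValueError(f"unexpected token {val!r} in expression")


def parse_expression(text: str) -> Expression:
    """Parse the small rule grammar (atoms ``X``, ``X=k``, ``X<k``, ``X>=k``;
    operators ``!``, ``&``, ``|``; parentheses)."""
    parser = _Parser(_tokenize(text))
    expr = parser.expr()
    if parser.pos != len(parser.tokens):
        raise ValueError(f"trailing tokens in expression {text!r}")
    return expr


def format_expression(expr: Expression) -> str:
    """Canonical text form; ``parse_expression`` inverts it exactly."""
    return _fmt(expr, 0)


def _fmt(expr: Expression, parent_prec: int) -> str:
    if isinstance(expr, Atom):
        if expr.op == _GE and expr.level == 1:
            out = expr.var
        else:
            out = f"{expr.var}{({'eq': '=', 'lt': '<', 'ge': '>='})[expr.op]}{expr.level}"
        return out
    if isinstance(expr, Not):
        return "!" + _fmt(expr.operand, Not._prec)
    joiner = " & " if isinstance(expr, And) else " | "
    out = joiner.join(_fmt(op, expr._prec) for op in expr.operands)
    if expr._prec < parent_prec:
        out = "(" + out + ")"
    return out


# ---------------------------------------------------------------------------
# Nodes and models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSpec:
    """One component of a logical model.

    ``rules`` is an ordered tuple of ``(target_level, expression)`` pairs;
    rule scanning is always highest target first regardless of storage
    order. ``level_semantics`` optionally annotates levels with their
    biological meaning (e.g. concentration ranges).
    """

    name: str
    max_level: int = 1
    is_input: bool = False
    rules: tuple = ()
    level_semantics: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        object.__setattr__(self, "level_semantics", tuple(self.level_semantics))

    @property
    def rules_by_priority(self) -> tuple:
        return tuple(sorted(self.rules, key=lambda r: -r[0]))


class LogicalModel:
    """Named, ordered collection of :class:`NodeSpec`.

    Construction never raises on semantic problems; use
    :func:`validate_model` to obtain diagnostics. States are tuples of
    levels in node order.
    """

    def __init__(self, name: str, nodes: Iterable[NodeSpec]):
        self.name = name
        self.nodes = tuple(nodes)
        self._index = {n.name: i for i, n in enumerate(self.nodes)}

    # -- basic access -------------------------------------------------
    @property
    def names(self) -> tuple:
        return tuple(n.name for n in self.nodes)

    def node(self, name: str) -> NodeSpec:
        return self.nodes[self._index[name]]

    def index(self, name: str) -> int:
        return self._index[name]

    def max_level(self, name: str) -> int:
        return self.node(name).max_level

    @property
    def inputs(self) -> tuple:
        return tuple(n.name for n in self.nodes if n.is_input)

    @property
    def internal(self) -> tuple:
        return tuple(n.name for n in self.nodes if not n.is_input)

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LogicalModel)
            and self.name == other.name
            and self.nodes == other.nodes
        )

    def __repr__(self) -> str:
        return f"LogicalModel({self.name!r}, {len(self.nodes)} nodes)"

    # -- state helpers ------------------------------------------------
    def state(self, levels: Mapping[str, int]) -> State:
        """Build a state tuple from a complete name->level mapping."""
        missing = set(self._index) - set(levels)
        if missing:
            raise ValueError(f"incomplete state, missing {sorted(missing)}")
        return tuple(levels[n.name] for n in self.nodes)

    def state_dict(self, state: State) -> dict:
        return {n.name: v for n, v in zip(self.nodes, state)}

    def level(self, state: State, name: str):
        return state[self._index[name]]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_model(model: LogicalModel) -> list:
    """Return a list of human-readable diagnostics; empty iff well-formed."""
    diags: list = []
    seen: set = set()
    for node in model.nodes:
        if node.name in seen:
            diags.append(f"duplicate node name {node.name!r}")
        seen.add(node.name)
        if node.max_level < 1:
            diags.append(f"node {node.name!r}: max_level must be >= 1")
        if node.is_input and node.rules:
            diags.append(f"input node {node.name!r} must not carry rules")
        targets = [t for t, _ in node.rules]
        if len(targets) != len(set(targets)):
            diags.append(f"node {node.name!r}: duplicate target levels in rules")
        for target, expr in node.rules:
            if not 1 <= target <= node.max_level:
                diags.append(
                    f"node {node.name!r}: rule target {target} outside 1..{node.max_level}"
                )
            for atom in _atoms(expr):
                if atom.var not in model._index:
                    diags.append(
                        f"node {node.name!r}: rule references unknown node {atom.var!r}"
                    )
                elif not 0 <= atom.level <= model.max_level(atom.var):
                    diags.append(
                        f"node {node.name!r}: comparison level {atom.level} out of "
                        f"range for {atom.var!r} (max {model.max_level(atom.var)})"
                    )
    return diags


def _atoms(expr: Expression) -> Iterator[Atom]:
    if isinstance(expr, Atom):
        yield expr
    elif isinstance(expr, Not):
        yield from _atoms(expr.operand)
    else:
        for op in expr.operands:
            yield from _atoms(op)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def target_level(model: LogicalModel, node: str, state: State) -> int:
    """Target level of ``node`` in ``state``: rules are scanned from the
    highest target level down and the first satisfied rule wins; with no
    satisfied rule the target is 0. Rule-less (input) nodes target their
    current value."""
    spec = model.node(node)
    if not spec.rules:
        return state[model.index(node)]
    get = lambda var: state[model.index(var)]
    for target, expr in spec.rules_by_priority:
        if expr.evaluate(get):
            return target
    return 0


def satisfied_targets(model: LogicalModel, node: str, state: State) -> list:
    """All rule targets whose expression holds in ``state`` (for checking
    mutual exclusivity of rule rows)."""
    get = lambda var: state[model.index(var)]
    return [t for t, expr in model.node(node).rules if expr.evaluate(get)]


def compile_targets(model: LogicalModel, clamp: Clamp | None = None) -> list:
    """Compile per-node target functions over state tuples.

    Returns ``[(node_index, func)]`` for every free (unclamped, ruled)
    node; each func maps a state tuple to the node's target level. The
    compiled code is the hot path of state-transition-graph construction.
    """
    clamp = dict(clamp or {})
    compiled = []
    for i, node in enumerate(model.nodes):
        if node.name in clamp or not node.rules:
            continue
        lines = ["def _target(s):"]
        for target, expr in node.rules_by_priority:
            lines.append(f"    if {expr._source(model._index)}: return {target}")
        lines.append("    return 0")
        ns: dict = {}
        exec("\n".join(lines), ns)
        compiled.append((i, ns["_target"]))
    return compiled


def compile_successors(model: LogicalModel, clamp: Clamp | None = None) -> Callable:
    """Compile a single function mapping a state tuple to the list of its
    unitary asynchronous successors under ``clamp``.

    Semantically identical to :func:`successors` (which stays as the
    readable reference path); this fused version is what full-subspace STG
    construction uses.
    """
    clamp = dict(clamp or {})
    lines = ["def _succ(s):", "    out = []"]
    for i, node in enumerate(model.nodes):
        if node.name in clamp or not node.rules:
            continue
        kw = "if"
        for target, expr in node.rules_by_priority:
            lines.append(f"    {kw} {expr._source(model._index)}: t = {target}")
            kw = "elif"
        lines.append("    else: t = 0")
        lines.append(f"    v = s[{i}]")
        lines.append(f"    if t > v: out.append(s[:{i}] + (v + 1,) + s[{i + 1}:])")
        lines.append(f"    elif t < v: out.append(s[:{i}] + (v - 1,) + s[{i + 1}:])")
    lines.append("    return out")
    ns: dict = {}
    exec("\n".join(lines), ns)
    return ns["_succ"]


def _check_clamp(model: LogicalModel, state: State, clamp: Clamp) -> None:
    for name, lvl in clamp.items():
        if not 0 <= lvl <= model.max_level(name):
            raise ValueError(f"clamp {name}={lvl} outside 0..{model.max_level(name)}")
        if state[model.index(name)] != lvl:
            raise ValueError(
                f"state has {name}={state[model.index(name)]}, clamp requires {lvl}"
            )


def successors(
    model: LogicalModel, state: State, clamp: Clamp | None = None
) -> list:
    """Unitary asynchronous successors of ``state``.

    One successor per free node whose target differs from its current
    level; that node moves one level toward the target, everything else is
    unchanged. Clamped nodes never move. Order follows the model's node
    order, so output is deterministic.
    """
    clamp = dict(clamp or {})
    _check_clamp(model, state, clamp)
    out = []
    for i, node in enumerate(model.nodes):
        if node.name in clamp or not node.rules:
            continue
        t = target_level(model, node.name, state)
        cur = state[i]
        if t != cur:
            nxt = list(state)
            nxt[i] = cur + (1 if t > cur else -1)
            out.append(tuple(nxt))
    return out


def _check_clamp_names(model: LogicalModel, clamp: Clamp) -> None:
    unknown = set(clamp) - set(model._index)
    if unknown:
        raise ValueError(f"clamp names unknown to the model: {sorted(unknown)}")


def enumerate_states(model: LogicalModel, clamp: Clamp | None = None) -> Iterator[State]:
    """Yield every state of the clamped subspace exactly once, in
    lexicographic order (node order fixed, levels ascending)."""
    clamp = dict(clamp or {})
    _check_clamp_names(model, clamp)
    ranges = []
    for node in model.nodes:
        if node.name in clamp:
            lvl = clamp[node.name]
            if not 0 <= lvl <= node.max_level:
                raise ValueError(f"clamp {node.name}={lvl} outside 0..{node.max_level}")
            ranges.append((lvl,))
        else:
            ranges.append(tuple(range(node.max_level + 1)))
    return itertools.product(*ranges)


def subspace_size(model: LogicalModel, clamp: Clamp | None = None) -> int:
    clamp = clamp or {}
    _check_clamp_names(model, clamp)
    size = 1
    for node in model.nodes:
        if node.name not in clamp:
            size *= node.max_level + 1
    return size


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DependencyEdge:
    """Regulatory edge derived from rule texts.

    ``thresholds`` collects the comparison levels at which the regulator
    appears in the target's rules; a regulator acting at two thresholds is
    still one edge. Signs are not inferred from rule syntax."""

    regulator: str
    target: str
    thresholds: tuple
    sign: str = "unknown"


def dependency_graph(model: LogicalModel) -> list:
    """One :class:`DependencyEdge` per (regulator, target) pair appearing
    in the target's rules, in deterministic (target, regulator) node
    order."""
    edges = []
    for node in model.nodes:
        per_reg: dict = {}
        for _, expr in node.rules:
            for atom in _atoms(expr):
                per_reg.setdefault(atom.var, set()).add(max(1, atom.level))
        for reg in sorted(per_reg, key=lambda n: model.index(n) if n in model._index else len(model)):
            edges.append(
                DependencyEdge(reg, node.name, tuple(sorted(per_reg[reg])))
            )
    return edges


# ---------------------------------------------------------------------------
# Model-definition text format
# ---------------------------------------------------------------------------
#
#   model <name>
#
#   node <Name> max=<k> [input]
#     @<level>: free-text level annotation
#     <target>: <expression>
#
# Comments start with '#'. The writer emits a canonical form that the
# reader inverts byte-identically.

_NODE_RE = re.compile(
    r"^node\s+(?P<name>[A-Za-z_][A-Za-z0-9_\-]*)\s+max=(?P<max>\d+)(?P<input>\s+input)?\s*$"
)
_SEM_RE = re.compile(r"^@(?P<level>\d+):\s?(?P<text>.*)$")
_RULE_RE = re.compile(r"^(?P<target>\d+):\s*(?P<expr>.+)$")


def format_model(model: LogicalModel) -> str:
    lines = [f"model {model.name}", ""]
    for node in model.nodes:
        head = f"node {node.name} max={node.max_level}"
        if node.is_input:
            head += " input"
        lines.append(head)
        for level, text in node.level_semantics:
            lines.append(f"  @{level}: {text}")
        for target, expr in node.rules:
            lines.append(f"  {target}: {format_expression(expr)}")
        lines.append("")
    return "\n".join(lines)


def parse_model(text: str) -> LogicalModel:
    name = None
    nodes: list = []
    current: dict | None = None

    def flush():
        if current is not None:
            nodes.append(
                NodeSpec(
                    current["name"],
                    current["max"],
                    current["input"],
                    tuple(current["rules"]),
                    tuple(current["semantics"]),
                )
            )

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("model "):
            name = line[len("model ") :].strip()
            continue
        m = _NODE_RE.match(line)
        if m:
            flush()
            current = {
                "name": m.group("name"),
                "max": int(m.group("max")),
                "input": m.group("input") is not None,
                "rules": [],
                "semantics": [],
            }
            continue
        if current is None:
            raise ValueError(f"unexpected line outside node block: {raw!r}")
        m = _SEM_RE.match(line)
        if m:
            current["semantics"].append((int(m.group("level")), m.group("text")))
            continue
        m = _RULE_RE.match(line)
        if m:
            current["rules"].append(
                (int(m.group("target")), parse_expression(m.group("expr")))
            )
            continue
        raise ValueError(f"cannot parse model line: {raw!r}")
    flush()
    if name is None:
        raise ValueError("model file lacks a 'model <name>' header")
    return LogicalModel(name, nodes)


def load_model(path) -> LogicalModel:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_model(fh.read())


def save_model(model: LogicalModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_model(model))
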