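"""In-silico genetic perturbations and the growth-defect screen.

A perturbation clamps one or more internal (non-input) nodes at a constant
level for the whole simulation: knock-out (KO) clamps to 0, ectopic
expression to a nonzero level. Environmental inputs are conditions, not
genotypes, and cannot be perturbed.

The growth-defect screen flags a (perturbation, condition) pair when both
Fe-S cluster assembly machineries are fully off in the attractor — Isc = 0
and Suf = 0 in *every* attractor state. Transient presence of either
machinery during an oscillation still supplies some biogenesis, so
oscillating cases are not flagged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .engine import LogicalModel
from .fes import CONDITIONS, ConditionAtlas, build_atlas

__all__ = [
    "Perturbation",
    "ScreenReport",
    "knockout",
    "ectopic",
    "combine",
    "enumerate_single_mutants",
    "enumerate_double_knockouts",
    "mutant_atlas",
    "growth_defect_screen",
]


@dataclass(frozen=True)
class Perturbation:
    """Labelled clamp over internal nodes (KO = clamp to 0)."""

    label: str
    clamp: tuple  # ((node, level), ...) sorted by node

    @staticmethod
    def of(label: str, clamp: dict) -> "Perturbation":
        return Perturbation(label, tuple(sorted(clamp.items())))

    @property
    def clamp_dict(self) -> dict:
        return dict(self.clamp)

    def validate(self, model: LogicalModel) -> None:
        for node, level in self.clamp:
            if node not in model.names:
                raise ValueError(f"unknown node {node!r}")
            if model.node(node).is_input:
                raise ValueError(f"cannot perturb input node {node!r}")
            if not 0 <= level <= model.max_level(node):
                raise ValueError(
                    f"clamp {node}={level} outside 0..{model.max_level(node)}"
                )


def knockout(node: str) -> Perturbation:
    return Perturbation.of(f"{node} KO", {node: 0})


def ectopic(node: str, level: int) -> Perturbation:
    return Perturbation.of(f"{node}={level}", {node: level})


def combine(*perturbations: Perturbation) -> Perturbation:
    """Union of clamps; two clamps on the same node must agree."""
    clamp: dict = {}
    for p in perturbations:
        for node, level in p.clamp:
            if node in clamp and clamp[node] != level:
                raise ValueError(
                    f"conflicting clamps on {node!r}: {clamp[node]} vs {level}"
                )
            clamp[node] = level
    label = "+".join(p.label for p in perturbations)
    return Perturbation.of(label, clamp)


def enumerate_single_mutants(model: LogicalModel, ko_only: bool = False) -> list:
    """Every internal node clamped at each of its levels: KO at 0, ectopic
    expression at each level >= 1 (unless ``ko_only``). Deterministic node
    order."""
    out = []
    for name in model.internal:
        out.append(knockout(name))
        if not ko_only:
            for level in range(1, model.max_level(name) + 1):
                out.append(ectopic(name, level))
    return out


def enumerate_double_knockouts(model: LogicalModel) -> list:
    """All unordered KO pairs over internal nodes."""
    return [
        combine(knockout(a), knockout(b))
        for a, b in itertools.combinations(model.internal, 2)
    ]


def mutant_atlas(
    model: LogicalModel, perturbation: Perturbation, conditions=CONDITIONS
) -> ConditionAtlas:
    """Attractor atlas over the condition grid under a perturbation."""
    perturbation.validate(model)
    return build_atlas(
        model, perturbation.clamp_dict, label=perturbation.label, conditions=conditions
    )


@dataclass
class ScreenReport:
    """Result of a growth-defect screen.

    ``atlases`` maps perturbation label -> :class:`ConditionAtlas`;
    ``defects`` maps label -> tuple of flagged (Fe_ext, O2) conditions.
    The wild type is always included as baseline under label "WT".
    """

    model: LogicalModel
    atlases: dict = field(default_factory=dict)
    defects: dict = field(default_factory=dict)
    defect_nodes: tuple = ("Isc", "Suf")

    @property
    def defective_perturbations(self) -> tuple:
        return tuple(lbl for lbl, conds in self.defects.items() if conds)

    def to_frame(self, nodes=None) -> pd.DataFrame:
        """Long-format table: (perturbation, Fe_ext, O2, node, min, max,
        mean, oscillating, defect_flag)."""
        frames = []
        for label, atlas in self.atlases.items():
            frame = atlas.to_frame(nodes)
            flagged = set(self.defects[label])
            frame["defect_flag"] = [
                (fe, o2) in flagged for fe, o2 in zip(frame["Fe_ext"], frame["O2"])
            ]
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


def _is_defect(entry, model: LogicalModel, defect_nodes) -> bool:
    idx = [model.index(n) for n in defect_nodes]
    return all(
        all(state[i] == 0 for i in idx)
        for attractor in entry.attractors
        for state in attractor.states
    )


def growth_defect_screen(
    model: LogicalModel,
    perturbations,
    conditions=CONDITIONS,
    defect_nodes=("Isc", "Suf"),
    include_wildtype: bool = True,
) -> ScreenReport:
    """Flag every (perturbation, condition) whose attractor has all
    ``defect_nodes`` at 0 in every state."""
    report = ScreenReport(model, defect_nodes=tuple(defect_nodes))
    todo = []
    if include_wildtype:
        todo.append(Perturbation.of("WT", {}))
    todo.extend(perturbations)
    for pert in todo:
        atlas = build_atlas(
            model, pert.clamp_dict, label=pert.label, conditions=conditions
        )
        report.atlases[pert.label] = atlas
        report.defects[pert.label] = tuple(
            cond
            for cond in atlas.conditions
            if _is_defect(atlas[cond], model, defect_nodes)
        )
    return report
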