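"""The *E. coli* Fe-S cluster biogenesis regulatory network.

A 14-node multivalued logical model of how the two Fe-S cluster assembly
machineries (Isc, the housekeeping system; Suf, the stress system) and the
A-type carriers ErpA and NfuA are controlled by iron homeostasis (free
intracellular iron, the Fur repressor, the small RNA RyhB) and the
oxidative-stress response (intracellular H2O2, OxyR, and the catalases /
peroxidases lumped as Hpx). The IscR transcription factor is split into its
apo (clusterless, Suf-activating) and holo (cluster-bound, Isc-repressing)
forms. Two rule-less input nodes set the environment: external iron
(Fe_ext, ternary) and oxygen (O2: 0 anaerobiosis, 1 aerobiosis, 2 oxidative
stress), giving a 3x3 grid of conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .attractors import (
    Attractor,
    MultipleAttractorsError,
    condition_attractors,
    summarize,
)
from .engine import LogicalModel, NodeSpec, parse_expression

__all__ = [
    "build_fes_model",
    "load_packaged_model",
    "packaged_model_text",
    "CONDITIONS",
    "INPUT_SEMANTICS",
    "MODULES",
    "TRACKED_NODES",
    "HEATMAP_NODES",
    "AtlasEntry",
    "ConditionAtlas",
    "build_atlas",
    "wildtype_atlas",
]


def _rules(*pairs):
    return tuple((target, parse_expression(text)) for target, text in pairs)


def build_fes_model() -> LogicalModel:
    """Construct the 14-node Fe-S cluster biogenesis model.

    Rule conventions: for each node the highest-target rule that holds
    wins; with no rule satisfied the node targets 0. ``!X`` on a
    multivalued variable means X=0; negated equality (e.g. "not at full
    repression") is written with ``<``.
    """
    nodes = (
        NodeSpec(
            "Fe_ext",
            2,
            is_input=True,
            level_semantics=(
                (0, "external iron < 1 uM (starvation)"),
                (1, "external iron 1-5 uM"),
                (2, "external iron > 5-10 uM (replete)"),
            ),
        ),
        NodeSpec(
            "O2",
            2,
            is_input=True,
            level_semantics=(
                (0, "anaerobiosis"),
                (1, "aerobiosis"),
                (2, "oxidative stress (external [H2O2] > 2 uM)"),
            ),
        ),
        NodeSpec(
            "Fe_free",
            2,
            rules=_rules(
                (
                    1,
                    "(!Fe_ext & ((H2O2 & !OxyR) | RyhB=2))"
                    " | ((Fe_ext=2 | (Fe_ext=1 & !O2)) & Fur=2 & RyhB<2)"
                    " | (Fe_ext=1 & O2>=1 & RyhB<2 & !(H2O2 & Fur<2))",
                ),
                (
                    2,
                    "((Fe_ext=2 | (Fe_ext=1 & !O2)) & (Fur<2 | (RyhB=2 & Fur=2)))"
                    " | (Fe_ext=1 & O2>=1 & (RyhB=2 | (H2O2 & Fur<2)))",
                ),
            ),
            level_semantics=(
                (0, "free intracellular iron <= 1 uM"),
                (1, "free intracellular iron ~ 10 uM (optimum)"),
                (2, "free intracellular iron >= 50 uM"),
            ),
        ),
        NodeSpec(
            "H2O2",
            1,
            rules=_rules((1, "(O2=1 & !Hpx & Fe_free=2) | (O2=2 & Hpx<2)")),
            level_semantics=(
                (0, "internal [H2O2] < 50 nM"),
                (1, "internal [H2O2] >= 50 nM (activates OxyR)"),
            ),
        ),
        NodeSpec("OxyR", 1, rules=_rules((1, "H2O2"))),
        NodeSpec(
            "Hpx",
            2,
            rules=_rules((1, "!OxyR"), (2, "OxyR")),
            level_semantics=(
                (0, "knock-out only"),
                (1, "basal catalase/peroxidase expression"),
                (2, "OxyR-induced expression"),
            ),
        ),
        NodeSpec(
            "Fur",
            2,
            rules=_rules(
                (1, "Fe_free=1 & (!H2O2 | OxyR)"),
                (2, "Fe_free=2 & (!H2O2 | OxyR)"),
            ),
            level_semantics=(
                (0, "inactive"),
                (1, "partial repression (RyhB only)"),
                (2, "full repression of the Fur regulon"),
            ),
        ),
        NodeSpec(
            "RyhB",
            2,
            rules=_rules((1, "Fur=1"), (2, "!Fur")),
            level_semantics=(
                (0, "repressed"),
                (1, "inhibits Isc translation"),
                (2, "inhibits Isc and ErpA"),
            ),
        ),
        NodeSpec("IscR-A", 1, rules=_rules((1, "!IscR-H"))),
        NodeSpec("IscR-H", 1, rules=_rules((1, "IscR-A & Isc & !H2O2"))),
        NodeSpec("Isc", 1, rules=_rules((1, "!IscR-H & !RyhB & Fe_free=2 & !H2O2"))),
        NodeSpec(
            "Suf",
            2,
            rules=_rules(
                (1, "Fur<2 & (OxyR | IscR-A) & !(OxyR & IscR-A)"),
                (2, "Fur<2 & OxyR & IscR-A"),
            ),
            level_semantics=(
                (0, "no suf expression"),
                (1, "medium suf expression"),
                (2, "high suf expression"),
            ),
        ),
        NodeSpec("ErpA", 1, rules=_rules((1, "!IscR-H & RyhB<2"))),
        NodeSpec("NfuA", 1, rules=_rules((1, "!IscR-H"))),
    )
    return LogicalModel("fes_wildtype", nodes)


def packaged_model_text() -> str:
    """Text of the model-definition file shipped with the package."""
    return (
        resources.files("feslogic").joinpath("data/fes_model.txt").read_text("utf-8")
    )


def load_packaged_model() -> LogicalModel:
    """Load the shipped model-definition file (must equal
    :func:`build_fes_model` — golden test)."""
    from .engine import parse_model

    return parse_model(packaged_model_text())


#: the 9 environmental conditions, row-major over (Fe_ext, O2)
CONDITIONS: tuple = tuple(
    (fe, o2) for fe in (0, 1, 2) for o2 in (0, 1, 2)
)

INPUT_SEMANTICS = {
    "Fe_ext": {0: "iron starvation", 1: "medium iron", 2: "iron replete"},
    "O2": {0: "anaerobiosis", 1: "aerobiosis", 2: "oxidative stress"},
}

#: biological-process modules whose joint oscillation pattern defines the
#: behavior classes; Suf, ErpA and NfuA behave on their own and are tracked
#: individually.
MODULES = {
    "oxidative_stress": frozenset({"H2O2", "OxyR", "Hpx"}),
    "iron": frozenset({"Fe_free", "Fur", "RyhB"}),
    "iscrsua": frozenset({"IscR-A", "IscR-H", "Isc"}),
}

TRACKED_NODES = ("Suf", "ErpA", "NfuA")

#: the six readout nodes of the published wild-type heatmaps
HEATMAP_NODES = ("Fe_free", "H2O2", "Isc", "Suf", "ErpA", "NfuA")


@dataclass
class AtlasEntry:
    """Attractor(s) of one (Fe_ext, O2) condition."""

    condition: tuple
    attractors: tuple

    @property
    def unique(self) -> bool:
        return len(self.attractors) == 1

    @property
    def attractor(self) -> Attractor:
        if not self.unique:
            raise MultipleAttractorsError(self.attractors)
        return self.attractors[0]

    @property
    def summary(self) -> dict:
        return summarize(self.attractor)


@dataclass
class ConditionAtlas:
    """Attractor summary for every condition of the 3x3 input grid.

    The substrate of the heatmaps, the behavior classification, and the
    perturbation screens. ``perturbation`` is the clamp applied on top of
    the inputs ({} for wild type)."""

    model: LogicalModel
    perturbation: dict
    label: str
    entries: dict = field(default_factory=dict)

    def __getitem__(self, condition: tuple) -> AtlasEntry:
        return self.entries[condition]

    def __iter__(self):
        return iter(self.entries.values())

    @property
    def conditions(self) -> tuple:
        return tuple(self.entries)

    @property
    def ambiguous_conditions(self) -> tuple:
        """Conditions with more than one attractor (never silently dropped)."""
        return tuple(c for c, e in self.entries.items() if not e.unique)

    def to_frame(self, nodes=None) -> pd.DataFrame:
        """Long-format summary table: one row per (condition, node)."""
        names = nodes if nodes is not None else self.model.names
        rows = []
        for (fe, o2), entry in self.entries.items():
            summary = entry.summary
            for node in names:
                a = summary[node]
                rows.append(
                    {
                        "perturbation": self.label,
                        "Fe_ext": fe,
                        "O2": o2,
                        "node": node,
                        "min": a.min,
                        "max": a.max,
                        "mean": a.mean,
                        "oscillating": a.is_oscillating,
                    }
                )
        return pd.DataFrame(rows)


def build_atlas(
    model: LogicalModel,
    perturbation: dict | None = None,
    label: str | None = None,
    conditions=CONDITIONS,
) -> ConditionAtlas:
    """Compute the attractor of every input condition under an optional
    perturbation clamp."""
    perturbation = dict(perturbation or {})
    if label is None:
        label = (
            "WT"
            if not perturbation
            else "+".join(f"{n}={v}" for n, v in sorted(perturbation.items()))
        )
    atlas = ConditionAtlas(model, perturbation, label)
    for fe, o2 in conditions:
        found = condition_attractors(model, {"Fe_ext": fe, "O2": o2}, perturbation)
        atlas.entries[(fe, o2)] = AtlasEntry((fe, o2), tuple(found))
    return atlas


def wildtype_atlas(model: LogicalModel | None = None) -> ConditionAtlas:
    """The wild-type attractor atlas over the 9 conditions."""
    return build_atlas(model if model is not None else build_fes_model())
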