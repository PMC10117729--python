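"""Module-level behavior classes and heatmap tables.

Each condition's attractor is reduced to an oscillation signature: for each
biological-process module (oxidative stress, iron homeostasis, IscRSUA) a
flag that is true iff at least one member node oscillates in the attractor.
Conditions sharing a signature form a behavior class. For the wild-type
Fe-S model exactly five signatures occur, labelled I-V:

  I   nothing oscillates (stable state; both inputs at level 1)
  II  iron module only (iron limitation without oxidative stress)
  III all but the oxidative-stress module (iron-replete, no stress)
  IV  all but the IscRSUA module (iron limitation plus oxidative stress)
  V   all three modules (iron-replete plus oxidative stress)

Signatures outside this table (which arise in mutants) get subsequent
Roman numerals in deterministic sorted order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fes import HEATMAP_NODES, MODULES, ConditionAtlas

__all__ = [
    "OscillationSignature",
    "BehaviorClassMap",
    "module_signature",
    "classify_grid",
    "heatmap_table",
]


@dataclass(frozen=True)
class OscillationSignature:
    """Per-module oscillation flags, in the module order given at
    classification time."""

    flags: tuple  # ((module_name, bool), ...)

    @property
    def oscillating_modules(self) -> tuple:
        return tuple(name for name, osc in self.flags if osc)

    @property
    def bools(self) -> tuple:
        return tuple(osc for _, osc in self.flags)


#: canonical labels for the wild-type Fe-S signatures, keyed by the flag
#: vector over (oxidative_stress, iron, iscrsua)
_CANONICAL_LABELS = {
    (False, False, False): "I",
    (False, True, False): "II",
    (False, True, True): "III",
    (True, True, False): "IV",
    (True, True, True): "V",
}

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV", "XVI",
]


def module_signature(summary: dict, modules: dict = MODULES) -> OscillationSignature:
    """Oscillation flag per module: true iff any member node oscillates.

    ``summary`` maps node -> NodeAsymptotics (see ``attractors.summarize``).
    """
    flags = []
    for name, members in modules.items():
        missing = set(members) - set(summary)
        if missing:
            raise ValueError(f"module {name!r} references unknown nodes {sorted(missing)}")
        flags.append((name, any(summary[n].is_oscillating for n in members)))
    return OscillationSignature(tuple(flags))


@dataclass
class BehaviorClassMap:
    """Partition of the condition grid by oscillation signature."""

    by_condition: dict = field(default_factory=dict)  # condition -> signature
    labels: dict = field(default_factory=dict)  # signature -> class label

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def label_of(self, condition) -> str:
        return self.labels[self.by_condition[condition]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "Fe_ext": fe,
                "O2": o2,
                "class": self.labels[sig],
                "oscillating_modules": "+".join(sig.oscillating_modules) or "none",
            }
            for (fe, o2), sig in self.by_condition.items()
        ]
        return pd.DataFrame(rows)


def classify_grid(atlas: ConditionAtlas, modules: dict = MODULES) -> BehaviorClassMap:
    """Classify every condition of an atlas by its module signature.

    Labels are stable across runs: signatures in the canonical wild-type
    table keep their Roman numeral; any others are numbered onward in
    sorted order of their flag vectors.
    """
    cmap = BehaviorClassMap()
    for cond in atlas.conditions:
        cmap.by_condition[cond] = module_signature(atlas[cond].summary, modules)

    distinct = set(cmap.by_condition.values())
    canonical = tuple(MODULES)
    used = set()
    leftovers = []
    for sig in sorted(distinct, key=lambda s: s.bools):
        module_names = tuple(name for name, _ in sig.flags)
        label = (
            _CANONICAL_LABELS.get(sig.bools) if module_names == canonical else None
        )
        if label is not None:
            cmap.labels[sig] = label
            used.add(label)
        else:
            leftovers.append(sig)
    remaining = (r for r in _ROMAN if r not in used)
    for sig in leftovers:
        cmap.labels[sig] = next(remaining)
    return cmap


def heatmap_table(atlas: ConditionAtlas, nodes=HEATMAP_NODES) -> pd.DataFrame:
    """Long-format data behind the published heatmaps: one row per
    (condition, node) with the mean level over attractor states (the
    heatmap color), the oscillation flag, and the level range."""
    frame = atlas.to_frame(nodes)
    return frame[
        ["perturbation", "Fe_ext", "O2", "node", "mean", "oscillating", "min", "max"]
    ]
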