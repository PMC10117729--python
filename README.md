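# feslogic

Qualitative dynamics of iron-sulfur (Fe-S) cluster biogenesis regulation in
*Escherichia coli*, modeled in the multivalued logical (Thomas) formalism
with asynchronous updating.

Fe-S clusters are essential protein cofactors whose synthesis is threatened
by the two stresses a bacterium meets most often: iron starvation (no iron
to build clusters) and hydrogen-peroxide stress (which destroys exposed
clusters and, via the Fenton reaction Fe²⁺ + H₂O₂ → HO·, turns free iron
itself into a hazard). *E. coli* runs two assembly machineries — Isc, the
housekeeping system, and Suf, the stress system — and chooses between them
through a regulatory network coupling the IscR transcription factor (in its
apo and holo forms), iron homeostasis (free intracellular iron, the Fur
repressor, the small RNA RyhB), and the OxyR-controlled peroxide response.

`feslogic` provides, for modelers and microbial physiologists:

- a **generic engine** for multivalued logical models: each node has a
  discrete level in `0..max_level` and ordered target rules
  `(target, Boolean expression)`; the effective target is the highest-level
  rule satisfied (default 0), and dynamics are *unitary asynchronous* — one
  node per transition, moving one level toward its target;
- **attractor analysis**: the full state transition graph (STG) of a
  clamped subspace is built and attractors are extracted as its terminal
  strongly connected components — stable states (size 1) or cyclic
  attractors (homeostatic oscillations), summarized per node by
  min / max / mean level over attractor states;
- the **encoded 14-node Fe-S network** (7 Boolean + 7 ternary nodes), with
  external iron `Fe_ext` and oxygen `O2` as ternary inputs spanning a 3×3
  grid of environmental conditions;
- **behavior classification** of each condition by which of the three
  biological-process modules (oxidative stress, iron homeostasis, IscRSUA)
  oscillate in the attractor — five classes I–V in the wild type;
- **in-silico knock-out screens**: clamp internal nodes (KO = 0, ectopic =
  higher level), recompute the atlas, and flag growth-defect conditions
  where both `Isc` and `Suf` are 0 in every attractor state;
- a **random-model generator** plus an independent brute-force attractor
  oracle (exhaustive reachability, no SCC machinery) used to validate the
  engine on ensembles unrelated to the biology.

## Worked example

```python
from feslogic import build_fes_model, wildtype_atlas, classify_grid, heatmap_table

model = build_fes_model()          # the 14-node network
atlas = wildtype_atlas(model)      # one attractor per (Fe_ext, O2) condition

entry = atlas[(1, 1)]
print(entry.attractor.kind, "size", entry.attractor.size)

table = heatmap_table(atlas)       # the data behind the published heatmaps
print(table[(table.Fe_ext == 2) & (table.O2 == 2)].to_string(index=False))

print(classify_grid(atlas).to_frame().to_string(index=False))
```

prints

```
stable_state size 1
perturbation  Fe_ext  O2    node     mean  oscillating  min  max
          WT       2   2 Fe_free 1.529412         True    1    2
          WT       2   2    H2O2 0.500000         True    0    1
          WT       2   2     Isc 0.500000         True    0    1
          WT       2   2     Suf 1.000000         True    0    2
          WT       2   2    ErpA 0.500000         True    0    1
          WT       2   2    NfuA 0.500000         True    0    1
 Fe_ext  O2 class           oscillating_modules
      0   0    II                          iron
      0   1    II                          iron
      0   2    IV         oxidative_stress+iron
      1   0   III                  iron+iscrsua
      1   1     I                          none
      1   2     V oxidative_stress+iron+iscrsua
      2   0   III                  iron+iscrsua
      2   1   III                  iron+iscrsua
      2   2     V oxidative_stress+iron+iscrsua
```

Reading this: at intermediate iron and oxygen (`Fe_ext=1, O2=1`) the system
sits in a single stable state — the only stable condition of the nine. Under
combined iron excess and oxidative stress (`2,2`) every module oscillates
(class V): free iron cycles between 1 and 2 with mean ≈ 1.53 (homeostasis
pulling it back toward its optimum), peroxide flickers as catalases catch
up, and the Isc machinery is intermittently shut by holo-IscR and RyhB. The
`mean` column is the unweighted average level over the attractor's states —
the color in a heatmap rendering.

Mutants are one call away:

```python
from feslogic import knockout, combine, mutant_atlas
atlas = mutant_atlas(model, combine(knockout("Fur"), knockout("OxyR")))
```

In this double mutant `Isc` is 0 and `Suf` is 1 stably in all nine
conditions — the stress machinery is the only one left running.

## Command line

```sh
feslogic atlas --out wt.csv              # wild-type condition atlas
feslogic classify                        # behavior classes I-V
feslogic mutant --clamp Fur=0,OxyR=0     # one perturbed atlas
feslogic screen --order 1 --ko-only      # growth-defect screen
feslogic generate --nodes 8 --seed 1 --out model.txt
```

Models travel as a plain-text definition format (see
`src/feslogic/data/fes_model.txt`, the shipped network) with rules in a
small grammar: atoms `Name` (≥1), `Name=k`, `Name<k`, `Name>=k`, operators
`!`, `&`, `|`.

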