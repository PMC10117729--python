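# Methods

## The formalism

A model is a set of named nodes, each carrying a discrete level
`0..max_level` (`max_level` is 1 for Boolean nodes, 2 for ternary ones).
Every non-input node has an ordered list of target rules
`(target_level, expression)`, where expressions combine level comparisons
(`X` meaning X≥1, `X=k`, `X<k`, `X>=k`) with `!`, `&`, `|`. In a given
state the node's *target* is the target_level of the first satisfied rule
when rules are scanned from the highest target down; if no rule is
satisfied the target is 0.

Two conventions deserve making explicit because published rule tables in
this formalism are often loose about them:

- **Highest-target-first scanning.** When rule rows are written in a
  mutually exclusive style this changes nothing; when a lower row
  logically overlaps a higher one, the higher level wins. For the Fe-S
  network the two readings coincide (the test suite sweeps all 279,936
  states and asserts at most one rule row per node is ever satisfied), but
  the convention makes the encoding robust to either style.
- **Unitary asynchronous updating.** One node updates per transition and
  moves one level toward its target, not directly to it (a node at 0 with
  target 2 passes through 1). This is the standard convention of the
  GINsim family of tools; direct-jump semantics would generate different
  transition graphs for multivalued nodes.

Input nodes (here `Fe_ext` and `O2`) are rule-less and are clamped to a
constant level per simulation; the same clamping mechanism implements
genetic perturbations on internal nodes (knock-out = 0, ectopic expression
= a nonzero level). Clamps on inputs and on mutated nodes compose by
union; two clamps on one node must agree.

## Attractors

The state transition graph (STG) over a clamped subspace has every state
of the subspace as a vertex — not just states reachable from some chosen
initial condition — and the unitary asynchronous successor relation as its
edges. Attractors are the terminal strongly connected components of the
STG, computed via graph condensation (networkx; iterative, so subspaces of
~3×10⁵ states pose no recursion risk). A configurable safety limit
(default 10⁶ states) guards against accidentally materializing huge
subspaces.

Computing over the full subspace reflects how the biological results are
stated: one attractor per environmental condition, with no initial state
singled out. For the Fe-S network every condition indeed has a unique
terminal SCC; the API still reports all attractors and flags multiplicity,
because arbitrary models can have several (e.g. a self-activator).

Each attractor is summarized per node by min, max, and the **unweighted
arithmetic mean** of the level over attractor states, plus an oscillation
flag (min < max). The mean deliberately ignores any notion of stationary
distribution — asynchronous logical dynamics are nondeterministic, not
stochastic, so no state-visit weighting is defined; the unweighted mean is
the quantity the original heatmaps display.

Stable states are additionally found by a direct subspace scan (target ==
current for every free node) with no graph construction; agreement between
this scan and the size-1 terminal SCCs is asserted in tests as a
cross-check of two independent code paths.

## The Fe-S network encoding

14 nodes: inputs `Fe_ext`, `O2` (ternary); ternary `Fe_free`, `Hpx`,
`Fur`, `RyhB`, `Suf`; Boolean `H2O2`, `OxyR`, `IscR-A`, `IscR-H`, `Isc`,
`ErpA`, `NfuA`. Level meanings are attached to the nodes as annotations
(e.g. `Fe_free`: 0 ≲ 1 µM, 1 ≈ 10 µM, 2 ≳ 50 µM free intracellular iron;
`O2`: anaerobiosis / aerobiosis / oxidative stress; `Hpx=0` exists only to
express the catalase/peroxidase knock-out). Notation used in some
published tables, such as "¬Hpx = 2", is encoded as the comparison it
denotes (`Hpx<2`); `!X` on a multivalued variable means X=0. The Suf
level-1 rule is encoded in its mutually exclusive form
(`Fur<2 & (OxyR | IscR-A) & !(OxyR & IscR-A)`), which under
highest-target-first scanning is equivalent to the looser
`Fur<2 & (OxyR | IscR-A)`.

The network ships both as a Python constructor (`build_fes_model`) and as
a model-definition text file (`data/fes_model.txt`); a golden test asserts
the two load identically and that the file round-trips byte-for-byte
through the parser and writer.

The rule-derived dependency graph yields 29 (regulator, target) pairs
(`Fe_free` has six regulators), whereas the drawn regulatory graph is
usually described with 28 arcs; since rule-derived pairs and drawn arcs
can legitimately count differently (e.g. merged multi-threshold arcs), the
node count (14) is enforced structurally but the edge count is not.

## Behavior classes

Three node modules track the biological processes: oxidative stress
{H2O2, OxyR, Hpx}, iron homeostasis {Fe_free, Fur, RyhB}, and IscRSUA
{IscR-A, IscR-H, Isc}. A condition's signature is the per-module flag "at
least one member oscillates in the attractor". Class identity is defined
by this three-module signature alone — `Suf`, `ErpA` and `NfuA` behave
individually and are reported but do not enter class identity; this
definition yields exactly five signatures on the wild-type grid, labelled
I–V to match their verbal descriptions (I stable; II iron only; III all
but oxidative stress; IV all but IscRSUA; V all three). Signatures outside
that table (mutants can produce them) receive subsequent Roman numerals in
deterministic sorted order, so labels are stable across runs.

## Perturbation screens

Single-mutant enumeration clamps each of the 12 internal nodes at each of
its levels: 29 variants (KO plus ectopic levels), or 12 in KO-only mode.
Double-KO screens cover all 66 unordered pairs. Input nodes are not
enumerated: environmental levels are conditions, not genotypes.

The growth-defect criterion is strict: a (perturbation, condition) pair is
flagged only when `Isc = 0` **and** `Suf = 0` in *every* attractor state.
An oscillation that transiently expresses either machinery still supplies
some Fe-S biogenesis and is not flagged. Under this criterion the wild
type is never flagged; among single KOs exactly the apo-IscR KO and the
Suf KO produce defects, and every defect-bearing double KO contains one of
those two — the model's central testable predictions.

## The random-model generator and oracle

`synth.random_model(GeneratorConfig(...))` generates well-formed models
for engine validation: node count, ternary fraction, input count, rule
density (expected regulators per node, drawn per node from a normal
approximation with a floor of one regulator), and a seed; the same config
and seed reproduce the identical model byte-for-byte through the text
format. Expressions are generated in disjunction-of-conjunctions normal
form so the grammar round-trips. The ensemble emulates the *formal*
properties the engine must handle — mixed Boolean/ternary nodes, multiple
rule rows, overlapping or contradictory rules, clamped inputs — not
biologically realistic topology (no scale-free structure, no signed
feedback design); passing it validates the dynamics engine, not any
biological conclusion.

`synth.brute_force_attractors` is the independent oracle: it enumerates
transitions through the interpreted rule evaluator (not the compiled one
used for STG construction) and finds attractor states by exhaustive
per-state reachability closures — a state is in an attractor iff every
state it can reach can reach it back — with no SCC algorithm involved. It
is quadratic and capped at 10⁴ states; equivalence with the terminal-SCC
pipeline is asserted on 50+ random models across every input clamp.

## Numerical and procedural choices

- States are tuples of ints in a fixed node order (the order the nodes
  are declared in), giving bit-reproducible iteration, stable CSV row
  order, and hashable graph vertices. Attractor lists are ordered by their
  lexicographically smallest state.
- Rule evaluation for STG construction is compiled to plain Python
  comparison expressions per node (≈20× faster than the interpreted
  walker); the interpreted path is kept as the readable reference and the
  two are asserted equal on random probes.
- Problem sizes: per condition the clamped wild-type subspace has
  3⁵ × 2⁷ = 31,104 states; the full screen (wild type, 12 single KOs, 66
  double KOs across 9 conditions each) therefore runs a few hundred STGs,
  which the compiled evaluator completes in a few minutes on one core.
  The engine-vs-oracle ensemble uses 4–8-node models (subspaces ≤ ~3,000
  states) because the oracle is deliberately quadratic.
- The acceptance script is exact and deterministic; its `--seed` only
  shuffles condition evaluation order as a determinism probe.

## Known limitations

- Synchronous, priority-class, and direct-jump update semantics are not
  implemented; all results are unitary-asynchronous.
- No reachability analysis from user-chosen initial states and no
  basin-of-attraction computation: the unit of analysis is the condition,
  not the trajectory.
- Attractor means are unweighted; they should not be read as expected
  expression levels under any stochastic semantics.
- The five behavior classes are a wild-type notion; mutant grids reuse the
  labels where signatures match and invent new ones otherwise.
- Oscillations in these attractors are qualitative homeostatic cycles;
  their amplitude/period have no quantitative interpretation, and real
  expression noise, delays, and continuous concentrations are outside the
  formalism.
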