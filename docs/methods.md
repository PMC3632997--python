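# Methods

This note records the scientific and numerical choices behind the
package: what is modeled, how the inference and tracing are defined, what
the generated test models do and do not emulate, and where genuinely open
design questions were settled.

## The representation

A map holds *entity* nodes and *process* nodes. An entity is identified
by its **borne-entity key**: the bearer chain of its composite annotation
(base entity term plus structural refinements such as
`contained-in`), or, for unannotated species, its normalised free label.
The physical property observed on the entity is deliberately *not* part
of its identity: in the circulatory example the upstream evidence for a
flow is a pressure (a force property) and the downstream evidence a
volume (an amount property) of the *same* portion of blood, and a
property-inclusive identity would split that blood pool into two nodes.
The observed amount-class property is kept on the entity as
`amount_property`. Composite-annotation equivalence between *variables*
(`annotations_equivalent`) remains the strict element-wise comparison
including the property term; subsumption-aware matching (e.g. a specific
blood portion against a broader anatomical class) is intentionally not
performed — exact matching never unifies wrongly, at the cost of missing
some unifications.

Flow processes carry a biophysical domain (fluid, chemical, electrical,
diffusion) and role-tagged participants with stoichiometry; modulation
processes carry a regulator entity, a target (process or entity) and a
polarity in {−1, 0, +1}. A mediator participant is assumed to enable its
flow positively (enzyme-like); an effector whose direction is unknown
should be encoded as a polarity-0 modulation instead, which the tracer
treats as "could act either way".

## The term registry

The shipped registry is a small TSV forest: property terms classified
under three anchors (dynamical flow rate, force property, amount
property) with per-term biophysical domains, plus process, domain and a
handful of entity terms used by the bundled generators. CURIEs are
local (`opbx:`, `fmax:`, `chebix:`); an `external_iri` column carries a
real identifier where one is certain (a few ChEBI small molecules) and
is otherwise empty, so reconciliation against the full ontologies can
happen later without fabricated identifiers. Property classification
walks the parent chain to the nearest anchor; the anchors themselves are
abstract and carry no domain. Entity CURIEs outside the registry are
accepted as opaque identifiers throughout (full FMA/ChEBI import is out
of scope), which is also why random-network species terms need no
registry entries.

## Ingestion

SBML Level 2/3 is read with a namespace-tolerant parser covering the
subset the inference needs: species/compartments/parameters, reactions
with kinetic-law MathML, rate and assignment rules, MIRIAM
biology-qualifier annotations (`is` and `isVersionOf` both accepted,
since tools vary) and SBO modifier terms (inhibitor family → −1,
stimulator/catalyst family → +1, anything else → 0). For every non-boundary
species touched by reactions the implied mass balance
`dS/dt = Σ ±ν·v` is synthesized as an equation, so the dependency graph
reflects the full equation system the file encodes. Reaction rate
variables are annotated as chemical molar flow rates — a reaction rate
*is* one — which is what makes the dependency path applicable to models
read from SBML. Boundary-condition species are ingested as ordinary
variables but flagged as clamped. Piecewise math and events are outside
the expression language; such constructs are retained dependency-wise
with a warning and their dependence signs report indeterminate.

The equation-model format is a minimal line-oriented stand-in for
equation-based modeling languages: `var` declarations with inline
composite annotations, `eq x = …` assignments, `eq x' = …` derivatives
and `init` values, with `name'` chosen as the derivative marker for
being unambiguous in one token. Undeclared symbols become unannotated
parameters with a warning so circuit constants need no ceremony.

## Dependence signs

The sign of `∂(rhs of v)/∂u` is estimated by central finite differences
at the model's nominal operating point (unvalued symbols default to 1.0,
a positive point that avoids spurious zeros in monotone rate laws), with
relative step 1e−6 cross-checked at 1e−4: agreement yields the sign, a
flip or an evaluation failure (e.g. division by zero at the nominal
point) yields *indeterminate*, and |difference| < 1e−12 yields 0. The
two-step cross-check guards against cancellation artifacts. The suite
validates the estimator against symbolic differentiation on a library of
linear, ratio, mass-action and Hill-type forms.

## Participant inference

For each flow-rate variable, a breadth-first traversal of the dependency
graph runs upstream (what the rate depends on) and downstream (what
depends on the rate), passing through unannotated, other-property and
wrong-domain variables, and stopping each branch at the first
force/amount variable of the flow's own domain — deeper drivers are
taken to be mediated by the nearer one. A hop limit of 10 guards
pathological chains; a visited set handles cycles (each variable expands
once per direction, and conflicting same-depth path signs collapse to
indeterminate). Each evidence record composes the edge signs along its
path.

Role assignment: upstream `+` → source, upstream `−` → sink,
downstream `+` → sink, downstream `−` → source. An entity assigned both
source and sink with definite signs is demoted to mediator with a
recorded warning (it participates, but the orientation is contradictory —
the symmetric-conflict case). Wrong-domain or indeterminate evidence
becomes a polarity-0 modulation.

One genuinely open question was whether a same-domain amount variable
that feeds a rate law is a driver or a modulator. The rule adopted here:
if the entity also shows **downstream mass-balance evidence** for that
flow (it is moved by the flow), it is a participant; if it only feeds
the rate law, it is a modulator, emitted as a modulation process whose
polarity is the sign of the dependence. This is the physically faithful
reading — an enzyme in `v = k·S·E` affects the rate without mass
transfer — and it is what makes the explicit-tag and dependency paths
produce isomorphic maps on models whose modifiers appear in the kinetic
math. Force evidence is always a driver: forces are not conserved
quantities and cannot be "consumed" as a mass-balance check would
require. Flows with no definite evidence at all still produce a process,
flagged unresolved, with an implicit `environment` entity on the empty
side; reactions with an empty reactant or product list get the same
environment treatment. Reversible reactions map to a single flow process
(a negative instantaneous rate is a tracing concern, not a structural
one).

## The signed influence graph and tracing

Sources, mediators and regulators influence their process with `+1`; a
flow influences its sinks with `+1`; a modulation passes its polarity to
its target. Source-pool depletion (`flow → source` with `−1`) is off by
default — the default reading is downstream increments — and available
via `include_depletion`. Modulations targeting a flow process contribute
the one process-to-process edge kind, so the graph is bipartite in the
sense that entities are never adjacent to entities.

Propagation is a monotone fixed point over the join-semilattice
`unset < up, down < ambiguous`: a node's state is the join of its
initial perturbation and, over incoming edges, the transmitted state
(`+1` preserves, `−1` flips up/down, `0` transmits ambiguous from any
active source — an unlabeled modulator may act either way, and silence
would understate uncertainty). `clamp` models a variable held constant
experimentally: it absorbs influence and transmits nothing. Within
cycles this least-fixed-point semantics means a node reached with
conflicting signs reads ambiguous — the conservative qualitative-reasoning
choice; loops themselves are reported separately. Since each node can
climb the lattice at most twice, the sweep count is bounded by 2·|nodes|,
which the suite asserts on cyclic fixtures.

Path enumeration is depth-first over simple paths with lexicographic
neighbor order and a configurable length cap (default 12); a path's sign
is the product of its edge signs, indeterminate if any edge is 0. Loop
detection enumerates elementary cycles (cap 20), canonicalised to start
at their smallest node; polarity is the parity of negative edges, with
any 0-sign edge making the loop indeterminate.

## Merging

Entities unify by borne-entity key (free-label entities only by
normalised exact label — never unify unannotated species on structure).
Processes unify only on their **full** signature: kind, domain, and the
complete participant set with roles and stoichiometries; modulations
additionally require the regulator, the (signature-resolved) target and
the polarity. Pairs equal up to stoichiometry or polarity are conflicts:
both variants are retained under disambiguated ids and reported. Partial
participant overlap is never a match. Matching is multiset-aware (a
signature occurring twice in one map consumes two matches). Semantic
content of a merge is order-independent; id assignment is not, so the
report carries per-node provenance (`m1`, `m2`, `m1+m2`).

## Generated models and the numeric oracle

*Glycolysis toy*: a six-metabolite linear chain with five irreversible
mass-action reactions and two clamped modifier pools — AMP multiplying
the phosphofructokinase-step rate (stimulator) and ATP dividing the
pyruvate-kinase-step rate (inhibitor), mirroring the classic allosteric
regulators. It reproduces the *topology* of the pathway's textbook
fragment; rate constants (0.8–1.2) and initial amounts are round
placeholder values, not any published parameterization — the tested
surface is structure, not kinetics.

*Cardiovascular ring*: n elastic compartments (default 4, the first two
named LV and aorta) in a closed loop with `V' = F_in − F_out`,
`P = V/C`, `F = ΔP/R`; volumes 40–100, compliances 1–3, resistances 1.
The closed ring conserves total volume, which doubles as an integrator
check (RK4 preserves linear invariants to rounding).

*Random networks*: seeded mass-action networks. The general form draws
1–2 reactants and products with stoichiometries in {1, 2}; the acyclic
form emits single-reactant/single-product reactions along a fixed
species order, which guarantees the signed graph (depletion off) is a
DAG *and* that qualitative reachability coincides with the ODE influence
pattern: with single-reactant mass action, consumption enters the
Jacobian only on the diagonal, so depletion creates no cross-variable
influence the map omits. Modulated reactions in the acyclic form draw
their substrate from a dedicated clamped boundary pool for the same
reason — modulating a rate must not numerically drain a dynamic pool the
depletion-off map cannot see. Modifiers always act through the rate law
(`·M` or `/(1+M)`) with the matching polarity tag, so both inference
paths see the same physics. These are structural constraints of the
generator, chosen so the concordance property is a theorem of the
construction rather than an accident of parameters; real models with
multi-substrate kinetics or modulator-driven depletion would need
depletion edges on for faithful tracing, which is exactly why the flag
exists.

The numeric oracle integrates baseline and perturbed trajectories
(initial value of the perturbed variable × 1.001) with fixed-step RK4 —
deterministic and dependency-light; the default step keeps
`k_max·dt ≤ 0.01` — and reports response signs at the probe time with a
1e−9 dead band. Probe time 1.0 with rate constants in [0.5, 2] keeps the
deepest responses in the generated networks (≤ 6 hops) orders of
magnitude above the dead band while short enough that sign structure,
not equilibration, is measured.

What passing these checks does *not* show: correctness on stiff or
oscillatory dynamics (fixed-step RK4 and short probes would both
mislead), on models whose annotations are wrong or missing (the
dependency path silently degrades to boundary flows), or on qualitative
predictions through cycles, where the fixed point is deliberately
conservative (ambiguous) rather than sharp.

## Serialization and determinism

The XML format sorts node ids and writes attributes in a fixed order,
UTF-8 with LF endings, so write→read→write is byte-identical and equal
maps have equal files; the schema version is `1.0`. All traversals
iterate in sorted order and every generator is seeded, so identical
inputs give byte-identical outputs across runs and platforms. Problem
sizes used by the bundled verification runs (50 random networks for
path agreement, 100 for trace concordance at 8 species / 6 reactions,
20 merge pairs) were chosen as the smallest sets that exercise the
combinatorial variety of the generators while keeping the whole
verification run in seconds.

## Known limitations

Capacitive and transducer processes (energy storage and cross-domain
conversion) are not inferred — only flow and modulation. Temporal
process relations are representable in the XML schema in principle but
never inferred. CellML/JSim sources are not read; the equation-model
format is the ingestion path for equation-based models. Unit checking is
absent. Composite-annotation matching is exact, so semantically
overlapping but differently-grained annotations will not unify.
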