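# Methods

This note records the semantics the engine implements, the numerical
and design choices made where the design was genuinely open, what the
bundled models emulate, and the known limitations.

## Language semantics

**Grammar.** Statements are `;`-terminated; `//` starts a comment.
`+` separates multiset elements, `{}` encloses compartment contents,
and `()` holds attribute constraints — the two are interchangeable on
a species occurrence (`C(?a+?b)` is a content pattern), with bare
names inside `(...)` resolved during type checking (attribute binding
if the name is an attribute of the species, content species if it is
a declared species).  Counts in `init` and on rule right-hand sides
are unary or parenthesized expressions (`10 A`, `(2+3) A`,
`(L.n) mRNA`); a sum used as a count must be parenthesized because
`+` separates elements.  A species is a *compartment* exactly when
some occurrence anywhere in the model carries a content block.

**Matching.** A rule's reactants are matched inside one *context*
compartment (any compartment, including the root scope).  Matching
runs against the grouped canonical state: identical non-compartment
entities are merged per (species, attribute-tuple) *variant*, and one
reaction instance is created per (rule, context, variant combination,
compartment-instance combination).  Compartment instances are
individuals and are never merged.  For several syntactically
interchangeable patterns of one species, instances/variants are
assigned as unordered selections, so a reactant pair is instantiated
once, not twice.

**Kinetics are explicit.** The rate expression evaluated in a match
*is* the propensity; no mass-action factors are inserted.  Write
`k*#m` (or `k*#m*(#m-1)` for pairs) with a population binding
`mRNA:m`.  Availability guards (reactant counts, dynamic
compartment-attribute constraints, exact-content checks) multiply the
propensity, so an instance whose reactants are exhausted has
propensity zero and revives automatically when counts recover; this
also means the enumerated network contains instances for every
*reachable* variant, not only currently present ones.

**Content blocks.** A left-hand-side content block without a sequence
variable matches the content *exactly*; write `?rest` to allow
residual content.  A compartment pattern without any content block
leaves the content untouched.  Source-free rules (`-> A @ k`) apply
at the root scope only; matching them in every compartment would be
ambiguous.

**Reachable variants.** Enumerated attributes must have statically
computable update values; the engine closes the set of variants under
all rule productions, starting from the state's variants.  An
attribute updated with state-dependent or sampled values must be
declared network-free, and the closure aborts with "model too large"
past the configured index cap (default 10⁶ indices), which is also
enforced on the (instance × variant) slot space.

**Units.** Five base dimensions: length, time, amount, mass, volume
(volume is deliberately independent of length³; litres and cubic
metres do not interconvert).  Literals are rescaled to canonical
units (m, s, mol, kg, L) at type-checking time, so the runtime sees
pure floats.  Rates must reduce to 1/time **or** be fully
dimensionless — a dimensionless rate means "per canonical time unit"
(seconds); this keeps unitless toy models writable.  Trajectory CSVs
report time in canonical seconds unless the model's constants were
written in other units, in which case conversion happened on input.

## Classification and rewriting

A rule is **structural** iff it creates or deletes a compartment
(unpaired compartment occurrence on either side after pairing k-th
left occurrence with k-th right occurrence of each species per
content level), or moves/drops a sequence variable relative to its
binding slot.  Everything else — attribute updates, count changes,
molecules shuttling between two preserved compartments — is
**regular** and runs on the flat state.  Classification is per-rule
and conservative.

Structural rewriting consumes the matched reactants, extracts each
content block's residual, binds it to the block's sequence variables
(splitting with the weight law `R_j/ΣR`, each entity copy assigned
independently; a child compartment travels as an atomic unit with its
contents — recursing into it would violate compartment integrity),
destroys unpaired left compartments together with any unbound
content, then builds the right side.  In a fusion the first-matched
instance — compartment combinations are enumerated in ascending
instance-id order, so the lowest id — keeps its identity; new
compartments draw fresh ids from a per-run monotone counter.  After a
rebuild the exponential clock restarts: by memorylessness this is
exact for CTMCs.  The sampled (dt, selection) pair that chose the
structural reaction is consumed, the clock advances to the firing
time, and the event is applied on the tree.

## SSA numerics

* Selection walks one uniform draw down the cumulative-sum tree in
  (own value, left subtree, right subtree) order; comparisons are
  strict `<` against the node's own propensity and `<=` on subtree
  entry.  A linear cumulative scan in the same order is the testing
  oracle.
* Updates are two-phase: changed node values first, then the
  de-duplicated ancestor set recomputed children-first.  Each
  affected subtree sum is recomputed from its children, never
  adjusted incrementally, so floating-point error is bounded by one
  summation over the tree depth and does not grow with step count
  (measured ≲ 10⁻¹⁵ relative after 10⁶ updates).
* Exactly two uniforms per regular step (waiting time via
  `-log1p(-u)/total`, selection).  Network-free instance choice and
  structural-rewrite sampling draw additional variates from the same
  stream when those events occur.
* Replication r of a run with base seed s uses
  `SeedSequence((s, r))`; identical configuration and seed give
  byte-identical outputs.
* Reactions are laid out in descending build-time propensity; the
  layout is never re-sorted mid-run (sorting is a build-time choice,
  and rebuilds are frequent enough in structural models to refresh
  it).
* A propensity evaluating negative, NaN or infinite aborts with a
  model error naming the rule; division by zero in a rate is an
  error, not a silent zero.

**Performance templates.** Bound rate expressions are rendered to
Python source with every literal and state index abstracted into a
parameter vector; the source string is the cache key, the compiled
callable is shared by all expressions of that shape, and the cache
persists across rebuilds (observable: zero compilations on a rebuild
of an unchanged rule set).  The tree-walking interpreter is the
semantic reference (property-tested to 10⁻¹² relative agreement) and
evaluates cold paths: firing-time effects, split weights, samplers.
An on-disk cache was considered and omitted: compiling a shape costs
microseconds, so persistence would only add invalidation hazards.

**Network-free attributes.** Per-copy values live in vectors keyed by
(instance, variant), kept in lock-step with the count array.  Rules
constrained on network-free attributes use the *eligible count* in
their propensity (exact, not rejection sampling), maintained through
the same dependency edges; the fired instance is drawn uniformly
among eligible ones (a choice — the semantics only require some
instantiation).  Rates may use eligible counts but cannot aggregate
over network-free values (e.g. a sum of volumes); that is a
documented limitation.

**Observables** are pattern-count queries (optionally scoped to a
parent compartment species) sampled on a fixed grid; samples at a
grid point coinciding with a structural event reflect the post-event
state, while timed-event boundaries record the pre-event state.
**Timed events** are configuration-level interventions (currently: a
species purge at root or global scope) that interrupt the static run,
edit the tree and rebuild — they are not rule syntax, since their
semantics (instantaneous, exhaustive) differ from CTMC transitions.

## Bundled models and what the tests show

The analytic toys pin the engine to closed forms: immigration–death
(stationary law Poisson(k/d)), the Yule compartment splitter (mean
e^{kt}, exercising the full rebuild loop), weighted fission (binomial
split law), shuttle/entry toys (conservation, regular-vs-structural
classification), and a network-free/enumerated twin model (identical
CTMC, distributions compared by KS).  The synthetic generator emits
bounded models (every species decays; fission rates scaled down) that
typecheck by construction; it covers the regular engine paths and
compartment fission/dissolution/creation, but not deeply nested rule
patterns or units, which the case studies and hand-written tests
cover instead.

The two case-study files are structural transcriptions: species
counts, rule structure, initial state (1 cell + 200 lipoplexes;
washing event at 1 h) and the printed rule forms are faithful, but
the kinetic constants are stand-ins chosen for plausible qualitative
behaviour (the yeast MPF oscillator was tuned to relax-oscillate with
a cycle of order 100–200 minutes; the mRNA model to a regime where
most replications deliver nothing).  Quantities that depend on those
constants — structural-change counts, zero-protein fractions,
division times — are *measured and reported* by the acceptance
script, not asserted as test gates.  Passing tests therefore
demonstrate engine correctness on the analytic laws and structural
facts, not quantitative reproduction of the original studies.

Problem sizes in the default suite and acceptance script (10⁴-step
oracle lockstep runs on 20 models, 10⁵ chi-square samples, 10³
replications for growth/KS laws, 10⁶ tree updates, 6–8 case-study
replications) were chosen as the smallest sizes at which the
statistical tolerances (3σ, α = 0.01) are meaningful.

## Known limitations

* No SBML import/export; no tau-leaping or next-reaction scheduling;
  rebuilds are always global (no localized partial rebuilds).
* Enumerated `real` attributes are allowed but only useful with a
  finite reachable value set; otherwise declare them network-free.
* `S.attr` requires a unique left-hand occurrence of species S in the
  rule; disambiguation across repeated species uses bare attribute
  bindings.
* Exact-content matching and `#seqvar` counts create dependency edges
  on all of an instance's slots, which can make updates conservative
  (over-approximation is by design; under-approximation never
  occurs).
* A sequence variable placed inside a counted compartment production
  (`N C{?x}` with N > 1) is not supported.
* Unit names are reserved in numeric-literal position (`2 m` is two
  metres); constants named like units remain usable everywhere else.
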