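# compartsim

Rule-based stochastic simulation of cell-biological models with
**dynamic nested compartments** — compartments that are created,
deleted, fused, split, and that enter or leave one another while the
simulation runs.

`compartsim` is for modelers who want to write processes like
endocytosis, organelle fission/fusion, viral entry or cell division as
single rewriting rules instead of manually unrolled reaction lists,
and for methods developers who need an exact, inspectable reference
engine for compartmental SSA variants.

## The model class

A model is a finite set of multiset-rewriting rules

```
<left> -> <right> @ <rate>;
```

with continuous-time Markov chain semantics: each concrete match of a
left-hand side is a potential transition with propensity `p_i` given
by the rate expression evaluated in that match; sojourn times are
exponential with rate `Σ p_i` and the next reaction is a weighted
random choice.  Species carry named, typed attributes (`int`, `real`,
`string`, `enum`, and the network-free kinds `nf_int` / `nf_real`),
numeric literals and constants carry units of measurement that are
checked and converted at compile time, and `{}` denotes nesting:

```
Cell{ L{?solL} + ?solC } -> Cell{ ?solL + ?solC } @ kU;       // unpack
Mito( ?m1[R1] + ?m2[R2] ) -> Mito(?m1) + Mito(?m2) @ kF;      // weighted fission
```

Sequence variables `?x` bind the residual content of a compartment;
in a split, each residual element is assigned to branch *j* with
probability `R_j / Σ R`.

## The engine

The simulator is a hybrid of a fast static SSA and a tree rewriter:

1. every rule is classified **regular** (pure count/attribute updates)
   or **structural** (changes the compartment tree);
2. the compartment tree is flattened to index-based count and
   attribute arrays and all concrete reactions are enumerated;
3. an exact SSA runs on a **binary tree with cumulative-sum
   tracking** (O(log n) selection and update, likely reactions sorted
   toward the root, two-phase de-duplicated ancestor updates from
   precomputed plans, no error accumulation over steps), updating only
   the propensities a firing can affect via a dependency graph;
4. when a structural reaction fires, the state is converted back to
   the tree, the rewrite is applied there, and the flat simulator is
   rebuilt from scratch — costly, but amortized while structural
   events are rare.

Rate expressions are evaluated through cached **performance
templates**: each expression shape is compiled once to a callable with
constants and state indices abstracted into parameters, and reused
across reactions and rebuilds.  Attributes declared network-free are
kept out of the enumerated network; their per-copy values live in
instance vectors consulted when a rule fires.

## Worked example

Three lipoplexes, each carrying 350 mRNA, unpack inside a cell; the
released mRNA is translated:

```python
from compartsim import load_model, SimConfig, run

text = """
const kU: 0.4;          // lipoplex unpacking, per lipoplex in the cell
const kT: 0.05;         // translation initiation, per mRNA
species Cell(); species L(); species mRNA(); species Protein();
init 1 Cell{ 3 L{ 350 mRNA } };
Cell{ L{?load} + ?c } -> Cell{ ?load + ?c } @ kU;
Cell{ mRNA:m + ?c } -> Cell{ mRNA + Protein + ?c } @ kT*#m;
observe free_mRNA: mRNA in Cell;
observe Protein: Protein;
observe Lipoplexes: L;
"""
model = load_model(text)
print([(r.idx, r.kind) for r in model.rules])
traj = run(model, SimConfig(t_end=20.0, seed=42, interval=5.0))
print(traj.to_dataframe().to_string(index=False))
print(traj.n_regular, traj.n_structural, traj.n_rebuilds)
```

prints

```
[(0, 'structural'), (1, 'regular')]
 time  free_mRNA  Protein  Lipoplexes
  0.0        0.0      0.0         3.0
  5.0     1050.0    177.0         0.0
 10.0     1050.0    436.0         0.0
 15.0     1050.0    691.0         0.0
 20.0     1050.0    928.0         0.0
928 3 3
```

The unpack rule is structural (it deletes a lipoplex compartment and
transplants its content), so the three unpacking events each trigger
a simulator rebuild; the 928 translation firings run on the static
engine in between.  All 3×350 mRNA end up free in the cell —
content transplanting conserves entities — and protein accumulates at
rate `kT · 1050` per time unit thereafter.

## Command line

```sh
compartsim validate model.mlr3            # typecheck + rule classification
compartsim run model.mlr3 --t-end "30 h" --reps 10 --seed 1 \
    --event "purge:L@1 h" --out-dir out/  # CSV trajectories + event logs
compartsim bench model.mlr3 --t-end "1000 min"
compartsim generate --species 4 --rules 8 --compartment-types 1
```

Exit codes: 1 for model errors (with line/column diagnostics), 2 when
the enumerated network exceeds the configured index cap.

Bundled under `compartsim.fixtures`: analytic toy models
(immigration–death, Yule compartment splitter, weighted fission,
protein shuttling, virus entry, a network-free/enumerated twin pair),
a deterministic synthetic-model generator, and transcriptions of a
fission-yeast multicellular cell-cycle model and an mRNA-delivery
model (stand-in kinetic constants; see the file headers).

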