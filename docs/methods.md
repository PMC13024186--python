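# Methods

`cherryrules` mines Pareto-optimal sets of interpretable if–then interval
rules that classify cherry fruit fly (*Rhagoletis cerasi*) infestation
levels — Low, Medium, High — from ten numeric pomological measurements per
fruit sample. This note documents the model, the parameters that matter,
the synthetic-data design, and the numerical choices an implementer or
reviewer would want spelled out.

## Problem setting and data model

Infestation classes derive from adult flies captured in yellow sticky
traps: counts of 0–5 are Low, 6–10 Medium, and strictly more than 10 High.
A count of exactly 10 is ambiguous between the Medium and High
definitions; this package resolves it to Medium (High is *strictly* more
than 10). The choice is localized in `dataset_io.label_from_trap_count`.

The canonical feature schema is the ten measured fruit traits with their
observed ranges (Color 1–5, Weight 2.86–7.03 g, Width 14.28–23.26 mm,
Length 15.23–29.89 mm, StemLength 13.01–19.81 mm, Hardness 14.44–61.14,
Core_weight 0.60–10.0 g, SCKM 12.7–17.0 °Bx, NaOH 8.83–15.48, Acidity
0.59–1.07 %). SCKM is the soluble-solid-content attribute. These ranges
are the coordinate frame for genome decoding; decoded rule bounds can
never leave them.

## Rule representation and objectives

An individual is three parallel vectors in [0, 1], one entry per feature:
inclusion scores, lower-bound scores, upper-bound scores. Feature *i*
enters the rule antecedent iff its inclusion score exceeds the threshold
λ (default 0.5). Active bounds decode affinely into feature units:
`min_i + score · (max_i − min_i)`. Two totality repairs keep the
genome→rule map defined everywhere:

* if the decoded lower bound exceeds the upper, the two are swapped;
* if no feature clears λ, the single feature with the highest inclusion
  score is forcibly activated.

A rule's antecedent is a conjunction of **closed** intervals
(`lower ≤ value ≤ upper`); the rendered text prints `<` purely as display
convention. On continuous data the distinction has measure zero.

Rule quality against a labeled dataset is one-vs-rest: antecedent true
and label equal to the target class is a true positive; both false a true
negative; true/unequal a false positive; false/equal a false negative.
The three maximized objectives are accuracy `(TP+TN)/total`, precision
`TP/(TP+FP)` and recall `TP/(TP+FN)`, with precision and recall defined
as 0 when their denominator is 0 — a rule that never fires earns nothing,
which is the right penalty in a maximization context.

## The evolutionary engine

The engine is a strength-Pareto evolutionary algorithm (SPEA2) over the
three objectives. Per generation, for every individual *i* in the union
of population and archive:

* strength `S(i)` — the number of pool members *i* dominates;
* raw fitness `R(i)` — the summed strengths of *i*'s dominators
  (0 exactly for the non-dominated);
* density `D(i) = 1 / (σ_k + 2)`, with `σ_k` the Euclidean distance in
  objective space to the *k*-th nearest other member,
  `k = round(√(N + N̄))` by default (6 for the default 20+20 sizes);
* fitness `F(i) = R(i) + D(i)`, minimized.

Since `D ≤ 1/2`, `F < 1` holds exactly for the non-dominated members.
Environmental selection admits all of them, fills an under-full archive
with dominated individuals in ascending `F` (ties by insertion order),
and truncates an over-full one by repeatedly deleting the member with the
lexicographically smallest sorted distance vector to the others (the
classic crowding truncation; final ties go to the lowest index). The
density formula is the canonical SPEA2 choice; the framework description
this implements names only "k-nearest neighbour", and `1/(σ+2)` is the
standard form that guarantees `D < 1` so that the "fitness below 1"
selection rule picks exactly the non-dominated set.

Mating draws from the archive only, by binary tournament (two uniform
draws with replacement, lower `F` wins, ties to the first drawn).
Offspring replace the whole population each generation. Crossover
(probability 0.8) is uniform at *gene-triple* granularity: the whole
(inclusion, lower, upper) triple of a feature is swapped between
offspring with probability 1/2, keeping interval encodings coherent.
Mutation (probability 0.1 per gene) replaces the gene's value with the
next value of the run's tent-map stream — value replacement, not
perturbation, which is the reading under which the mutation is literally
chaotic. The loop runs a fixed number of generations (default 100, no
early stopping), with one final fitness assignment and environmental
selection after the last breeding step; a zero-generation run therefore
returns the environmental selection of the initial population. Objective
evaluation during evolution uses the training split only; test metrics
are computed once on the returned rules.

## The tent-map stream and its degeneracy guard

Chaos enters in exactly two places — initialization (the population is
filled row-major from one continuous stream) and chaotic mutation. All
other randomness is an ordinary seeded PRNG, so a run is reproducible
from the pair (chaos seed, PRNG seed).

The tent map at control parameter 2 is uniformly distributed in exact
arithmetic but degenerate in floating point: doubling shifts one mantissa
bit out per step, so every double-precision orbit collapses onto a dyadic
rational — and then the absorbing fixed point 0 — within about 50 steps.
The guard detects any raw iterate outside `(ε, 1−ε)` with `ε = 1e−9` and
re-seeds the orbit at `frac(x + j·φ)`, clamped into the open interval,
where φ = 0.6180339887 and *j* counts guard events on the stream. The
event index matters: a stateless re-seed `frac(x + φ)` restarts every
collapsed segment near φ (at guard time `x` is always close to 0 or 1),
correlating the segments and measurably biasing the long-run mean (≈0.525
over 10⁴ iterates). Walking the restart points along the golden-ratio
Weyl sequence keeps them equidistributed; measured 10⁴-iterate means sit
at 0.500–0.502 across seeds, and guarded orbits stay strictly inside
(0, 1) for 10⁶ iterates from 1000 random seeds.

## Experimental protocol

The mining protocol is one-vs-rest: a separate evolutionary run per
target class. The repeated-experiment harness performs, per class, *n*
independent runs (default 10), each with a fresh stratified 70/30 split
and fresh seeds (run *r* uses PRNG seed `base + r` and a chaos seed
stepped along the Weyl sequence), then reports min/max/mean/median/std
over the runs of each metric's per-run best value, on both splits.

Stratified splitting rounds `train_fraction × class_count` half-up
independently per class, with no global correction — stratification is
preserved exactly and the overall fraction may deviate by a sample or
two.

## Synthetic data

The field dataset the protocol was designed around (381 samples; 204 L,
101 M, 76 H) is not publicly distributed, so the package ships two
generators.

**Compositional generator.** Emits exactly the configured per-class
counts (defaults 204/101/76). Each feature is drawn from a normal clamped
to the schema range, centred at `midpoint ± class_shift/2 · range` (L
below, M at, H above the midpoint) with standard deviation 0.18·range.
`class_shift = 0` makes the classes statistically exchangeable — the
negative control under which no classifier should beat the majority
baseline; the default 0.25 gives overlapping but learnable classes,
which is the regime a field dataset of this kind plausibly occupies.
Every sample also receives a trap count drawn uniformly from its class's
admissible range (L 0–5, M 6–10, H 11–30; the High upper bound of 30 is a
generator choice, since the labelling rule only requires "more than 10"),
so the two labelling paths agree by construction. The generator emulates
only ranges and counts — not the covariance structure of real fruit
measurements — so passing tests demonstrate algorithmic correctness, not
field-data performance.

**Planted-rule generator.** Draws features uniformly over the schema box,
conditions a chosen fraction of samples to satisfy a known ground-truth
rule (uniform within the rule's intervals) and rejection-samples the rest
off the rule, labels samples by rule membership, then flips each label
independently to a different class with a configurable noise rate. This
gives recovery experiments an exact known answer: at 5% noise the planted
rule itself scores ≈0.95 training accuracy, and the engine's best rule
reaching ≥0.90 across seeded runs is the recovery criterion. The
canonical planted rule used by the tests and the acceptance script is the
single-condition mid-range interval Weight ∈ [3.5, 5.5] → H at 40%
positive fraction.

## Interpretability metrics

Over a Pareto rule set: average rule length (mean antecedent condition
count), maximum rule length, rule coverage (fraction of samples matched
by at least one rule's antecedent — computed over all samples by default,
with a flag restricting to target-class samples, since both readings are
defensible), and feature frequency (per-feature count of rules using it,
ranked descending, ties alphabetical), which doubles as a
feature-importance analysis.

## Problem sizes and numerical notes

* Default engine sizes: population 20, archive 20, 100 generations,
  λ = 0.5, crossover 0.8, mutation 0.1 — the protocol's printed settings.
* The acceptance script runs the full protocol (10 runs × 3 classes ×
  100 generations on the 381-sample synthetic dataset) plus a 10-run
  planted-rule recovery; the long-orbit chaos checks in the test suite
  use 10⁶ iterates × 1000 seeds, vectorized.
* Archive-invariant stress tests use 50 complete runs at 20 generations
  on 114-sample datasets; the invariants asserted (archive bound,
  `F < 1 ⟺ non-dominated`, mutual non-dominance of returned rules) are
  generation-by-generation, so shorter runs lose no coverage.
* All fitness quantities are computed in float64; the brute-force oracle
  comparison is exact for the integer quantities S and R and within
  1e−12 for D and F.
* Degenerate pools: a singleton pool gets density 1/2 (σ treated as 0);
  coincident objective vectors dominate neither each other (dominance is
  strict in at least one component) and receive density 1/2.

## Known limitations

* Synthetic data cannot reproduce the numeric results of the original
  field study; only structural and behavioural properties are testable.
* The truncation operator is O(m³ log m) per over-full selection; fine at
  archive sizes ~10², not tuned for much larger archives.
* Antecedents are conjunctions of closed intervals only — no
  disjunctions, negations, or categorical tests.
* The float tent map's orbit segments are ~50 steps between guard events;
  the Weyl re-seed restores equidistribution but the stream is best
  thought of as piecewise-chaotic rather than a single infinite orbit.
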