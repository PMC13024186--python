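# cherryrules

Chaos-embedded multi-objective evolutionary rule mining for classifying
cherry fruit fly (*Rhagoletis cerasi*) infestation levels from fruit
measurements.

The European cherry fruit fly is a major pest of sweet cherry; its
population level in an orchard — Low, Medium or High, derived from adult
counts in yellow sticky traps (0–5 / 6–10 / >10 flies) — correlates with
the pomological state of the fruit. `cherryrules` learns that link as a
set of human-readable if–then rules over ten numeric fruit traits (color
stage, weight, width, length, stem length, firmness, pit weight, soluble
solids, NaOH maturity index, acidity), giving growers and pest-management
experts a transparent decision aid: which measurable fruit states go with
which infestation risk.

## The method

Each candidate rule is encoded as three vectors in [0, 1]ⁿ (n = 10
features): inclusion scores `a_b` (feature *i* joins the antecedent iff
`a_b[i] > λ`, default λ = 0.5) and lower/upper bound scores `a_l`, `a_u`
decoded affinely onto each feature's measured range. A decoded rule

```
IF  a_l4 ≤ F4 ≤ a_u4  and  a_l8 ≤ F8 ≤ a_u8  THEN  C
```

is scored one-vs-rest against a labeled sample table by its confusion
counts, giving three conflicting objectives, all maximised:

* accuracy  = (TP + TN) / (TP + TN + FP + FN)
* precision = TP / (TP + FP)
* recall    = TP / (TP + FN)

A strength-Pareto evolutionary algorithm (SPEA2) searches the genome
space: strength S(i) = #{j : i ≻ j}, raw fitness R(i) = Σ S(j) over
dominators j ≻ i, density D(i) = 1/(σ_k + 2) from the k-th-nearest
neighbour distance in objective space, fitness F = R + D (minimised;
F < 1 ⟺ non-dominated). An external archive of capacity 20 keeps the
current Pareto front via environmental selection with crowding
truncation; mating is binary tournament on the archive, uniform crossover
at the per-feature triple level (p = 0.8), and chaotic mutation (p = 0.1
per gene) that replaces genes with successive values of a guarded tent
chaotic map, `x ← 2x` (x < ½) else `2(1−x)` — the same stream that seeds
the initial population, giving a well-spread start and non-repeating
variation. The result of a run is the archive's Pareto front: mutually
non-dominated rules trading accuracy against precision against recall,
from which a decision-maker picks (high precision to avoid needless
spraying; high recall to never miss a heavy infestation).

Since the original field data are not distributed, the package includes a
synthetic generator that emulates the study composition (381 samples,
204/101/76 across L/M/H, features in the published ranges) and a
planted-rule generator for ground-truth recovery experiments. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```
$ cherryrules generate --out cherries.csv --seed 1
wrote 381 samples (L=204, M=101, H=76) to cherries.csv

$ cherryrules mine --data cherries.csv --class H --seed 1 --out-dir mined
class H: 20 Pareto rules, best train accuracy 0.854
rule sets and metrics written to mined/
```

`mined/rules_H.txt` then holds the Pareto front for the High class, e.g.

```
IF (15.785 < StemLength < 19.567) and (30.493 < Hardness < 55.657) and
   (5.300 < Core_weight < 9.670) and (0.789 < Acidity < 0.988) THEN H
   [Acc=0.846 Pre=0.625 Rec=0.566]
IF (30.493 < Hardness < 55.657) and (0.631 < Acidity < 1.025) THEN H
   [Acc=0.487 Pre=0.272 Rec=0.943]
```

Read: the first rule is a precise profile of high-infestation fruit
(long stems, firm flesh, heavy pits, low-to-mid acidity) — right on 84.6%
of training samples when used as an H-vs-rest classifier; the second is a
broad screen that catches 94.3% of all H samples at the cost of many
false alarms. Neither dominates the other; that trade-off is the point.
`mined/interpretability.csv` summarises the front structurally — here
average rule length 3.55 conditions, maximum 7, and 93.0% of test samples
covered by at least one rule, with Hardness and Acidity the dominant
features:

```
class,average_rule_length,max_rule_length,rule_coverage,dominant_features
H,3.55,7,0.9298245614035088,"Hardness, Acidity"
```

`cherryrules report --data cherries.csv --runs 10` repeats the protocol
with fresh stratified 70/30 splits per run and writes
min/max/mean/median/std tables of the per-run best accuracy, precision
and recall per class, on both splits. The library API (`evolve`,
`run_experiment`, `generate_dataset`, …) exposes the same functionality
to Python; everything is deterministic given its seeds.

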