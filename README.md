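# splicessl

Ensemble-based semi-supervised learning for highly imbalanced acceptor
splice-site classification.

## The problem

Acceptor splice sites mark the 3' end of introns and carry an `AG` dimer,
but only about 1% of `AG` occurrences in a genome are true acceptor sites —
the rest are decoys. Labeling sites is expensive, so the practical setting
is a *tiny* labeled set (≤1% of the training data), a large unlabeled pool,
and a positive:negative ratio as skewed as 1-to-99. `splicessl` implements
a family of self-training and co-training ensembles designed for exactly
this regime, along with the evaluation protocol to compare them and a
synthetic acceptor-site generator so everything runs without downloads.

## The methods

Each instance is a fixed 141-nt window (the `AG` dimer at 1-based positions
61–62) seen through two static feature views: **view 1**, one categorical
feature per position (141 features × 4 nucleotides), and **view 2**, one
feature per overlapping 3-mer (139 features × 64 categories). The base
learner is categorical Naïve Bayes with Laplace smoothing; its posterior
P(y|x) doubles as prediction confidence.

The supervised baseline **LBE** (Lower Bound Ensemble) trains N models on N
*balanced subsets* — every subset holds all p labeled positives plus p
negatives — and averages their posteriors. Eight semi-supervised variants
wrap a pseudo-labeling loop around it: each iteration draws a subsample U
of the unlabeled pool, refits each subclassifier, lets it pick its most
confident predictions from U, appends those to the training subsets, and
discards the rest of U until the pool is exhausted. The variants differ
along three axes:

|              | shared routing | distributed routing |
|--------------|----------------|---------------------|
| co-training, ±  | CTEO  | CTEOD |
| self-training, ± | STEO | STEOD |
| co-training, + only | CTEP | CTEPD |
| self-training, + only | STEP | STEPD |

"±" variants add 2 positives + 2 negatives per subclassifier per iteration;
"+ only" variants add 2 positives (*dynamic balancing*, counteracting the
skew). *Shared* variants append every subclassifier's picks to every
subset; *distributed* (`*D`) variants give each subset only its own unique
picks, preserving ensemble diversity. Co-training selection admits only
candidates whose two views agree on the label, preferring those one view
labels confidently while the other is unsure (≤ `tau_low`).

Evaluation is stratified 10-fold cross-validation with a ~1% stratified
labeled split inside each training fold, scored by minority-class auPRC
(step-wise average precision — no linear PR interpolation), with two-tailed
paired t-tests of each variant against LBE.

## Worked example

```python
import splicessl as ssl

grid = ssl.run_experiment(
    [5, 10], ["LBE", "CTEPD", "STEPD"],
    sim_config=ssl.SimulationConfig(n_pos=200, signal=0.6),
    k=10, labeled_fraction=0.01, n_subsets=5, seed=7)
print(grid.to_tsv())
```

prints

```
Imbal.Degree	LBE	CTEPD	STEPD
1-to-5	0.236	0.265	0.339*
1-to-10	0.127	0.140	0.167
```

Rows are imbalance degrees (1-to-5 = five decoys per true site), columns
are methods, cells are mean test-fold auPRC over the 10 folds. Both
distributed variants beat the supervised baseline here; the `*` marks a
cell whose paired t-test against LBE rejected at 0.05 in every replicate
dataset (one, in this example). With only ~1% of the data labeled, auPRC is
far below what a fully supervised model would reach — the point is the
*relative* lift the unlabeled pool provides.

The same grid is available from the shell:

```bash
splicessl simulate --n-pos 200 --degree 10 --seed 7 --out data/
splicessl experiment --degrees 5,10 --methods LBE,CTEPD,STEPD --seed 7 --out results/
```

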