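# Methods

## Model and procedure

`splicessl` treats acceptor splice-site prediction as binary classification
of fixed-length DNA windows: positives are true acceptor sites, negatives
are decoy `AG` occurrences. Windows are 141 nt by default with the `AG`
dimer starting at 1-based position 61; both numbers are configuration
parameters (`ViewSpec(window_length, dimer_start)`).

Two static categorical views represent each window: the
nucleotide/position view (L features, 4 categories each) and the
3-mer/position view (L−2 features, 64 categories each, overlapping step-1
trimers). Self-training variants and the supervised baseline use the
concatenated views (280 features at L=141); co-training variants train one
model per view. The views are deterministic projections of the same
instance, so pseudo-labeling operates at instance level — both views of a
subset always contain the same instances.

The base learner is two-class categorical Naïve Bayes. Class priors are
maximum-likelihood frequencies of the training subset (0.5/0.5 on balanced
subsets, by construction); conditionals are Laplace-smoothed with weight
`alpha` over the category set fixed by the ViewSpec, so unseen categories
have positive probability whenever `alpha > 0`. All accumulation is in log
space: 280-feature products underflow double precision in linear space.
Posteriors are normalized with log-sum-exp; the posterior of the predicted
class is the confidence used everywhere.

The supervised **LBE** baseline builds N balanced subsets (all p labeled
positives + p negatives each), fits one combined-view model per subset, and
averages positive-class posteriors over members. The eight semi-supervised
variants run the iterative loop described in the README; per-subset growth
per iteration is 4N / 2N / 4 / 2 for CTEO·STEO / CTEP·STEP / CTEOD·STEOD /
CTEPD·STEPD. After the unlabeled pool is exhausted, all subclassifiers are
refit once on their final subsets, and that ensemble scores the test set.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 1.0 | Laplace smoothing weight; add-one is the standard choice for sparse categorical data and very small labeled sets |
| `tau_low` | 0.7 | the "low confidence" cutoff in the co-training admission rule; when no agreeing candidate passes it, the top-confidence agreeing candidate is taken instead (counted as a fallback) so each iteration makes progress |
| `n_subsets` (N) | imbalance degree of the labeled set | one balanced subset per unit of skew reflects the original class distribution at ensemble level; independently configurable (N=99 means 99 subsets — allowed but costly) |
| `target_iterations` | 50 | subsample size is S = ceil(D_u/target_iterations), so every run makes about 50 passes regardless of pool size |
| `k_per_class` | 2 | pseudo-labels each self-training subclassifier contributes per class per iteration |
| `labeled_fraction` | 0.01 | labeled share of each training fold; floor rounding with a ≥1-positive (and ≥1-negative) guarantee, since the fraction is an upper bound but Naïve Bayes needs both classes |
| `k` (CV folds) | 10 | stratified folds |
| `signal` (s) | 0.6 | generator signal strength, see below |

## Numerical and procedural choices

* **Ranking and ties.** Candidates are ranked by positive-class posterior;
  ties break by stable instance order (lowest index first), making every
  run bit-reproducible. The top-ranked candidates are taken as
  pseudo-positives even when no candidate's argmax class is positive, so
  augmentation rates stay constant; occurrences are visible in the run
  ledger.
* **Pair-committed selection.** In both-classes mode, selections commit as
  whole positive/negative pairs; a final partial subsample can reduce the
  number of pairs but never append an uneven class mix, so balanced subsets
  stay exactly balanced in the `*EO*` variants.
* **Co-training admission.** Only candidates whose two views agree on the
  label are admissible. For each view and requested class the admissible
  candidate maximizing that view's class posterior is selected among those
  the other view rates ≤ `tau_low`; threshold failure falls back to the
  best admissible candidate; an empty agreement set yields a logged
  shortfall and the iteration proceeds. Because of this escape hatch, the
  exact augmentation rate is guaranteed for self-training whenever the
  subsample suffices, and for co-training additionally requires a non-empty
  agreement set (rarely violated in practice; always ledgered).
* **Negative recycling.** Balanced-subset negatives are partitioned without
  replacement while the labeled negative pool lasts, then recycled by fresh
  permutations of the full pool; within-subset duplicates are avoided
  whenever distinct negatives remain.
* **Seeding.** One integer seed fixes a run end to end (subset
  construction, subsampling, selection); LBE and every variant derive the
  subset stream from the same child seed, which is what makes the
  empty-pool degenerate case *bit-exact*: with no unlabeled data the loop
  body never executes, no semi-supervised model is ever trained, and the
  ensemble reduces to LBE.
* **auPRC.** Step-wise average precision, AP = Σ (R_k − R_{k−1})·P_k over
  the stable ranking. Linear interpolation between PR points is invalid
  (precision is not linear in recall) and deliberately not used; sklearn's
  `average_precision_score` agrees on tie-free inputs but groups tied
  scores at one threshold, whereas this implementation resolves ties by
  input order, which keeps results exactly reproducible.
* **Paired t-tests.** Two-tailed, on per-fold auPRC pairs against LBE.
  All-zero differences report (t=0, p=1); zero-variance nonzero differences
  take the overflow-guard path (t=±∞, p=0).
* **Aggregation order.** Mean over folds within a replicate dataset, then
  mean over replicates; significance marks count the replicates in which
  the t-test rejected (`*` all, `†` all but one, `◇` all but two).

## The synthetic generator

Real acceptor datasets are external downloads; the generator emulates the
features the ensembles rely on: fixed geometry (`AG` at a fixed offset in
both classes — negatives are decoys, not random sequence), a positional
signal in positives (pyrimidine-rich C/T tract, probability 0.85 at full
signal, over the 20 positions upstream of the dimer; a mildly G/A-enriched
3-position exon start downstream), uniform background elsewhere, and exact,
nested imbalance series (the degree-10 dataset contains every instance of
the degree-5 dataset). The signal parameter `s` interpolates every
non-dimer position between background (s=0, classes identically
distributed) and the full profile (s=1); the default s=0.6 gives a task
that is learnable but far from saturated at ~1% labeled data.

What the generator does **not** emulate: positional dependence. Its
positions are sampled independently, so the 3-mer view carries no
information beyond the nucleotide view — it only adds smoothing noise at
small sample sizes. Real splice-site data have nucleotide correlations that
make the two views partially complementary, which is the premise of
co-training. Consequently, on synthetic data the distributed self-training
variant with dynamic balancing (STEPD) robustly beats LBE, CTEPD sits near
or slightly above it, and CTEOD — whose selections lean hardest on
cross-view information — tends to sit below it. Passing trend checks here
demonstrate the machinery (rates, routing, diversity preservation, metric,
tests), not organism-level performance; the benchmark margins are computed
and logged, not hard-asserted, because the sign of small margins is
seed-dependent.

## Benchmark problem sizes

The packaged benchmark uses 1,598 positives per replicate (the size of a
well-known *D. melanogaster* acceptor dataset), degree 1-to-10, one
stratified 2/3–1/3 train/test split per seed, 1% labeled (≈10 labeled
positives), N=10 subsets, 5 seeds. The full 13-degree × 9-method grid is
available through `run_experiment` / `splicessl experiment` for users who
want the complete table at their own scale.

## Known limitations

* IUPAC ambiguity codes are rejected rather than mapped to an extra
  category: the Naïve Bayes category sets are fixed at 4/64 and the
  intended inputs never contain them.
* Naïve Bayes is the only base learner; the ensemble framework would admit
  others, but calibrated posteriors are assumed by the selection rules.
* No genome scanning: inputs are pre-extracted fixed-length windows, not
  chromosomes.
* At extreme imbalance with very few labeled positives (1–2), all methods
  hover near prevalence; the protocol guards (≥1 labeled positive, negative
  recycling) keep runs well-defined but cannot make the task learnable.
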