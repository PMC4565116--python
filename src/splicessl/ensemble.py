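"""Balanced-subset ensembles and their semi-supervised variants.

The supervised baseline (LBE, *Lower Bound Ensemble*) trains N Naïve Bayes
models on N balanced subsets of the labeled data — each subset holds every
positive plus an equal number of negatives — and averages their posteriors.

Eight semi-supervised variants wrap an iterative pseudo-labeling loop around
that ensemble.  Each iteration draws a subsample ``U`` of the unlabeled pool
(without replacement; the pool is consumed destructively), refits every
subclassifier on its current subset, lets each subclassifier pick its most
confident predictions from ``U``, appends those pseudo-labeled instances to
the subsets, discards the rest of ``U``, and repeats until the pool is
exhausted.  The variants differ along three axes:

================  ===========================================================
axis              choices
================  ===========================================================
base scheme       co-training (``CT*``: a view1/view2 model pair per subset)
                  vs self-training (``ST*``: one combined-view model)
augmentation      both classes (``*EO*``: 2 positives + 2 negatives per
                  subclassifier) vs dynamic balancing with positives only
                  (``*EP*``: 2 positives)
routing           shared (all selections pooled into ``P`` and appended to
                  every subset) vs distributed (``*D``: each subset keeps
                  only its own selections, preserving ensemble diversity)
================  ===========================================================

Per-subset growth per iteration is therefore 4N (CTEO/STEO), 2N (CTEP/STEP),
4 (CTEOD/STEOD) or 2 (CTEPD/STEPD), where N is the subset count.

Co-training selection admits only candidates on whose label the two views
agree; among those it prefers instances labeled with high confidence by one
view and low confidence (``<= tau_low``) by the other, so that each view
teaches the other what it cannot see for itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .naive_bayes import NBModel, fit_nb
from .sequences import EncodedDataset, NEGATIVE, POSITIVE

SUPERVISED_VARIANTS = ("LBE",)
SSL_VARIANTS = ("CTEO", "STEO", "CTEP", "STEP",
                "CTEOD", "STEOD", "CTEPD", "STEPD")
ALL_VARIANTS = SUPERVISED_VARIANTS + SSL_VARIANTS


@dataclass
class SplitDataset:
    """Labeled instances plus an unlabeled pool, as row indices into ``data``."""

    data: EncodedDataset
    labeled_idx: np.ndarray
    unlabeled_idx: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labeled_idx = np.asarray(self.labeled_idx, dtype=np.intp)
        self.unlabeled_idx = np.asarray(self.unlabeled_idx, dtype=np.intp)
        if np.intersect1d(self.labeled_idx, self.unlabeled_idx).size:
            raise ValueError("labeled and unlabeled index sets overlap")


@dataclass
class VariantConfig:
    """Configuration shared by all ensemble variants."""

    variant: str = "LBE"
    n_subsets: int | None = None      # default: imbalance degree of D_l
    target_iterations: int = 50
    sample_size: int | None = None    # S; default ceil(|D_u| / target_iterations)
    alpha: float = 1.0
    tau_low: float = 0.7
    k_per_class: int = 2              # self-training selections per class
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ALL_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"expected one of {ALL_VARIANTS}")
        if self.n_subsets is not None and self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.target_iterations < 1:
            raise ValueError("target_iterations must be >= 1")
        if not (0 < self.tau_low <= 1):
            raise ValueError("tau_low must be in (0, 1]")

    @property
    def is_co(self) -> bool:
        return self.variant.startswith("CT")

    @property
    def pos_only(self) -> bool:
        return "EP" in self.variant

    @property
    def distributed(self) -> bool:
        return self.variant.endswith("D") and self.variant != "LBE"


@dataclass
class BalancedSubset:
    """One labeled subset feeding one (ST) or two (CT) subclassifiers.

    Starts exactly balanced; pseudo-labeled instances are append-only and
    recorded per iteration in ``growth_log``.
    """

    indices: list[int]
    labels: list[int]
    n_initial: int
    growth_log: list[list[dict]] = field(default_factory=list)

    def append_batch(self, selections: list["Selection"]) -> None:
        for s in selections:
            self.indices.append(s.index)
            self.labels.append(s.label)
        self.growth_log.append([s.as_dict() for s in selections])

    @property
    def class_counts(self) -> tuple[int, int]:
        lab = np.asarray(self.labels)
        return int((lab == POSITIVE).sum()), int((lab == NEGATIVE).sum())


@dataclass(frozen=True)
class Selection:
    """A pseudo-labeled instance with its provenance."""

    index: int
    label: int
    confidence: float
    subset: int
    view: str

    def as_dict(self) -> dict:
        return {"index": int(self.index), "label": int(self.label),
                "confidence": float(self.confidence),
                "subset": int(self.subset), "view": self.view}


@dataclass
class PseudoLabelBatch:
    selections: list[Selection] = field(default_factory=list)
    n_fallback: int = 0
    n_short: int = 0   # selections that could not be made (pool too small)

    def extend(self, other: "PseudoLabelBatch") -> None:
        ids = {s.index for s in self.selections}
        for s in other.selections:
            if s.index in ids:
                raise ValueError(f"duplicate instance {s.index} in batch")
            self.selections.append(s)
        self.n_fallback += other.n_fallback
        self.n_short += other.n_short


class UnlabeledSample:
    """The per-iteration subsample ``U``, consumed by selection."""

    def __init__(self, data: EncodedDataset, indices: Sequence[int], S: int):
        self.data = data
        self.indices = list(int(i) for i in indices)
        self.S = S

    def __len__(self) -> int:
        return len(self.indices)

    def remove(self, idx: int) -> None:
        self.indices.remove(idx)


def imbalance_degree(labels: np.ndarray) -> int:
    """Round(n_negative / n_positive), at least 1."""
    p = int((labels == POSITIVE).sum())
    n = int((labels == NEGATIVE).sum())
    if p == 0 or n == 0:
        raise ValueError("need at least one positive and one negative")
    return max(1, round(n / p))


def make_balanced_subsets(data: EncodedDataset, labeled_idx: Sequence[int],
                          n_subsets: int,
                          rng: np.random.Generator) -> list[BalancedSubset]:
    """Build N balanced subsets: all positives + an equal draw of negatives.

    Negatives are partitioned across subsets without replacement while the
    pool lasts, then recycled by drawing fresh permutations of the full
    negative pool (within-subset duplicates avoided whenever distinct
    negatives remain available).
    """
    labeled_idx = np.asarray(labeled_idx, dtype=np.intp)
    lab = data.labels[labeled_idx]
    pos = labeled_idx[lab == POSITIVE]
    neg = labeled_idx[lab == NEGATIVE]
    p, n = len(pos), len(neg)
    if p == 0 or n == 0:
        raise ValueError("balanced subsets need both classes in D_l")
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")

    queue: list[int] = list(rng.permutation(neg))
    subsets = []
    for _ in range(n_subsets):
        chosen: list[int] = []
        seen: set[int] = set()
        while len(chosen) < p:
            if not queue:
                queue = list(rng.permutation(neg))
            x = int(queue.pop())
            if x in seen and len(seen) < n:
                continue  # distinct negatives still exist; skip the duplicate
            chosen.append(x)
            seen.add(x)
        indices = list(pos) + chosen
        labels = [POSITIVE] * p + [NEGATIVE] * p
        subsets.append(BalancedSubset(indices=[int(i) for i in indices],
                                      labels=labels, n_initial=2 * p))
    return subsets


def draw_unlabeled_sample(pool: list[int], S: int, rng: np.random.Generator,
                          data: EncodedDataset) -> UnlabeledSample:
    """Remove min(S, |pool|) instances uniformly at random from the pool."""
    if S < 1:
        raise ValueError("sample size must be >= 1")
    m = min(S, len(pool))
    if m == 0:
        return UnlabeledSample(data, [], S)
    take = rng.choice(len(pool), size=m, replace=False)
    take_set = set(int(t) for t in take)
    drawn = [pool[t] for t in sorted(take_set)]
    pool[:] = [x for i, x in enumerate(pool) if i not in take_set]
    return UnlabeledSample(data, drawn, S)


def _stable_top(scores: np.ndarray, mask: np.ndarray) -> int | None:
    """Index of the masked maximum; ties broken by lowest index."""
    if not mask.any():
        return None
    masked = np.where(mask, scores, -np.inf)
    return int(np.argmax(masked))


def select_self(model: NBModel, sample: UnlabeledSample, mode: str,
                k_per_class: int = 2, subset: int = 0) -> PseudoLabelBatch:
    """Rank candidates by positive-class posterior; take the extremes.

    Top ``k_per_class`` become pseudo-positives; in ``pos_and_neg`` mode the
    bottom ``k_per_class`` (lowest positive posterior) become
    pseudo-negatives.  Selections are removed from the shared sample so that
    successive callers never pick the same instance.  The top-ranked
    candidates are taken as pseudo-positives even when no candidate's argmax
    class is positive, keeping the augmentation rate constant.

    When the pool is short, ``pos_and_neg`` mode selects whole
    positive/negative pairs only (never an uneven append), so balanced
    subsets stay exactly balanced; the shortfall is logged.
    """
    if mode not in ("pos_and_neg", "pos_only"):
        raise ValueError(f"unknown selection mode {mode!r}")
    batch = PseudoLabelBatch()
    if not sample.indices:
        batch.n_short = k_per_class * (2 if mode == "pos_and_neg" else 1)
        return batch
    idx = np.asarray(sample.indices, dtype=np.intp)
    scores = model.positive_posterior(sample.data.matrix(model.view)[idx])

    order_desc = np.argsort(-scores, kind="stable")
    n_pos = min(k_per_class,
                len(idx) // 2 if mode == "pos_and_neg" else len(idx))
    chosen = [int(order_desc[i]) for i in range(n_pos)]
    for j in chosen:
        batch.selections.append(Selection(int(idx[j]), POSITIVE,
                                          float(scores[j]), subset, model.view))
    batch.n_short += k_per_class - n_pos

    if mode == "pos_and_neg":
        remaining = np.setdiff1d(np.arange(len(idx)), chosen)
        order_asc = remaining[np.argsort(scores[remaining], kind="stable")]
        for j in order_asc[:n_pos]:
            batch.selections.append(Selection(int(idx[j]), NEGATIVE,
                                              float(1.0 - scores[j]),
                                              subset, model.view))
        batch.n_short += k_per_class - n_pos

    for s in batch.selections:
        sample.remove(s.index)
    return batch


def select_co(model_v1: NBModel, model_v2: NBModel, sample: UnlabeledSample,
              mode: str, tau_low: float = 0.7,
              subset: int = 0) -> PseudoLabelBatch:
    """Co-training selection from the two-view agreement set.

    Admissible candidates are those on whose label both views agree.  For
    each view and each requested class, the admissible candidate maximizing
    that view's class posterior is chosen among those the *other* view rates
    with confidence ``<= tau_low`` for that class; when no candidate passes
    the threshold the top-confidence admissible candidate is taken instead
    (counted as a fallback).  Each selection is removed from the sample, so
    one subset contributes 2 positives + 2 negatives (``pos_and_neg``) or
    2 positives (``pos_only``), all unique.
    """
    if mode not in ("pos_and_neg", "pos_only"):
        raise ValueError(f"unknown selection mode {mode!r}")
    batch = PseudoLabelBatch()
    classes = (POSITIVE, NEGATIVE) if mode == "pos_and_neg" else (POSITIVE,)
    n_requested = 2 * len(classes)
    if not sample.indices:
        batch.n_short = n_requested
        return batch

    idx = np.asarray(sample.indices, dtype=np.intp)
    proba = {
        "view1": model_v1.predict_proba(sample.data.view1[idx]),
        "view2": model_v2.predict_proba(sample.data.view2[idx]),
    }
    pred1 = np.argmax(proba["view1"], axis=1)
    pred2 = np.argmax(proba["view2"], axis=1)
    admissible = pred1 == pred2
    alive = np.ones(len(idx), dtype=bool)
    col = {NEGATIVE: 0, POSITIVE: 1}

    def pick(view: str, other: str, cls: int) -> tuple[int | None, bool]:
        score = proba[view][:, col[cls]]
        other_conf = proba[other][:, col[cls]]
        j = _stable_top(score, admissible & alive & (other_conf <= tau_low))
        if j is not None:
            return j, False
        return _stable_top(score, admissible & alive), True

    for view, other in (("view1", "view2"), ("view2", "view1")):
        picks: list[tuple[int, int, bool]] = []   # (candidate, class, fallback)
        for cls in classes:
            j, fb = pick(view, other, cls)
            if j is None:
                # commit whole per-view batches only (pairs in pos_and_neg
                # mode) so balanced subsets stay balanced
                for jj, _, _ in picks:
                    alive[jj] = True
                picks = []
                break
            picks.append((j, cls, fb))
            alive[j] = False
        if not picks:
            batch.n_short += len(classes)
            continue
        for j, cls, fb in picks:
            batch.selections.append(
                Selection(int(idx[j]), cls,
                          float(proba[view][j, col[cls]]), subset, view))
            batch.n_fallback += int(fb)

    for s in batch.selections:
        sample.remove(s.index)
    return batch


@dataclass
class EnsembleModel:
    """A trained ensemble: N subsets, each backing one or two NB models."""

    variant: str
    n_subsets: int
    models: list          # NBModel (ST/LBE) or (NBModel, NBModel) pairs (CT)
    subsets: list[BalancedSubset]
    config: VariantConfig
    ledger: list[dict] = field(default_factory=list)
    stats: dict = field(default_factory=dict)

    def flat_models(self) -> list[NBModel]:
        out: list[NBModel] = []
        for m in self.models:
            out.extend(m if isinstance(m, tuple) else (m,))
        return out

    def predict(self, data: EncodedDataset,
                idx: np.ndarray | None = None) -> np.ndarray:
        return predict_ensemble(self, data, idx)

    def manifest(self) -> dict:
        return {
            "variant": self.variant,
            "n_subsets": self.n_subsets,
            "config": {k: v for k, v in vars(self.config).items()},
            "iterations": self.ledger,
            "final_subset_sizes": [len(s.indices) for s in self.subsets],
            "stats": self.stats,
        }


def predict_ensemble(model: EnsembleModel, data: EncodedDataset,
                     idx: np.ndarray | None = None) -> np.ndarray:
    """Positive-class score = mean positive posterior over all constituent models."""
    flat = model.flat_models()
    scores = np.zeros(len(data) if idx is None else len(idx))
    for nb in flat:
        X = data.matrix(nb.view)
        if idx is not None:
            X = X[np.asarray(idx, dtype=np.intp)]
        scores += nb.positive_posterior(X)
    return scores / len(flat)


def _rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """(subset rng, loop rng) — LBE and the SSL variants share the first."""
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def _fit_subset_models(data: EncodedDataset, subsets: list[BalancedSubset],
                       is_co: bool, alpha: float) -> list:
    models = []
    for sub in subsets:
        idx = np.asarray(sub.indices, dtype=np.intp)
        lab = np.asarray(sub.labels)
        if is_co:
            models.append((fit_nb(data, "view1", alpha, idx, lab),
                           fit_nb(data, "view2", alpha, idx, lab)))
        else:
            models.append(fit_nb(data, "combined", alpha, idx, lab))
    return models


def train_lbe(data: EncodedDataset, labeled_idx: Sequence[int],
              n_subsets: int | None = None, seed: int = 0,
              alpha: float = 1.0) -> EnsembleModel:
    """Supervised Lower Bound Ensemble: no unlabeled data touched."""
    labeled_idx = np.asarray(labeled_idx, dtype=np.intp)
    if n_subsets is None:
        n_subsets = imbalance_degree(data.labels[labeled_idx])
    subset_rng, _ = _rngs(seed)
    subsets = make_balanced_subsets(data, labeled_idx, n_subsets, subset_rng)
    config = VariantConfig(variant="LBE", n_subsets=n_subsets,
                           alpha=alpha, seed=seed)
    models = _fit_subset_models(data, subsets, is_co=False, alpha=alpha)
    return EnsembleModel("LBE", n_subsets, models, subsets, config)


def run_variant(split: SplitDataset, config: VariantConfig) -> EnsembleModel:
    """Run one ensemble variant to completion and return the trained ensemble.

    Semi-supervised variants iterate until the unlabeled pool is exhausted;
    LBE skips the loop.  Fixing ``config.seed`` fixes the entire run.
    """
    data = split.data
    labeled_idx = split.labeled_idx
    n = config.n_subsets
    if n is None:
        n = imbalance_degree(data.labels[labeled_idx])

    if config.variant == "LBE":
        return train_lbe(data, labeled_idx, n, config.seed, config.alpha)

    if len(split.unlabeled_idx) == 0:
        # Degenerate: the loop body never executes, so no semi-supervised
        # model is ever trained; the ensemble reduces to the supervised LBE
        # on the same seed (bit-exact, combined-view models).
        model = train_lbe(data, labeled_idx, n, config.seed, config.alpha)
        model.variant = config.variant
        model.config = config
        return model

    subset_rng, loop_rng = _rngs(config.seed)
    subsets = make_balanced_subsets(data, labeled_idx, n, subset_rng)

    pool: list[int] = [int(i) for i in split.unlabeled_idx]
    n_initial = len(pool)
    S = config.sample_size
    if S is None:
        S = max(1, math.ceil(n_initial / config.target_iterations))

    mode = "pos_only" if config.pos_only else "pos_and_neg"
    ledger: list[dict] = []
    n_selected_total = 0
    n_discarded_total = 0

    sample = draw_unlabeled_sample(pool, S, loop_rng, data)
    iteration = 0
    while len(sample) > 0:
        iteration += 1
        entry = {"iteration": iteration, "U": len(sample),
                 "selections_per_subset": [], "fallbacks": 0, "short": 0}
        shared = PseudoLabelBatch()
        per_subset_batches: list[PseudoLabelBatch] = []
        for i in range(n):
            models_i = _fit_subset_models(data, [subsets[i]], config.is_co,
                                          config.alpha)[0]
            if config.is_co:
                batch = select_co(models_i[0], models_i[1], sample, mode,
                                  config.tau_low, subset=i)
            else:
                batch = select_self(models_i, sample, mode,
                                    config.k_per_class, subset=i)
            entry["fallbacks"] += batch.n_fallback
            entry["short"] += batch.n_short
            if config.distributed:
                subsets[i].append_batch(batch.selections)
                per_subset_batches.append(batch)
                entry["selections_per_subset"].append(len(batch.selections))
            else:
                shared.extend(batch)

        if not config.distributed:
            for sub in subsets:
                sub.append_batch(shared.selections)
            entry["selections_per_subset"] = [len(shared.selections)] * n
            n_selected_total += len(shared.selections)
        else:
            n_selected_total += sum(len(b.selections)
                                    for b in per_subset_batches)

        n_discarded_total += len(sample)  # rest of U is discarded
        ledger.append(entry)
        sample = draw_unlabeled_sample(pool, S, loop_rng, data)

    assert n_selected_total + n_discarded_total + len(pool) == n_initial

    models = _fit_subset_models(data, subsets, config.is_co, config.alpha)
    model = EnsembleModel(config.variant, n, models, subsets, config, ledger)
    model.stats = {
        "sample_size": S, "n_unlabeled": n_initial,
        "n_selected": n_selected_total, "n_discarded": n_discarded_total,
    }
    return model
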