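"""Experimental protocol: stratified CV with a tiny labeled split,
minority-class auPRC, paired t-tests, and the results grid.

The headline metric is the area under the precision-recall curve for the
positive (minority) class, computed as step-wise average precision

    AP = sum_k (R_k - R_{k-1}) * P_k

over the ranking by score, descending, with ties broken by instance index
(stable).  Linear interpolation between PR points is deliberately avoided —
precision does not interpolate linearly in recall.

Each experiment cell is: build the dataset at one imbalance degree, run
stratified k-fold CV (default 10), inside each training fold label a
stratified subset of at most ``labeled_fraction`` (default 1%) of the
instances and mask the rest as the unlabeled pool, train the variant, score
the held-out fold, and average the per-fold auPRC.  Semi-supervised cells
carry a two-tailed paired t-test against the supervised LBE baseline on the
per-fold values; with replicate datasets, significance marks count in how
many replicates the test rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from . import simulate
from .ensemble import (ALL_VARIANTS, EnsembleModel, SplitDataset,
                       VariantConfig, run_variant)
from .sequences import EncodedDataset, NEGATIVE, POSITIVE, encode_dataset


@dataclass
class PRResult:
    """A precision-recall curve and its step-wise area."""

    recall: np.ndarray
    precision: np.ndarray
    auprc: float


def auprc(scores, labels) -> PRResult:
    """Step-wise average precision of the positive class.

    Ranks by score descending with stable ties by index, then accumulates
    precision at every positive hit.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int((labels == POSITIVE).sum())
    n_neg = int((labels == NEGATIVE).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auPRC needs at least one instance of each class")

    order = np.argsort(-scores, kind="stable")
    hits = (labels[order] == POSITIVE).astype(float)
    tp = np.cumsum(hits)
    ranks = np.arange(1, len(scores) + 1)
    precision = tp / ranks
    recall = tp / n_pos
    ap = float((precision * hits).sum() / n_pos)
    return PRResult(recall=recall, precision=precision, auprc=ap)


def paired_ttest_twotailed(a, b) -> tuple[float, float]:
    """Two-tailed paired t-test on per-fold metric pairs.

    Returns (t, p).  All-zero differences are a degenerate input (reported
    as t=0, p=1, i.e. not significant); zero-variance nonzero differences
    yield an infinite t and p=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length samples with >= 2 pairs")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.ptp(d) == 0:  # identical nonzero differences: sd = 0
        return float(np.sign(d[0]) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class CVPlan:
    """Stratified k-fold plan with a tiny labeled split inside each fold."""

    k: int
    labeled_fraction: float
    seed: int
    folds: list[dict] = field(default_factory=list)
    # each fold: {"test": idx, "labeled": idx, "unlabeled": idx}


def make_cv_plan(labels, k: int = 10, labeled_fraction: float = 0.01,
                 seed: int = 0) -> CVPlan:
    """Stratified k-fold CV; within each training set, label a stratified
    subset of ``floor(fraction * |train|)`` instances (at least one positive)
    and pool the remainder as unlabeled."""
    labels = np.asarray(labels)
    for cls in (POSITIVE, NEGATIVE):
        if (labels == cls).sum() < k:
            raise ValueError(
                f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    plan = CVPlan(k=k, labeled_fraction=labeled_fraction, seed=seed)
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        pos = train_idx[labels[train_idx] == POSITIVE]
        neg = train_idx[labels[train_idx] == NEGATIVE]
        n_lab = int(np.floor(labeled_fraction * len(train_idx)))
        n_pos_lab = max(1, int(np.floor(n_lab * len(pos) / len(train_idx))))
        n_neg_lab = max(1, n_lab - n_pos_lab)
        lab = np.concatenate([rng.choice(pos, size=n_pos_lab, replace=False),
                              rng.choice(neg, size=n_neg_lab, replace=False)])
        unlab = np.setdiff1d(train_idx, lab)
        plan.folds.append({"test": np.sort(test_idx), "labeled": np.sort(lab),
                           "unlabeled": unlab})
    return plan


@dataclass
class ResultsGrid:
    """Mean auPRC per (imbalance degree, method) with significance marks."""

    degrees: list[int]
    methods: list[str]
    values: pd.DataFrame               # degree rows x method columns
    marks: pd.DataFrame                # significant-replicate counts
    n_replicates: int
    fold_values: dict = field(default_factory=dict)
    # (degree, method) -> list over replicates of per-fold auPRC lists
    manifest: dict = field(default_factory=dict)

    def mark_char(self, count: int) -> str:
        """Legend: * all replicates significant, † all but one, ◇ all but
        two (generalizing the organism-count marks to r replicates)."""
        if self.n_replicates < 3:
            return "*" if count == self.n_replicates and count > 0 else ""
        if count == self.n_replicates:
            return "*"
        if count == self.n_replicates - 1:
            return "†"
        if count == self.n_replicates - 2 and count > 0:
            return "◇"
        return ""

    def to_tsv(self, path=None) -> str:
        lines = ["\t".join(["Imbal.Degree"] + self.methods)]
        for d in self.degrees:
            cells = [f"1-to-{d}"]
            for m in self.methods:
                v = self.values.loc[d, m]
                suffix = ""
                if m != "LBE":
                    suffix = self.mark_char(int(self.marks.loc[d, m]))
                cells.append(f"{v:.3f}{suffix}")
            lines.append("\t".join(cells))
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_variant_on_fold(data: EncodedDataset, fold: dict,
                             variant: str, seed: int,
                             **config_kw) -> tuple[float, EnsembleModel]:
    """Train one variant on one fold's split and return test-fold auPRC."""
    split = SplitDataset(data, fold["labeled"], fold["unlabeled"])
    config = VariantConfig(variant=variant, seed=seed, **config_kw)
    model = run_variant(split, config)
    scores = model.predict(data, fold["test"])
    res = auprc(scores, data.labels[fold["test"]])
    return res.auprc, model


def run_experiment(degrees: list[int], methods: list[str] | None = None,
                   *, sim_config: simulate.SimulationConfig | None = None,
                   records_by_degree: dict[int, list] | None = None,
                   k: int = 10, labeled_fraction: float = 0.01,
                   n_replicates: int = 1, n_subsets: int | None = None,
                   alpha: float = 1.0, tau_low: float = 0.7,
                   target_iterations: int = 50, seed: int = 0,
                   significance: float = 0.05) -> ResultsGrid:
    """Run the full (degree x method) grid and aggregate the results table.

    Data come either from ``records_by_degree`` (e.g. loaded FASTA windows)
    or from the synthetic generator seeded per replicate; negatives are
    nested across degrees within each replicate.  Cell value = mean auPRC
    over folds, then over replicates; marks = number of replicates in which
    the two-tailed paired t-test vs LBE rejected at ``significance``.
    """
    if methods is None:
        methods = list(ALL_VARIANTS)
    unknown = set(methods) - set(ALL_VARIANTS)
    if unknown:
        raise ValueError(f"unknown variant(s): {sorted(unknown)}")
    methods = list(methods)
    if "LBE" not in methods:
        methods = ["LBE"] + methods
    degrees = sorted(set(int(d) for d in degrees))

    root = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 root.spawn(n_replicates)]

    fold_values: dict = {}
    manifest = {"seed": seed, "replicate_seeds": rep_seeds, "k": k,
                "labeled_fraction": labeled_fraction, "degrees": degrees,
                "methods": methods, "cells": {}}

    for rep, rep_seed in enumerate(rep_seeds):
        if records_by_degree is None:
            cfg = sim_config or simulate.SimulationConfig()
            base_cfg = simulate.SimulationConfig(
                n_pos=cfg.n_pos, degree=max(degrees),
                window_length=cfg.window_length, dimer_start=cfg.dimer_start,
                signal=cfg.signal, background=cfg.background, seed=rep_seed)
            base = simulate.simulate_records(base_cfg)
            datasets = simulate.nest_imbalance_series(base, degrees,
                                                      seed=rep_seed)
        else:
            datasets = records_by_degree
        for d in degrees:
            data = encode_dataset(datasets[d])
            plan = make_cv_plan(data.labels, k=k,
                                labeled_fraction=labeled_fraction,
                                seed=rep_seed)
            for fold_no, fold in enumerate(plan.folds):
                fold_seed = int(np.random.SeedSequence(
                    [rep_seed, d, fold_no]).generate_state(1)[0] % (2**31))
                for m in methods:
                    try:
                        value, _ = evaluate_variant_on_fold(
                            data, fold, m, fold_seed, n_subsets=n_subsets,
                            alpha=alpha, tau_low=tau_low,
                            target_iterations=target_iterations)
                    except Exception as exc:
                        raise RuntimeError(
                            f"experiment failed at degree=1-to-{d}, "
                            f"variant={m}, fold={fold_no}") from exc
                    fold_values.setdefault((d, m), [[] for _ in
                                                    range(n_replicates)])
                    fold_values[(d, m)][rep].append(value)

    values = pd.DataFrame(index=degrees, columns=methods, dtype=float)
    marks = pd.DataFrame(0, index=degrees, columns=methods, dtype=int)
    for d in degrees:
        for m in methods:
            per_rep = fold_values[(d, m)]
            values.loc[d, m] = float(np.mean([np.mean(v) for v in per_rep]))
            if m != "LBE":
                n_sig = 0
                for rep in range(n_replicates):
                    t, p = paired_ttest_twotailed(per_rep[rep],
                                                  fold_values[(d, "LBE")][rep])
                    if p < significance:
                        n_sig += 1
                marks.loc[d, m] = n_sig
            manifest["cells"][f"1-to-{d}/{m}"] = {
                "per_replicate_fold_auprc": per_rep}

    return ResultsGrid(degrees=degrees, methods=methods, values=values,
                       marks=marks, n_replicates=n_replicates,
                       fold_values=fold_values, manifest=manifest)


def single_split_benchmark(variants, *, n_pos=1598, degree=10, signal=0.6,
                           n_subsets=10, labeled_fraction=0.01,
                           test_fraction=1 / 3, n_seeds=5,
                           seed=0) -> dict[str, list[float]]:
    """Per-seed test-set auPRC of each variant under one stratified
    train/test split per seed.

    A lighter protocol than full k-fold CV for trend checks: each seed draws
    a fresh synthetic dataset, one stratified split, a ~1% stratified
    labeled subset inside the training part (the rest is the unlabeled
    pool), then trains every requested variant on the identical split.
    """
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(seed).spawn(n_seeds)]
    out: dict[str, list[float]] = {v: [] for v in variants}
    for s in seeds:
        recs = simulate.simulate_records(simulate.SimulationConfig(
            n_pos=n_pos, degree=degree, signal=signal, seed=s))
        data = encode_dataset(recs)
        sss = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                     random_state=s % (2**31))
        (train, test), = sss.split(np.zeros(len(data)), data.labels)
        rng = np.random.default_rng(s)
        pos = train[data.labels[train] == POSITIVE]
        neg = train[data.labels[train] == NEGATIVE]
        n_lab = int(np.floor(labeled_fraction * len(train)))
        n_pos_lab = max(1, int(np.floor(n_lab * len(pos) / len(train))))
        lab = np.concatenate([
            rng.choice(pos, size=n_pos_lab, replace=False),
            rng.choice(neg, size=max(1, n_lab - n_pos_lab), replace=False)])
        split = SplitDataset(data, lab, np.setdiff1d(train, lab))
        for v in variants:
            model = run_variant(split, VariantConfig(
                variant=v, n_subsets=n_subsets, seed=s))
            out[v].append(auprc(model.predict(data, test),
                                data.labels[test]).auprc)
    return out
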