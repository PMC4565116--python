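"""Categorical Naïve Bayes over fixed per-feature category sets.

The base learner for every ensemble variant.  Class priors are maximum-
likelihood frequencies of the training subset (0.5/0.5 on balanced subsets);
per-feature conditionals are Laplace-smoothed category frequencies with
weight ``alpha`` over the category set fixed by the :class:`~splicessl.sequences.ViewSpec`
(4 categories for view1 features, 64 for view2).  All probability
accumulation is in log space: the combined view has 280 features and the
joint product underflows in linear space.

Posteriors double as prediction confidence: the confidence of a predicted
label is that label's posterior probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .sequences import EncodedDataset, NEGATIVE, POSITIVE

_FORMAT_VERSION = 1


class FittingError(ValueError):
    pass


@dataclass
class NBModel:
    """A fitted two-class categorical Naïve Bayes model.

    ``log_cond`` has shape (2, F, K_max); entry [c, f, k] is
    log P(category k | class c) for feature f, and categories beyond a
    feature's set size are -inf (never indexed for valid instances).
    Class axis order is (negative, positive).
    """

    view: str
    alpha: float
    n_categories: np.ndarray          # (F,) per-feature category-set sizes
    log_prior: np.ndarray             # (2,) for classes (neg, pos)
    log_cond: np.ndarray              # (2, F, K_max)

    @property
    def n_features(self) -> int:
        return len(self.n_categories)

    # -- estimation ------------------------------------------------------

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, *, view: str,
            n_categories: np.ndarray, alpha: float = 1.0) -> "NBModel":
        """Fit from an (n, F) integer category matrix and 0/1 labels."""
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != len(n_categories):
            raise FittingError(
                f"X has {X.shape[1] if X.ndim == 2 else '?'} features, "
                f"expected {len(n_categories)}")
        if alpha < 0:
            raise FittingError("alpha must be >= 0")
        counts = np.array([(y == NEGATIVE).sum(), (y == POSITIVE).sum()])
        if (counts == 0).any():
            missing = "negative" if counts[0] == 0 else "positive"
            raise FittingError(f"class {missing!r} absent from training input")
        log_prior = np.log(counts / counts.sum())

        F = len(n_categories)
        k_max = int(n_categories.max())
        offsets = np.arange(F, dtype=np.int64) * k_max
        log_cond = np.full((2, F, k_max), -np.inf)
        for c, cls_label in enumerate((NEGATIVE, POSITIVE)):
            Xc = X[y == cls_label]
            flat = (Xc.astype(np.int64) + offsets).ravel()
            cat_counts = np.bincount(flat, minlength=F * k_max).reshape(F, k_max)
            denom = len(Xc) + alpha * n_categories.astype(float)
            with np.errstate(divide="ignore"):
                tab = np.log((cat_counts + alpha) / denom[:, None])
            # mask categories outside each feature's fixed set
            valid = np.arange(k_max)[None, :] < n_categories[:, None]
            log_cond[c] = np.where(valid, tab, -np.inf)
        return cls(view=view, alpha=float(alpha),
                   n_categories=np.asarray(n_categories, dtype=np.int64),
                   log_prior=log_prior, log_cond=log_cond)

    # -- prediction ------------------------------------------------------

    def joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) array of log prior + sum of per-feature log conditionals."""
        X = np.atleast_2d(np.asarray(X))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"instance has {X.shape[1]} features, model expects "
                f"{self.n_features}")
        if (X < 0).any() or (X >= self.n_categories[None, :]).any():
            raise ValueError("category code outside the model's fixed set")
        f_idx = np.arange(self.n_features)
        jll = np.empty((len(X), 2))
        for c in range(2):
            per_feat = self.log_cond[c][f_idx[None, :], X]
            if self.alpha == 0 and np.isneginf(per_feat).any():
                raise ValueError(
                    "category unseen at fit time with alpha=0; "
                    "posterior undefined")
            jll[:, c] = per_feat.sum(axis=1)
        return jll + self.log_prior[None, :]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) posteriors P(neg|x), P(pos|x), each row summing to 1."""
        jll = self.joint_log_likelihood(X)
        return np.exp(jll - logsumexp(jll, axis=1, keepdims=True))

    def posterior(self, x: np.ndarray) -> tuple[float, float]:
        """(P(pos|x), P(neg|x)) for a single instance."""
        p = self.predict_proba(np.atleast_2d(x))[0]
        return float(p[1]), float(p[0])

    def positive_posterior(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        prior = np.exp(self.log_prior)
        cond = np.exp(self.log_cond)
        return json.dumps({
            "format_version": _FORMAT_VERSION,
            "view": self.view,
            "alpha": self.alpha,
            "n_categories": self.n_categories.tolist(),
            "class_prior": {"negative": prior[0], "positive": prior[1]},
            "conditionals": [
                {"negative": cond[0, f, :self.n_categories[f]].tolist(),
                 "positive": cond[1, f, :self.n_categories[f]].tolist()}
                for f in range(self.n_features)
            ],
        })

    @classmethod
    def from_json(cls, doc: str) -> "NBModel":
        d = json.loads(doc)
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format {d.get('format_version')!r}")
        n_categories = np.asarray(d["n_categories"], dtype=np.int64)
        k_max = int(n_categories.max())
        log_cond = np.full((2, len(n_categories), k_max), -np.inf)
        with np.errstate(divide="ignore"):
            for f, tab in enumerate(d["conditionals"]):
                log_cond[0, f, :n_categories[f]] = np.log(tab["negative"])
                log_cond[1, f, :n_categories[f]] = np.log(tab["positive"])
            log_prior = np.log([d["class_prior"]["negative"],
                                d["class_prior"]["positive"]])
        return cls(view=d["view"], alpha=float(d["alpha"]),
                   n_categories=n_categories, log_prior=log_prior,
                   log_cond=log_cond)


def fit_nb(data: EncodedDataset, view: str, alpha: float = 1.0,
           idx: np.ndarray | None = None,
           labels: np.ndarray | None = None) -> NBModel:
    """Fit an :class:`NBModel` on (a subset of) an encoded dataset.

    ``idx`` selects rows; ``labels`` overrides the dataset's labels for those
    rows (used by the ensembles, whose subsets carry pseudo-labels).
    """
    X = data.matrix(view)
    y = data.labels if labels is None else np.asarray(labels)
    if idx is not None:
        X = X[np.asarray(idx, dtype=np.intp)]
        if labels is None:
            y = y[np.asarray(idx, dtype=np.intp)]
    return NBModel.fit(X, y, view=view,
                       n_categories=data.spec.n_categories(view), alpha=alpha)
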