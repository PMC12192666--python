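"""Uncertainty-driven sample selection around a probabilistic classifier.

Each round: train on the labeled set, score the unlabeled pool, select the
k most uncertain samples (binary predictive entropy by default), reveal
their labels, repeat.  The loop is model-agnostic: any factory returning an
object with ``fit(X, y)`` and ``predict_proba(X)`` (sklearn-style) or a
(fit, predict) pair for the sequence model works.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ALConfig", "uncertainty", "select_batch", "al_loop"]


@dataclass(frozen=True)
class ALConfig:
    initial_labeled: int = 100
    batch_per_round: int = 100
    rounds: int = 5
    measure: str = "entropy"   # or "margin" (|p - 0.5|, negated)
    seed: int = 0

    def __post_init__(self):
        if self.initial_labeled < 1 or self.batch_per_round < 1:
            raise ValueError("sizes must be positive")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.measure not in ("entropy", "margin"):
            raise ValueError("measure must be 'entropy' or 'margin'")


def uncertainty(p, measure: str = "entropy") -> np.ndarray:
    """Uncertainty of predicted probabilities.

    ``entropy``: binary entropy -p ln p - (1-p) ln(1-p), maximal log 2 at
    p = 0.5 and 0 at p in {0, 1}.  ``margin``: -|p - 0.5| (same ordering).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if measure == "margin":
        return -np.abs(p - 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(p * np.log(p) + (1 - p) * np.log(1 - p))
    return np.where((p <= 0) | (p >= 1), 0.0, h)


def select_batch(pool_probs, k: int, measure: str = "entropy") -> np.ndarray:
    """Indices of the k most uncertain pool samples.

    Deterministic: ties break by ascending index (stable sort on
    descending uncertainty).
    """
    pool_probs = np.asarray(pool_probs, dtype=float)
    if pool_probs.size == 0:
        raise ValueError("empty pool")
    if k > pool_probs.size:
        raise ValueError("k exceeds pool size")
    scores = uncertainty(pool_probs, measure)
    return np.argsort(-scores, kind="stable")[:k]


def al_loop(X_lab, y_lab, X_pool, y_pool_hidden, X_val, y_val,
            model_factory, config: ALConfig = ALConfig(),
            metric=None, random_selection: bool = False):
    """Active-learning loop; returns the learning curve as a list of dicts.

    Starts from the given labeled seed set; per round trains a fresh model
    (retraining from scratch avoids warm-start confounds), scores the pool,
    selects ``batch_per_round`` samples (entropy-based, or uniformly at
    random when ``random_selection``), reveals their hidden labels and
    continues.  Curve rows: round, labels_used, auroc on the validation
    split.
    """
    from .evaluation import metrics as _metrics

    if config.rounds * config.batch_per_round > len(y_pool_hidden):
        raise ValueError("label budget exceeds pool size")
    metric = metric or (lambda s, y: _metrics(s, y).auroc)
    rng = np.random.default_rng(config.seed)

    X_lab = np.asarray(X_lab, dtype=float).copy()
    y_lab = np.asarray(y_lab).copy()
    X_pool = np.asarray(X_pool, dtype=float).copy()
    y_pool = np.asarray(y_pool_hidden).copy()

    def fit_and_eval():
        model = model_factory()
        model.fit(X_lab, y_lab)
        proba = model.predict_proba(X_val)
        scores = proba[:, 1] if proba.ndim == 2 else proba
        return model, metric(scores, y_val)

    model, score = fit_and_eval()
    curve = [dict(round=0, labels_used=len(y_lab), auroc=float(score))]
    for r in range(1, config.rounds + 1):
        proba = model.predict_proba(X_pool)
        pool_p = proba[:, 1] if proba.ndim == 2 else proba
        if random_selection:
            idx = rng.choice(len(pool_p), size=config.batch_per_round,
                             replace=False)
        else:
            idx = select_batch(pool_p, config.batch_per_round, config.measure)
        X_lab = np.vstack([X_lab, X_pool[idx]])
        y_lab = np.concatenate([y_lab, y_pool[idx]])
        keep = np.setdiff1d(np.arange(len(pool_p)), idx)
        X_pool, y_pool = X_pool[keep], y_pool[keep]
        model, score = fit_and_eval()
        curve.append(dict(round=r, labels_used=len(y_lab), auroc=float(score)))
    return curve
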