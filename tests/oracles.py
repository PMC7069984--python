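"""Independent brute-force oracles used to check the fast implementations."""

from __future__ import annotations

import itertools

import numpy as np


def pairwise_auc(y, scores) -> float:
    """AUC as explicit pairwise concordance over positive-negative pairs,
    ties counted one half."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_permutation_loss(model_scores_fn, X, column, loss_fn):
    """Average loss over ALL permutations of one column (n! enumeration).

    ``model_scores_fn`` maps a feature matrix to scores; ``loss_fn`` maps
    scores to a loss.  Returns (mean loss, per-permutation losses).
    """
    n = len(X)
    values = X[column].to_numpy().copy()
    losses = []
    work = X.copy()
    for perm in itertools.permutations(range(n)):
        work[column] = values[list(perm)]
        losses.append(loss_fn(model_scores_fn(work)))
    losses = np.asarray(losses)
    return float(losses.mean()), losses


def row_sum(items) -> np.ndarray:
    """Per-row item sum via an explicit Python loop."""
    items = np.asarray(items, dtype=float)
    return np.array([sum(row) for row in items])
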