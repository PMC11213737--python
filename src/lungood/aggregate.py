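"""Patient-level score aggregation, AUC evaluation, and strategy selection.

A subject's score S(X) is a symmetric statistic of its patch anomaly
scores. The candidate strategies are mean, max, top-k mean and upper
percentiles; the one used for testing is chosen by the highest mean
validation AUC over repeated runs, ties broken by lower AUC spread and
then by candidate order.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .types import PatientScore

__all__ = [
    "DEFAULT_STRATEGIES",
    "aggregate",
    "auc",
    "select_aggregation",
]

#: candidate aggregation strategies compared on the validation set
DEFAULT_STRATEGIES = ("mean", "max", "topk_mean(5)", "topk_mean(10)",
                      "percentile(90)", "percentile(95)")


def _parse(strategy: str) -> tuple[str, float | None]:
    if "(" in strategy:
        name, arg = strategy.rstrip(")").split("(")
        return name, float(arg)
    return strategy, None


def aggregate(patch_scores, strategy: str = "mean",
              subject_id: str = "") -> PatientScore:
    """Aggregate patch scores into S(X).

    Strategies: ``mean``; ``max``; ``topk_mean(k)`` — mean of the k largest
    scores (k clipped to the list length); ``percentile(q)`` — linearly
    interpolated q-th percentile.
    """
    scores = np.asarray(list(patch_scores), dtype=np.float64)
    if scores.size == 0:
        raise ValueError("cannot aggregate an empty score list")
    name, arg = _parse(strategy)
    if name == "mean":
        S = scores.mean()
    elif name == "max":
        S = scores.max()
    elif name == "topk_mean":
        k = min(int(arg), scores.size)
        S = np.sort(scores)[-k:].mean()
    elif name == "percentile":
        S = np.percentile(scores, arg)  # linear interpolation
    else:
        raise ValueError(f"unknown aggregation strategy {strategy!r}")
    return PatientScore(subject_id=subject_id, S=float(S), strategy=strategy,
                        patch_scores=scores.tolist())


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(S_diseased > S_control) + 1/2 P(tie).

    ``labels`` are binary with 1 (or "diseased") the positive class.
    Computed from the rank-sum, which implements the half-tie convention.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray([
        1 if lab in (1, True, "diseased") else 0 for lab in labels
    ])
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks: ties count half
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def select_aggregation(candidate_strategies, run_val_aucs: dict[str, list[float]]
                       ) -> str:
    """Pick the strategy with the highest mean validation AUC across runs.

    ``run_val_aucs`` maps strategy -> per-run validation AUCs. Ties go to
    the lower AUC standard deviation, then to candidate order.
    """
    candidates = list(candidate_strategies)
    if not candidates:
        raise ValueError("no candidate strategies given")
    best = None
    best_key = None
    for rank, strat in enumerate(candidates):
        runs = np.asarray(run_val_aucs[strat], dtype=np.float64)
        # round so float summation noise cannot defeat the tie-break order
        key = (-round(runs.mean(), 12), round(runs.std(), 12), rank)
        if best_key is None or key < best_key:
            best, best_key = strat, key
    return best
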