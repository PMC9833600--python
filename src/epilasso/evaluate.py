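"""Effect-recovery evaluation: ranked predictions, pooled ROC, AUROC.

Recovery is judged purely on which effects are identified, not on how well
their strengths are estimated: every candidate id up to the evaluated depth
gets a strength |predicted beta| (zero when unselected) and a truth label,
predictions are pooled over replicates, and candidates are ranked by
strength.  The large mass of zero-strength candidates forms one tied block
at the end of the ranking, so the AUROC (trapezoidal, tie-sharing -
equivalently the Mann-Whitney statistic) correctly charges unrecovered
true effects as misses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .sparse import InteractionId


def candidate_universe(p: int, depth: int) -> Iterator[InteractionId]:
    """All interaction ids up to ``depth`` over ``p`` features, sorted order."""
    for order in range(1, depth + 1):
        yield from itertools.combinations(range(p), order)


@dataclass
class RankedPredictions:
    """Per-candidate strengths and truth labels, poolable over replicates."""

    ids: List[InteractionId] = field(default_factory=list)
    strength: np.ndarray = field(default_factory=lambda: np.empty(0))
    is_true: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def extend(self, other: "RankedPredictions") -> "RankedPredictions":
        self.ids = self.ids + other.ids
        self.strength = np.concatenate([self.strength, other.strength])
        self.is_true = np.concatenate([self.is_true, other.is_true])
        return self

    def nonzero_only(self) -> "RankedPredictions":
        """Restrict to candidates that received a nonzero prediction."""
        keep = self.strength > 0.0
        return RankedPredictions(
            ids=[id for id, k in zip(self.ids, keep) if k],
            strength=self.strength[keep],
            is_true=self.is_true[keep],
        )


def label_predictions(
    fitted: Dict[InteractionId, float],
    truth: Dict[InteractionId, float],
    universe: Iterable[InteractionId],
) -> RankedPredictions:
    """Strength = |estimate| (0 when unselected); is_true iff planted."""
    ids = list(universe)
    strength = np.array([abs(fitted.get(id, 0.0)) for id in ids])
    is_true = np.array([id in truth for id in ids], dtype=bool)
    return RankedPredictions(ids=ids, strength=strength, is_true=is_true)


def roc_auc(
    ranked: RankedPredictions,
) -> Tuple[float, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """AUROC plus curve points (fpr, tpr, thresholds) from a strength sweep."""
    labels = ranked.is_true
    if labels.all() or not labels.any():
        raise ValueError("ROC undefined: need at least one true and one false candidate")
    auc = float(roc_auc_score(labels, ranked.strength))
    fpr, tpr, thr = roc_curve(labels, ranked.strength, drop_intermediate=False)
    return auc, (fpr, tpr, thr)


def precision_recall_at_k(
    ranked: RankedPredictions, k: int
) -> Tuple[float, float]:
    """Precision and recall of the top-k candidates by strength.

    Ties are broken by sorted id; k beyond the candidate count uses all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(
        range(len(ranked.ids)),
        key=lambda t: (-ranked.strength[t], ranked.ids[t]),
    )
    top = order[: min(k, len(order))]
    n_true_top = int(ranked.is_true[top].sum())
    n_true = int(ranked.is_true.sum())
    precision = n_true_top / len(top)
    recall = n_true_top / n_true if n_true else 0.0
    return precision, recall
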