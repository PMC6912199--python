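"""Score fusion, per-disease candidate ranking and CV evaluation metrics.

The two classifier scores (similarity-feature model s1, topology-feature
model s2) are fused linearly, s = lambda*s1 + (1-lambda)*s2 with
lambda = 0.5 by default.  Candidates are ranked per disease by fused
score; evaluation uses ROC AUC (held-out positives vs. the remaining
candidates, ties counted 1/2) and precision/recall over the top-k ranked
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "ScoreTable",
    "fuse_scores",
    "rank_candidates",
    "roc_auc",
    "precision_recall_at_k",
]


def fuse_scores(s1: np.ndarray, s2: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Elementwise lambda*s1 + (1-lambda)*s2."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    s1, s2 = np.asarray(s1, float), np.asarray(s2, float)
    if s1.shape != s2.shape:
        raise ValueError("score vectors have different lengths")
    return lam * s1 + (1.0 - lam) * s2


@dataclass
class ScoreTable:
    """Per-pair scores with the fused column s = lam*s1 + (1-lam)*s2."""

    rows: pd.DataFrame  # columns: disease, mirna, s1, s2, s (+ extras)
    lam: float = 0.5

    def __post_init__(self) -> None:
        needed = {"disease", "mirna", "s1", "s2", "s"}
        missing = needed - set(self.rows.columns)
        if missing:
            raise ValueError(f"score table missing columns {sorted(missing)}")
        expected = fuse_scores(self.rows["s1"].to_numpy(), self.rows["s2"].to_numpy(), self.lam)
        if not np.allclose(self.rows["s"].to_numpy(), expected, atol=1e-12):
            raise ValueError("fused column s does not equal lam*s1 + (1-lam)*s2")

    def for_disease(self, disease: str) -> pd.DataFrame:
        sub = self.rows[self.rows["disease"] == disease]
        if sub.empty:
            raise KeyError(f"no scores for disease {disease!r}")
        return sub


def rank_candidates(table: ScoreTable, disease: str) -> list[str]:
    """miRNAs sorted by fused score descending; ties lexicographic by ID."""
    sub = table.for_disease(disease)
    order = sorted(
        zip(sub["mirna"].tolist(), sub["s"].tolist()), key=lambda t: (-t[1], t[0])
    )
    return [m for m, _ in order]


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (= Mann-Whitney concordance, ties 1/2)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def precision_recall_at_k(
    ranked: list[str], held_out: set[str], k: int
) -> tuple[float, float]:
    """Precision and recall of the top-k ranked candidates.

    pre = |top-k intersect held_out| / k, rec = same count / |held_out|.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not held_out:
        raise ValueError("held-out positive set is empty")
    hits = len(set(ranked[:k]) & held_out)
    return hits / k, hits / len(held_out)
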