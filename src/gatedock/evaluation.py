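"""Decoy ranking and hit-rate bookkeeping.

A *hit* for a target at rank k means at least one correct
(CAPRI-acceptable or better) decoy among the k highest-scored models
of that target.  The hit rate at k is the fraction of targets with a
hit; the grouped variant first averages the per-target hit indicator
within each redundancy group and then averages the group means, so
families of similar complexes count once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capri_metrics import QualityClass


@dataclass
class RankedTarget:
    target_id: str
    ranked: list[tuple[str, float, str]]  # (decoy_id, score, label), sorted

    def __post_init__(self):
        scores = [s for _, s, _ in self.ranked]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranked list must be sorted by score descending")

    def first_hit_rank(self) -> int | None:
        for rank, (_, _, label) in enumerate(self.ranked, start=1):
            if label == "correct":
                return rank
        return None

    def hit_at(self, k: int) -> bool:
        rank = self.first_hit_rank()
        return rank is not None and rank <= k


@dataclass
class HitRateCurve:
    fraction_with_hit: dict[int, float]  # rank k -> fraction of targets

    def as_array(self) -> np.ndarray:
        ks = sorted(self.fraction_with_hit)
        return np.array([self.fraction_with_hit[k] for k in ks])


def rank_decoys(scores: dict[str, float], labels: dict[str, str] | None = None,
                target_id: str = "") -> RankedTarget:
    """Stable descending sort; ties keep input (insertion) order."""
    if not scores:
        raise ValueError("no scores to rank")
    labels = labels or {}
    items = [(decoy, float(score), labels.get(decoy, "incorrect"))
             for decoy, score in scores.items()]
    ranked = sorted(items, key=lambda item: -item[1])  # sorted() is stable
    return RankedTarget(target_id=target_id, ranked=ranked)


def hit_rate(targets: list[RankedTarget], k_max: int) -> HitRateCurve:
    """Fraction of targets with >= 1 correct decoy in the top k, k=1..k_max."""
    if not targets:
        raise ValueError("no targets")
    curve = {}
    for k in range(1, k_max + 1):
        curve[k] = sum(t.hit_at(k) for t in targets) / len(targets)
    return HitRateCurve(curve)


def grouped_hit_rate(targets: list[RankedTarget], groups: dict[str, str],
                     k: int) -> float:
    """Per-group mean of the top-k hit indicator, then mean over groups."""
    by_group: dict[str, list[bool]] = {}
    for t in targets:
        if t.target_id not in groups:
            raise KeyError(f"target {t.target_id!r} missing from groups map")
        by_group.setdefault(groups[t.target_id], []).append(t.hit_at(k))
    return float(np.mean([np.mean(hits) for hits in by_group.values()]))


def top_k_quality_counts(target: RankedTarget,
                         metrics: dict[str, QualityClass],
                         k: int) -> dict[str, int]:
    """Cumulative class counts among the top k ranked decoys.

    Returns counts of acceptable-or-better, medium-or-better and
    high; by construction high <= medium <= acceptable.
    """
    counts = {"acceptable": 0, "medium": 0, "high": 0}
    for decoy_id, _, _ in target.ranked[:k]:
        if decoy_id not in metrics:
            raise KeyError(f"no quality class for top-{k} decoy {decoy_id!r}")
        cls = metrics[decoy_id]
        if cls >= QualityClass.acceptable:
            counts["acceptable"] += 1
        if cls >= QualityClass.medium:
            counts["medium"] += 1
        if cls >= QualityClass.high:
            counts["high"] += 1
    return counts
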