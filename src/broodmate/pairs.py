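"""Rank all sire x dam pairs with the composite v index and pick disjoint sets.

The v index is a user-weighted sum of cohort-relative diversity indicators:

    v = i_H * (H / max H) + i_ar * (ar / max ar) + i_wh * (1 - wh / max wh)

where H is the pair's expected progeny heterozygosity, ar its progeny allele
number and wh its weak-heterozygote share; maxima are taken over the cohort
of all candidate pairs, so v is in [0, 1] and the best attainable pair scores
1.  Heterozygosity and allele number are rewarded, weak heterozygotes
penalised.  Default weights: i_H = 0.45, i_wh = 0.1, i_ar = 0.45.

Selection returns K pairs in which no individual appears twice, either
greedily (take the best remaining pair repeatedly — smaller selected sets
nest inside larger ones) or exactly (a maximum-total-v assignment of size K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .panel import GenotypePanel, UsageError
from .progeny import PairPrediction, predict_pair

__all__ = [
    "VIndexWeights",
    "PairSelectionResult",
    "enumerate_pairs",
    "v_index",
    "score_pairs",
    "select_best_pairs",
    "count_pair_combinations",
]


@dataclass(frozen=True)
class VIndexWeights:
    """The three v-index coefficients; normalized to sum to 1."""

    i_H: float = 0.45
    i_wh: float = 0.1
    i_ar: float = 0.45

    def __post_init__(self):
        if min(self.i_H, self.i_wh, self.i_ar) < 0:
            raise UsageError("v-index weights must be non-negative")
        s = self.i_H + self.i_wh + self.i_ar
        if s <= 0:
            raise UsageError("at least one v-index weight must be positive")
        object.__setattr__(self, "i_H", self.i_H / s)
        object.__setattr__(self, "i_wh", self.i_wh / s)
        object.__setattr__(self, "i_ar", self.i_ar / s)


def count_pair_combinations(n_males: int, n_females: int) -> int:
    """Number of distinct sire x dam pairings (the product rule)."""
    if n_males < 0 or n_females < 0:
        raise UsageError("counts must be non-negative")
    return n_males * n_females


def enumerate_pairs(panel: GenotypePanel) -> list[PairPrediction]:
    """Progeny predictions for every male x female pair, in file order."""
    males = panel.males()
    females = panel.females()
    if not males or not females:
        raise UsageError("panel needs at least one male and one female")
    return [predict_pair(panel, m.id, f.id) for m in males for f in females]


def _cohort_maxima(cohort: Sequence[PairPrediction]) -> tuple[float, float, float]:
    return (max(p.H_mean for p in cohort),
            max(p.ar_total for p in cohort),
            max(p.wh_share for p in cohort))


def v_index(pair: PairPrediction, cohort: Sequence[PairPrediction],
            weights: Optional[VIndexWeights] = None) -> float:
    """Composite score of one pair relative to its cohort, in [0, 1].

    A cohort maximum of 0 makes its term contribute its full weight (the
    pair trivially attains the best value, and 0/0 is read as 1).
    """
    if not cohort:
        raise UsageError("cohort must be non-empty")
    w = weights or VIndexWeights()
    h_max, ar_max, wh_max = _cohort_maxima(cohort)
    rel_h = 1.0 if h_max == 0 else pair.H_mean / h_max
    rel_ar = 1.0 if ar_max == 0 else pair.ar_total / ar_max
    rel_wh = 0.0 if wh_max == 0 else pair.wh_share / wh_max
    return w.i_H * rel_h + w.i_ar * rel_ar + w.i_wh * (1.0 - rel_wh)


def score_pairs(cohort: Sequence[PairPrediction],
                weights: Optional[VIndexWeights] = None
                ) -> list[PairPrediction]:
    """Fill the ``v`` field of every prediction in the cohort (in place)."""
    for p in cohort:
        p.v = v_index(p, cohort, weights)
    return list(cohort)


@dataclass
class PairSelectionResult:
    """K disjoint breeding pairs plus selected-vs-cohort mean indicators."""

    pairs: list[PairPrediction]          # descending v
    mean_H: float
    mean_ar: float
    mean_wh: float
    mean_v: float
    cohort_mean_H: float
    cohort_mean_ar: float
    cohort_mean_wh: float
    cohort_mean_v: float


def _rank_key(p: PairPrediction):
    # ties in v: prefer more alleles, fewer weak hets, then lexicographic IDs
    return (-p.v, -p.ar_total, p.wh_share, p.male_id, p.female_id)


def _greedy(cohort: list[PairPrediction], k: int) -> list[PairPrediction]:
    chosen: list[PairPrediction] = []
    used: set[str] = set()
    for p in sorted(cohort, key=_rank_key):
        if p.male_id in used or p.female_id in used:
            continue
        chosen.append(p)
        used.update((p.male_id, p.female_id))
        if len(chosen) == k:
            break
    return chosen


def _exact(cohort: list[PairPrediction], k: int,
           male_ids: list[str], female_ids: list[str]) -> list[PairPrediction]:
    """Maximum-total-v set of exactly k disjoint pairs.

    Solved as a rectangular assignment problem: each male is assigned to a
    real female (gaining that pair's v) or to one of M-k dummy columns whose
    bonus exceeds any v, so exactly M-k males sit out and the k real
    assignments maximize summed v.
    """
    m, f = len(male_ids), len(female_ids)
    mi = {x: i for i, x in enumerate(male_ids)}
    fi = {x: j for j, x in enumerate(female_ids)}
    lut: dict[tuple[int, int], PairPrediction] = {
        (mi[p.male_id], fi[p.female_id]): p for p in cohort}
    bonus = 2.0  # > max possible v (v <= 1)
    cost = np.full((m, f + (m - k)), 0.0)
    for (i, j), p in lut.items():
        cost[i, j] = -p.v
    cost[:, f:] = -bonus
    rows, cols = linear_sum_assignment(cost)
    chosen = [lut[(i, j)] for i, j in zip(rows, cols) if j < f]
    return sorted(chosen, key=_rank_key)


def select_best_pairs(panel: GenotypePanel, K: int,
                      weights: Optional[VIndexWeights] = None,
                      method: str = "greedy") -> PairSelectionResult:
    """Select K disjoint breeding pairs ranked by the v index.

    ``greedy`` (default) repeatedly takes the highest-v pair whose members
    are both unused; selections nest (the K=4 set is contained in the K=8
    set).  ``exact`` maximizes the summed v over all disjoint K-pair sets
    via an optimal assignment.
    """
    males = panel.males()
    females = panel.females()
    limit = min(len(males), len(females))
    if K < 1:
        raise UsageError("K must be at least 1")
    if K > limit:
        raise UsageError(
            f"K={K} exceeds the {limit} disjoint pairs this panel supports "
            f"({len(males)} males, {len(females)} females)")
    cohort = score_pairs(enumerate_pairs(panel), weights)
    if method == "greedy":
        chosen = _greedy(cohort, K)
    elif method == "exact":
        chosen = _exact(cohort, K, [m.id for m in males],
                        [f.id for f in females])
    else:
        raise UsageError(f"unknown selection method {method!r}")

    ids = [x for p in chosen for x in (p.male_id, p.female_id)]
    assert len(ids) == len(set(ids)), "selected pairs share an individual"

    def _means(ps):
        n = len(ps)
        return (sum(p.H_mean for p in ps) / n,
                sum(p.ar_total for p in ps) / n,
                sum(p.wh_share for p in ps) / n,
                sum(p.v for p in ps) / n)

    mh, mar, mwh, mv = _means(chosen)
    ch, car, cwh, cv = _means(cohort)
    return PairSelectionResult(chosen, mh, mar, mwh, mv, ch, car, cwh, cv)
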