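"""Subset search for volitional group spawning.

Given a broodstock panel, find m males and f females whose combined genotypes
maximize the allelic diversity transmitted to the progeny group — the number
of alleles is the primary indicator, with expected progeny heterozygosity
(equal-contribution model) breaking ties.  The search space C(M,m) * C(F,f)
explodes quickly, so exhaustive enumeration is used only under a configurable
budget; above it, a greedy build on the (monotone, submodular) allele-coverage
objective followed by single-swap local exchange is used instead.

Allele coverage is encoded as one bitmask per individual over the panel's
(locus, allele) inventory, so the union of a candidate set is a bitwise OR
and its size a popcount — cheap enough to enumerate millions of subsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

from .panel import GenotypePanel, Individual, UsageError
from .progeny import SpawningPrediction, predict_group

__all__ = [
    "SearchSpaceReport",
    "SpawningSetResult",
    "count_subsets",
    "search_space",
    "search_best_set",
    "list_alternative_sets",
    "DEFAULT_EXHAUSTIVE_LIMIT",
]

DEFAULT_EXHAUSTIVE_LIMIT = 10_000_000


def count_subsets(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k), integer arithmetic throughout."""
    if n < 0 or k < 0:
        raise UsageError("n and k must be non-negative")
    if k > n:
        raise UsageError(f"cannot choose {k} from {n}")
    return math.comb(n, k)


@dataclass(frozen=True)
class SearchSpaceReport:
    """How many candidate subsets and subset pairs a search faces."""

    male_subsets: int
    female_subsets: int
    total_combinations: int


def search_space(panel: GenotypePanel, m: int, f: int) -> SearchSpaceReport:
    """Exact size of the m-male/f-female subset search space."""
    n_males = len(panel.males())
    n_females = len(panel.females())
    if m > n_males:
        raise UsageError(f"requested {m} males but panel has {n_males}")
    if f > n_females:
        raise UsageError(f"requested {f} females but panel has {n_females}")
    ms = count_subsets(n_males, m)
    fs = count_subsets(n_females, f)
    return SearchSpaceReport(ms, fs, ms * fs)


@dataclass
class SpawningSetResult:
    """A chosen spawning set with its progeny prediction."""

    male_ids: tuple[str, ...]
    female_ids: tuple[str, ...]
    prediction: SpawningPrediction
    rank: int
    search_mode: str


# ---------------------------------------------------------------------------
# allele-coverage machinery
# ---------------------------------------------------------------------------

def _allele_bitmasks(panel: GenotypePanel,
                     parents: Sequence[Individual]) -> list[int]:
    """One bitmask per parent over the panel-wide (locus, allele) inventory."""
    bit: dict[tuple[int, int], int] = {}
    for k, locus in enumerate(panel.locus_names):
        for ind in panel.individuals:
            gt = ind.genotypes[k]
            if gt is not None:
                for a in gt:
                    bit.setdefault((k, a), len(bit))
    masks = []
    for p in parents:
        mask = 0
        for k in range(panel.n_loci):
            gt = p.genotypes[k]
            if gt is not None:
                for a in gt:
                    mask |= 1 << bit[(k, a)]
        masks.append(mask)
    return masks


def _coverage(masks: Sequence[int], idx: Sequence[int]) -> int:
    u = 0
    for i in idx:
        u |= masks[i]
    return u.bit_count()


def _set_key(panel: GenotypePanel, male_ids, female_ids):
    """Lexicographic objective with deterministic tie-break (larger is better).

    (alleles transmitted, H_mean, -wh_share, then smallest sorted ID tuples).
    """
    pred = predict_group(panel, male_ids, female_ids)
    tie = tuple(sorted(male_ids)) + tuple(sorted(female_ids))
    return (pred.ar_total, pred.H_mean, -pred.wh_share,
            tuple(-ord(c) for c in "\x00".join(tie))), pred


def _better(key_a, key_b) -> bool:
    return key_a > key_b


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def _exhaustive_best(panel: GenotypePanel, males, females, m, f):
    m_masks = _allele_bitmasks(panel, males)
    f_masks = _allele_bitmasks(panel, females)
    male_sets = list(combinations(range(len(males)), m))
    female_sets = list(combinations(range(len(females)), f))
    f_unions = []
    for s in female_sets:
        u = 0
        for j in s:
            u |= f_masks[j]
        f_unions.append((u, s))
    # pass 1: find the maximum allele coverage with cheap popcounts
    best_ar = -1
    candidates = []
    for ms in male_sets:
        mu = 0
        for i in ms:
            mu |= m_masks[i]
        for fu, fs in f_unions:
            ar = (mu | fu).bit_count()
            if ar > best_ar:
                best_ar = ar
                candidates = [(ms, fs)]
            elif ar == best_ar:
                candidates.append((ms, fs))
    # pass 2: break ties on the full prediction
    best_key, best_pred, best_ids = None, None, None
    for ms, fs in candidates:
        mids = tuple(males[i].id for i in ms)
        fids = tuple(females[j].id for j in fs)
        key, pred = _set_key(panel, mids, fids)
        if best_key is None or _better(key, best_key):
            best_key, best_pred, best_ids = key, pred, (mids, fids)
    return best_ids, best_pred


def _greedy_exchange_best(panel: GenotypePanel, males, females, m, f,
                          seed: int):
    all_parents = list(males) + list(females)
    masks = _allele_bitmasks(panel, all_parents)
    is_male = [True] * len(males) + [False] * len(females)

    # greedy build: add the eligible candidate with the largest marginal
    # allele-coverage gain; ties by own coverage then ID
    chosen: set[int] = set()
    union = 0
    n_m = n_f = 0
    while n_m < m or n_f < f:
        best = None  # (gain, own coverage, id, index)
        for i, mask in enumerate(masks):
            if i in chosen:
                continue
            if is_male[i] and n_m >= m:
                continue
            if not is_male[i] and n_f >= f:
                continue
            gain = (union | mask).bit_count() - union.bit_count()
            cand = (gain, mask.bit_count(), all_parents[i].id, i)
            # larger gain wins; then richer individual; then smaller ID
            if (best is None
                    or (cand[0], cand[1]) > (best[0], best[1])
                    or ((cand[0], cand[1]) == (best[0], best[1])
                        and cand[2] < best[2])):
                best = cand
        i = best[3]
        chosen.add(i)
        union |= masks[i]
        if is_male[i]:
            n_m += 1
        else:
            n_f += 1

    mids = tuple(all_parents[i].id for i in chosen if is_male[i])
    fids = tuple(all_parents[i].id for i in chosen if not is_male[i])
    key, pred = _set_key(panel, mids, fids)

    # 1-swap local exchange on the full lexicographic objective
    improved = True
    while improved:
        improved = False
        cur_m, cur_f = set(mids), set(fids)
        best_key, best_state = key, None
        for pool, cur in ((males, cur_m), (females, cur_f)):
            for out in sorted(cur):
                for cand in pool:
                    if cand.id in cur_m or cand.id in cur_f:
                        continue
                    new_m = tuple(sorted((cur_m - {out}) | {cand.id})) \
                        if pool is males else tuple(sorted(cur_m))
                    new_f = tuple(sorted((cur_f - {out}) | {cand.id})) \
                        if pool is females else tuple(sorted(cur_f))
                    k2, p2 = _set_key(panel, new_m, new_f)
                    if _better(k2, best_key):
                        best_key, best_state = k2, (new_m, new_f, p2)
        if best_state is not None:
            mids, fids, pred = best_state
            key = best_key
            improved = True
    return (tuple(mids), tuple(fids)), pred


def search_best_set(panel: GenotypePanel, m: int, f: int,
                    mode: str = "auto",
                    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
                    seed: int = 0) -> SpawningSetResult:
    """Find the m-male/f-female set maximizing transmitted allelic diversity.

    The objective is lexicographic: most alleles transmitted first, then
    highest expected progeny heterozygosity.  ``auto`` enumerates
    exhaustively when the search space is within ``limit`` subset pairs and
    otherwise falls back to greedy construction plus 1-swap exchange, which
    is locally optimal (no single-individual replacement improves it).
    """
    if limit <= 0:
        raise UsageError("limit must be positive")
    males = panel.males()
    females = panel.females()
    if not (1 <= m <= len(males)):
        raise UsageError(f"need 1 <= m <= {len(males)}, got {m}")
    if not (1 <= f <= len(females)):
        raise UsageError(f"need 1 <= f <= {len(females)}, got {f}")
    space = search_space(panel, m, f)
    if mode == "auto":
        mode = ("exhaustive" if space.total_combinations <= limit
                else "greedy_exchange")
    if mode == "exhaustive":
        if space.total_combinations > limit:
            raise UsageError(
                f"exhaustive search over {space.total_combinations} "
                f"combinations exceeds limit={limit}")
        ids, pred = _exhaustive_best(panel, males, females, m, f)
    elif mode == "greedy_exchange":
        ids, pred = _greedy_exchange_best(panel, males, females, m, f, seed)
    else:
        raise UsageError(f"unknown search mode {mode!r}")
    return SpawningSetResult(ids[0], ids[1], pred, rank=1, search_mode=mode)


def list_alternative_sets(panel: GenotypePanel, m: int, f: int,
                          min_alleles: int,
                          h_range: tuple[float, float] = (0.0, 1.0),
                          limit: int = DEFAULT_EXHAUSTIVE_LIMIT
                          ) -> list[SpawningSetResult]:
    """All m/f subset pairs meeting an allele floor and a heterozygosity band.

    Requires the search space to fit the exhaustive budget; results are
    ranked by (alleles transmitted, H_mean) descending with the deterministic
    ID tie-break.
    """
    males = panel.males()
    females = panel.females()
    space = search_space(panel, m, f)
    if space.total_combinations > limit:
        raise UsageError(
            f"exhaustive enumeration over {space.total_combinations} "
            f"combinations exceeds limit={limit}; alternative-set listing "
            "needs an exhaustive search")
    lo, hi = h_range
    hits = []
    for ms in combinations(males, m):
        for fs in combinations(females, f):
            mids = tuple(p.id for p in ms)
            fids = tuple(p.id for p in fs)
            pred = predict_group(panel, mids, fids)
            if pred.ar_total >= min_alleles and lo <= pred.H_mean <= hi:
                tie = tuple(sorted(mids)) + tuple(sorted(fids))
                hits.append(((-pred.ar_total, -pred.H_mean, pred.wh_share,
                              tie), mids, fids, pred))
    hits.sort(key=lambda t: t[0])
    return [SpawningSetResult(mids, fids, pred, rank=r + 1,
                              search_mode="exhaustive")
            for r, (_, mids, fids, pred) in enumerate(hits)]
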