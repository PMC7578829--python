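"""Expected progeny diversity under Mendelian inheritance.

For a single sire x dam pair, each locus yields four equally likely offspring
genotypes (one allele from each parent), so every pair statistic has a closed
form over those four outcomes:

* expected offspring heterozygosity — fraction of the 4 outcomes with two
  distinct alleles;
* progeny allele number — distinct alleles among the 4 parental copies
  (every parental allele is transmissible to the progeny group);
* "weak heterozygote" flag — the parents' four copies show the 3:1 AAAB
  pattern, i.e. heterozygous offspring can differ by only a single allele.
  Half of the offspring at such a locus are those weak heterozygotes.

For a group-spawning set the model assumes every spawner contributes equally:
an offspring draws its sire uniformly from the selected males, its dam
uniformly from the selected females, and one random allele from each.  Loci
are treated as independent (no linkage).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .panel import (FEMALE, MALE, Genotype, GenotypePanel, Individual,
                    UndefinedStatisticError, UsageError)

__all__ = [
    "PairLocusStats",
    "PairPrediction",
    "SpawningPrediction",
    "pair_locus_offspring_distribution",
    "pair_expected_heterozygosity",
    "pair_allele_count",
    "pair_weak_het_share",
    "is_weak_pattern",
    "predict_pair",
    "predict_group",
    "group_weak_het_share",
]


# ---------------------------------------------------------------------------
# single-locus pair statistics
# ---------------------------------------------------------------------------

def pair_locus_offspring_distribution(gm: Genotype, gf: Genotype
                                      ) -> list[tuple[int, int]]:
    """The four equally likely offspring genotypes of one locus.

    Returns the ordered combinations {sire allele} x {dam allele} as sorted
    pairs, each with probability 1/4.  This enumeration is the brute-force
    oracle behind the closed-form pair statistics.
    """
    if gm is None or gf is None:
        raise UndefinedStatisticError("missing parental genotype")
    return [tuple(sorted((a, b))) for a in gm for b in gf]


def pair_expected_heterozygosity(gm: Genotype, gf: Genotype) -> float:
    """P(offspring heterozygous) = (1/4) * #{(i,j): sire_i != dam_j}."""
    if gm is None or gf is None:
        raise UndefinedStatisticError("missing parental genotype")
    return sum(a != b for a in gm for b in gf) / 4.0

def pair_allele_count(gm: Genotype, gf: Genotype) -> int:
    """Distinct alleles among the four parental copies (1..4)."""
    if gm is None or gf is None:
        raise UndefinedStatisticError("missing parental genotype")
    return len(set(gm) | set(gf))

def is_weak_pattern(gm: Genotype, gf: Genotype) -> bool:
    """True iff the four parental copies are two alleles in a 3:1 pattern."""
    if gm is None or gf is None:
        raise UndefinedStatisticError("missing parental genotype")
    counts = Counter(gm) + Counter(gf)
    return sorted(counts.values()) == [1, 3]


def pair_weak_het_share(male: Individual, female: Individual) -> float:
    """Expected share of weak-heterozygous offspring outcomes across loci.

    At an AAAB locus half the offspring are heterozygotes differing by the
    single odd allele copy; elsewhere the contribution is 0.  The share is
    the mean over loci where both parents are called.
    """
    vals = []
    for gm, gf in zip(male.genotypes, female.genotypes):
        if gm is None or gf is None:
            continue
        vals.append(0.5 if is_weak_pattern(gm, gf) else 0.0)
    if not vals:
        raise UndefinedStatisticError(
            f"pair {male.id} x {female.id} has no locus called in both")
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# pair-level aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairLocusStats:
    H_exp: float     # in {0, .25, .5, .75, 1}
    ar: int          # 1..4
    weak: bool


@dataclass
class PairPrediction:
    """Expected progeny statistics of one sire x dam pair.

    ``H_mean`` averages per-locus expected heterozygosity, ``ar_total`` sums
    per-locus allele numbers, ``wh_share`` is the weak-heterozygote share —
    all over loci called in both parents.  ``v`` is the composite ranking
    score, filled in by pair selection (cohort-relative, so undefined for an
    isolated pair).
    """

    male_id: str
    female_id: str
    per_locus: dict[str, Optional[PairLocusStats]]
    H_mean: float
    ar_total: int
    wh_share: float
    n_evaluable: int
    v: Optional[float] = None


def predict_pair(panel: GenotypePanel, male_id: str, female_id: str
                 ) -> PairPrediction:
    """Closed-form progeny prediction for one candidate breeding pair."""
    male = panel.individual(male_id)
    female = panel.individual(female_id)
    if male.sex != MALE:
        raise UsageError(f"{male_id!r} is not male")
    if female.sex != FEMALE:
        raise UsageError(f"{female_id!r} is not female")

    per_locus: dict[str, Optional[PairLocusStats]] = {}
    hs, ars, whs = [], [], []
    for locus, gm, gf in zip(panel.locus_names, male.genotypes,
                             female.genotypes):
        if gm is None or gf is None:
            per_locus[locus] = None  # non-evaluable, excluded from means
            continue
        st = PairLocusStats(pair_expected_heterozygosity(gm, gf),
                            pair_allele_count(gm, gf),
                            is_weak_pattern(gm, gf))
        per_locus[locus] = st
        hs.append(st.H_exp)
        ars.append(st.ar)
        whs.append(0.5 if st.weak else 0.0)
    if not hs:
        raise UndefinedStatisticError(
            f"pair {male_id} x {female_id} has no evaluable locus")
    return PairPrediction(
        male_id=male_id,
        female_id=female_id,
        per_locus=per_locus,
        H_mean=sum(hs) / len(hs),
        ar_total=sum(ars),
        wh_share=sum(whs) / len(whs),
        n_evaluable=len(hs),
    )


# ---------------------------------------------------------------------------
# group-spawning prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupLocusStats:
    alleles_transmitted: int
    H_exp: Optional[float]   # None where either sex has no called genotype


@dataclass
class SpawningPrediction:
    """Expected progeny statistics of a group-spawning set.

    Equal-contribution model: offspring sire and dam are uniform over the
    selected males and females (restricted, per locus, to parents called
    there), and each transmits one of its two alleles with probability 1/2.
    ``alleles_transmitted`` per locus is the union of all selected parents'
    alleles; ``wh_share`` is the mean weak-heterozygote share over all
    member sire x dam pairs.
    """

    male_ids: tuple[str, ...]
    female_ids: tuple[str, ...]
    per_locus: dict[str, GroupLocusStats]
    ar_total: int
    H_mean: float
    wh_share: float


def _sex_frequencies(parents: Sequence[Individual], locus_index: int
                     ) -> Optional[dict[int, float]]:
    """Allele frequencies in one parental sex pool under equal contribution.

    Each called parent carries weight 1/(number called), split 1/2 per allele
    copy; parents uncalled at the locus drop out of that locus's pool.
    """
    called = [p.genotypes[locus_index] for p in parents
              if p.genotypes[locus_index] is not None]
    if not called:
        return None
    w = 1.0 / (2 * len(called))
    freqs: dict[int, float] = {}
    for a, b in called:
        freqs[a] = freqs.get(a, 0.0) + w
        freqs[b] = freqs.get(b, 0.0) + w
    return freqs


def predict_group(panel: GenotypePanel, male_ids: Sequence[str],
                  female_ids: Sequence[str]) -> SpawningPrediction:
    """Expected progeny diversity of a male/female set under group spawning."""
    if not male_ids or not female_ids:
        raise UsageError("male and female ID lists must be non-empty")
    if set(male_ids) & set(female_ids):
        raise UsageError("male and female ID lists overlap")
    if len(set(male_ids)) != len(male_ids) or len(set(female_ids)) != len(female_ids):
        raise UsageError("duplicate IDs in a spawning set")
    males = [panel.individual(i) for i in male_ids]
    females = [panel.individual(i) for i in female_ids]
    for p in males:
        if p.sex != MALE:
            raise UsageError(f"{p.id!r} listed as male but is {p.sex}")
    for p in females:
        if p.sex != FEMALE:
            raise UsageError(f"{p.id!r} listed as female but is {p.sex}")

    per_locus: dict[str, GroupLocusStats] = {}
    hs = []
    ar_total = 0
    for k, locus in enumerate(panel.locus_names):
        union: set[int] = set()
        for p in males + females:
            gt = p.genotypes[k]
            if gt is not None:
                union.update(gt)
        pm = _sex_frequencies(males, k)
        pf = _sex_frequencies(females, k)
        if pm is None or pf is None:
            per_locus[locus] = GroupLocusStats(len(union), None)
        else:
            h = 1.0 - sum(pm[a] * pf.get(a, 0.0) for a in pm)
            per_locus[locus] = GroupLocusStats(len(union), h)
            hs.append(h)
        ar_total += len(union)
    if not hs:
        raise UndefinedStatisticError("no locus is callable in both sexes")

    return SpawningPrediction(
        male_ids=tuple(male_ids),
        female_ids=tuple(female_ids),
        per_locus=per_locus,
        ar_total=ar_total,
        H_mean=sum(hs) / len(hs),
        wh_share=group_weak_het_share(panel, male_ids, female_ids),
    )


def group_weak_het_share(panel: GenotypePanel, male_ids: Sequence[str],
                         female_ids: Sequence[str]) -> float:
    """Mean pair-level weak-heterozygote share over all member pairs.

    One possible operationalization of a group-level "share of weak
    heterozygotes"; pairs with no jointly called locus are skipped.
    """
    males = [panel.individual(i) for i in male_ids]
    females = [panel.individual(i) for i in female_ids]
    vals = []
    for m in males:
        for f in females:
            try:
                vals.append(pair_weak_het_share(m, f))
            except UndefinedStatisticError:
                continue
    if not vals:
        raise UndefinedStatisticError("no member pair has an evaluable locus")
    return sum(vals) / len(vals)
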