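"""Summary statistics of genetic variation for a group of genotyped fish.

Observed heterozygosity (Ho), expected heterozygosity (He, gene diversity)
and the number of distinct alleles (ar) are computed per locus and averaged
(Ho, He) or summed (ar) across loci.  ``ar`` is a raw distinct-allele count,
not rarefaction-corrected allelic richness.  Missing genotypes are excluded
locus-by-locus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .panel import GenotypePanel, UndefinedStatisticError

__all__ = [
    "LocusDiversity",
    "DiversitySummary",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "allele_counts",
    "summarize",
]


@dataclass(frozen=True)
class LocusDiversity:
    Ho: float
    He: float
    ar: int
    n_typed: int


@dataclass(frozen=True)
class DiversitySummary:
    """Per-locus and across-loci diversity of a group of individuals.

    Across-loci Ho and He are unweighted means over loci with called data;
    ar_total is the sum of per-locus distinct-allele counts.
    """

    per_locus: dict[str, LocusDiversity]
    Ho: float
    He: float
    ar_total: int
    n_individuals: int


def _called(panel: GenotypePanel, locus: str):
    return [gt for gt in panel.genotypes_at(locus) if gt is not None]


def observed_heterozygosity(panel: GenotypePanel, locus: str) -> float:
    """Fraction of called genotypes at *locus* carrying two distinct alleles."""
    called = _called(panel, locus)
    if not called:
        raise UndefinedStatisticError(
            f"no called genotypes at locus {locus!r}")
    return sum(a != b for a, b in called) / len(called)


def expected_heterozygosity(panel: GenotypePanel, locus: str,
                            unbiased: bool = False) -> float:
    """Gene diversity 1 - sum(p_k^2) over allele frequencies at *locus*.

    With ``unbiased`` the plug-in value is scaled by 2n/(2n-1) (Nei's
    small-sample correction), where n is the number of called genotypes.
    """
    called = _called(panel, locus)
    if not called:
        raise UndefinedStatisticError(
            f"no called genotypes at locus {locus!r}")
    copies = Counter()
    for a, b in called:
        copies[a] += 1
        copies[b] += 1
    total = sum(copies.values())
    he = 1.0 - sum((c / total) ** 2 for c in copies.values())
    if unbiased and total > 1:
        he *= total / (total - 1)
    return he


def allele_counts(panel: GenotypePanel) -> tuple[dict[str, int], int]:
    """Distinct-allele count per locus and their sum across loci."""
    per_locus: dict[str, int] = {}
    for locus in panel.locus_names:
        alleles = set()
        for gt in panel.genotypes_at(locus):
            if gt is not None:
                alleles.update(gt)
        per_locus[locus] = len(alleles)
    return per_locus, sum(per_locus.values())


def summarize(panel: GenotypePanel,
              subset: Optional[Sequence[str]] = None,
              unbiased_he: bool = False) -> DiversitySummary:
    """Full diversity summary for the panel or a named subset of IDs."""
    target = panel if subset is None else panel.subset(subset)
    ar_per_locus, ar_total = allele_counts(target)
    per_locus: dict[str, LocusDiversity] = {}
    hos, hes = [], []
    for locus in target.locus_names:
        called = _called(target, locus)
        if not called:
            per_locus[locus] = LocusDiversity(float("nan"), float("nan"),
                                              ar_per_locus[locus], 0)
            continue
        ho = observed_heterozygosity(target, locus)
        he = expected_heterozygosity(target, locus, unbiased=unbiased_he)
        per_locus[locus] = LocusDiversity(ho, he, ar_per_locus[locus],
                                          len(called))
        hos.append(ho)
        hes.append(he)
    if not hos:
        raise UndefinedStatisticError("panel has no called genotypes")
    return DiversitySummary(
        per_locus=per_locus,
        Ho=sum(hos) / len(hos),
        He=sum(hes) / len(hes),
        ar_total=ar_total,
        n_individuals=len(target.individuals),
    )
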