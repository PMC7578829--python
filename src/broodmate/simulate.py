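"""Synthetic genotype panels with controlled allele-frequency structure.

Genotypes are drawn per locus from specified allele frequencies, with an
inbreeding-like heterozygote-deficit parameter f_is deforming the
Hardy-Weinberg proportions:

    P(het k,l)  = 2 p_k p_l (1 - f_is)
    P(hom k,k)  = p_k^2 + f_is p_k (1 - p_k)

so f_is = 0 gives Hardy-Weinberg and f_is = 1 all-homozygote.  Missingness
is applied per genotype (both copies together).  Everything is reproducible
from the spec's seed.

``study_scale_fixture`` emulates the shape of a small, genetically depleted
hatchery broodstock: 23 males, 25 females, 13 microsatellite loci carrying
33 alleles in total, overall observed heterozygosity in the low-diversity
band 0.30-0.46.  It reproduces that shape, not any real genotype values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .panel import (FEMALE, MALE, Genotype, GenotypePanel, Individual,
                    UsageError, ValidationError)
from .diversity import summarize, allele_counts

__all__ = [
    "LocusSpec",
    "PanelSpec",
    "simulate_panel",
    "study_scale_fixture",
    "frequency_recovery_check",
    "load_panel_spec",
]


@dataclass(frozen=True)
class LocusSpec:
    """Allele inventory, frequencies and heterozygote deficit of one locus."""

    name: str
    allele_codes: tuple[int, ...]
    frequencies: tuple[float, ...]
    f_is: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "allele_codes", tuple(self.allele_codes))
        object.__setattr__(self, "frequencies", tuple(self.frequencies))
        if len(self.allele_codes) != len(self.frequencies):
            raise ValidationError(
                f"locus {self.name!r}: {len(self.allele_codes)} alleles but "
                f"{len(self.frequencies)} frequencies")
        if len(set(self.allele_codes)) != len(self.allele_codes):
            raise ValidationError(f"locus {self.name!r}: duplicate allele codes")
        if any(a < 1 for a in self.allele_codes):
            raise ValidationError(f"locus {self.name!r}: allele codes must be >= 1")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValidationError(
                f"locus {self.name!r}: frequencies sum to "
                f"{sum(self.frequencies)}, not 1")
        if any(p < 0 for p in self.frequencies):
            raise ValidationError(f"locus {self.name!r}: negative frequency")
        if not -1.0 <= self.f_is <= 1.0:
            raise ValidationError(f"locus {self.name!r}: f_is outside [-1, 1]")


@dataclass(frozen=True)
class PanelSpec:
    """Blueprint of a simulated broodstock panel."""

    n_males: int
    n_females: int
    loci: tuple[LocusSpec, ...]
    missing_rate: float = 0.0
    seed: int = 0
    population: str = "sim"
    group: str = "SIM"

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))
        if self.n_males + self.n_females < 2:
            raise ValidationError("need at least two individuals in total")
        if self.n_males < 0 or self.n_females < 0:
            raise ValidationError("negative sex count")
        if not self.loci:
            raise ValidationError("need at least one locus")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")


def _genotype_distribution(spec: LocusSpec):
    """All genotype categories of a locus and their probabilities."""
    codes = spec.allele_codes
    p = spec.frequencies
    f = spec.f_is
    cats: list[Genotype] = []
    probs: list[float] = []
    for i, a in enumerate(codes):
        for j, b in enumerate(codes[i:], start=i):
            if i == j:
                pr = p[i] ** 2 + f * p[i] * (1 - p[i])
            else:
                pr = 2 * p[i] * p[j] * (1 - f)
            cats.append((a, b) if a <= b else (b, a))
            probs.append(pr)
    probs = np.clip(np.asarray(probs), 0.0, None)
    return cats, probs / probs.sum()


def simulate_panel(spec: PanelSpec) -> GenotypePanel:
    """Draw a full panel from a :class:`PanelSpec`; bit-reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_males + spec.n_females
    width = max(2, len(str(n)))
    ids = ([f"M{i + 1:0{width}d}" for i in range(spec.n_males)]
           + [f"F{i + 1:0{width}d}" for i in range(spec.n_females)])
    sexes = [MALE] * spec.n_males + [FEMALE] * spec.n_females

    columns: list[list[Genotype]] = []
    for locus in spec.loci:
        cats, probs = _genotype_distribution(locus)
        draws = rng.choice(len(cats), size=n, p=probs)
        gts: list[Genotype] = [cats[d] for d in draws]
        if spec.missing_rate > 0:
            miss = rng.random(n) < spec.missing_rate
            gts = [None if m else g for g, m in zip(gts, miss)]
        columns.append(gts)

    individuals = tuple(
        Individual(ids[i], sexes[i], spec.group, spec.population,
                   tuple(col[i] for col in columns))
        for i in range(n))
    return GenotypePanel(tuple(l.name for l in spec.loci), individuals)


# ---------------------------------------------------------------------------
# study-scale fixture
# ---------------------------------------------------------------------------

# 13 microsatellite loci, 7 tri-allelic + 6 bi-allelic = 33 alleles in total.
# Skewed frequencies plus a mild heterozygote deficit put the realized
# overall Ho in the depleted-broodstock band without making any allele so
# rare that it risks dropping out of a 48-fish sample.
_FIXTURE_LOCI = [
    ("Ca3",    (152, 158, 164), (0.55, 0.30, 0.15)),
    ("Ca4",    (131, 135, 139), (0.60, 0.25, 0.15)),
    ("Ca12",   (96, 100, 104),  (0.50, 0.35, 0.15)),
    ("Z9878",  (203, 207, 211), (0.55, 0.28, 0.17)),
    ("Z10362", (178, 182, 186), (0.58, 0.27, 0.15)),
    ("Z13419", (240, 244, 248), (0.52, 0.33, 0.15)),
    ("Eupe1",  (118, 122, 126), (0.56, 0.29, 0.15)),
    ("Eupe2",  (145, 149),      (0.85, 0.15)),
    ("Eupe4",  (167, 171),      (0.82, 0.18)),
    ("Eupe5",  (190, 194),      (0.86, 0.14)),
    ("Eupe6",  (210, 216),      (0.84, 0.16)),
    ("Eupe7",  (133, 137),      (0.83, 0.17)),
    ("Eupe9",  (156, 162),      (0.85, 0.15)),
]
_FIXTURE_F_IS = 0.10
_FIXTURE_HO_BAND = (0.30, 0.46)
_FIXTURE_TOTAL_ALLELES = 33


def study_scale_fixture(seed: int = 0) -> GenotypePanel:
    """A broodstock panel at the study's scale: 48 fish, 13 loci, 33 alleles.

    23 males and 25 females are simulated from the fixed locus inventory
    above and resampled (deterministically from *seed*) until every allele
    is realized in at least one individual and the overall observed
    heterozygosity falls in the low-diversity band 0.30-0.46.
    """
    loci = tuple(LocusSpec(name, codes, freqs, _FIXTURE_F_IS)
                 for name, codes, freqs in _FIXTURE_LOCI)
    lo, hi = _FIXTURE_HO_BAND
    for attempt in range(1000):
        sub_seed = (int(seed) * 100_003 + attempt * 7919 + 17) % (2 ** 31)
        spec = PanelSpec(n_males=23, n_females=25, loci=loci,
                         missing_rate=0.0, seed=sub_seed,
                         population="study-scale", group="SYN")
        panel = simulate_panel(spec)
        _, ar_total = allele_counts(panel)
        if ar_total != _FIXTURE_TOTAL_ALLELES:
            continue
        ho = summarize(panel).Ho
        if lo <= ho <= hi:
            return panel
    raise RuntimeError("could not realize the study-scale fixture")  # pragma: no cover




def frequency_recovery_check(panel: GenotypePanel, spec: PanelSpec
                             ) -> dict[str, float]:
    """Max absolute deviation of empirical from specified allele frequencies."""
    if tuple(panel.locus_names) != tuple(l.name for l in spec.loci):
        raise UsageError("panel loci do not match the spec")
    out: dict[str, float] = {}
    for locus_spec in spec.loci:
        counts = {a: 0 for a in locus_spec.allele_codes}
        total = 0
        for gt in panel.genotypes_at(locus_spec.name):
            if gt is None:
                continue
            for a in gt:
                counts[a] = counts.get(a, 0) + 1
                total += 1
        if total == 0:
            out[locus_spec.name] = float("nan")
            continue
        out[locus_spec.name] = max(
            abs(counts.get(a, 0) / total - p)
            for a, p in zip(locus_spec.allele_codes, locus_spec.frequencies))
    return out


def load_panel_spec(path) -> PanelSpec:
    """Read a PanelSpec from a YAML document.

    Layout::

        n_males: 10
        n_females: 10
        missing_rate: 0.0
        seed: 1
        loci:
          - {name: LocA, alleles: [152, 158], frequencies: [0.7, 0.3], f_is: 0.0}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        loci = tuple(
            LocusSpec(str(l["name"]), tuple(l["alleles"]),
                      tuple(l["frequencies"]), float(l.get("f_is", 0.0)))
            for l in doc["loci"])
        return PanelSpec(
            n_males=int(doc["n_males"]),
            n_females=int(doc["n_females"]),
            loci=loci,
            missing_rate=float(doc.get("missing_rate", 0.0)),
            seed=int(doc.get("seed", 0)),
            population=str(doc.get("population", "sim")),
            group=str(doc.get("group", "SIM")),
        )
    except KeyError as e:
        raise ValidationError(f"panel spec is missing field {e}") from None
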