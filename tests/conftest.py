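import numpy as np
import pytest

from broodmate import (GenotypePanel, Individual, LocusSpec, PanelSpec,
                       genotype, simulate_panel, study_scale_fixture)


def make_panel(locus_names, rows):
    """Build a panel from (id, sex, [(a1, a2), ...]) tuples; (0, 0) = missing."""
    individuals = []
    for id_, sex, gts in rows:
        individuals.append(Individual(
            id_, sex, "G", "pop",
            tuple(genotype(a, b) for a, b in gts)))
    return GenotypePanel(tuple(locus_names), tuple(individuals))


def random_spec(rng, n_males, n_females, n_loci, max_alleles=4,
                missing_rate=0.0, f_is=0.0):
    """A random PanelSpec for property tests, reproducible from rng."""
    loci = []
    for k in range(n_loci):
        n_all = int(rng.integers(1, max_alleles + 1))
        codes = tuple(int(c) for c in
                      sorted(rng.choice(np.arange(100, 260, 4), size=n_all,
                                        replace=False)))
        freqs = rng.dirichlet(np.ones(n_all))
        freqs = tuple(float(x) for x in freqs / freqs.sum())
        loci.append(LocusSpec(f"L{k + 1}", codes, freqs, f_is))
    return PanelSpec(n_males=n_males, n_females=n_females, loci=tuple(loci),
                     missing_rate=missing_rate,
                     seed=int(rng.integers(0, 2 ** 31)))


def random_panel(rng, n_males, n_females, n_loci, **kw):
    return simulate_panel(random_spec(rng, n_males, n_females, n_loci, **kw))


@pytest.fixture(scope="session")
def study_panel():
    """One realization of the 48-fish study-scale broodstock fixture."""
    return study_scale_fixture(seed=7)


@pytest.fixture
def tiny_panel():
    """2 males, 2 females, 2 loci, hand-written genotypes."""
    return make_panel(
        ["LocA", "LocB"],
        [
            ("M1", "male", [(152, 152), (200, 204)]),
            ("M2", "male", [(152, 158), (200, 200)]),
            ("F1", "female", [(158, 158), (204, 204)]),
            ("F2", "female", [(152, 158), (0, 0)]),
        ],
    )
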