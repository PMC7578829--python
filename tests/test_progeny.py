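"""Mendelian progeny predictions for pairs and group-spawning sets."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from broodmate import (UndefinedStatisticError, UsageError, genotype,
                       is_weak_pattern, pair_allele_count,
                       pair_expected_heterozygosity,
                       pair_locus_offspring_distribution, pair_weak_het_share,
                       predict_group, predict_pair)
from conftest import make_panel, random_panel

# the seven genotype shape classes a sire x dam locus can take
SHAPE_CLASSES = {
    "AAxAA": ((1, 1), (1, 1)),
    "AAxAB": ((1, 1), (1, 2)),
    "AAxBB": ((1, 1), (2, 2)),
    "AAxBC": ((1, 1), (2, 3)),
    "ABxAB": ((1, 2), (1, 2)),
    "ABxAC": ((1, 2), (1, 3)),
    "ABxCD": ((1, 2), (3, 4)),
}


class TestOffspringDistribution:
    def test_homozygous_cross_single_outcome(self):
        d = pair_locus_offspring_distribution((1, 1), (2, 2))
        assert d == [(1, 2)] * 4

    def test_punnett_square(self):
        d = pair_locus_offspring_distribution((1, 2), (1, 2))
        assert Counter(d) == Counter({(1, 1): 1, (1, 2): 2, (2, 2): 1})

    def test_four_distinct_heterozygotes(self):
        d = pair_locus_offspring_distribution((1, 2), (3, 4))
        assert len(set(d)) == 4
        assert all(a != b for a, b in d)

    def test_missing_parent_raises(self):
        with pytest.raises(UndefinedStatisticError):
            pair_locus_offspring_distribution(None, (1, 2))


class TestClosedFormsAgainstEnumeration:
    """Closed-form pair statistics must equal the 4-outcome oracle exactly."""

    @pytest.mark.parametrize("name", SHAPE_CLASSES)
    def test_heterozygosity(self, name):
        gm, gf = SHAPE_CLASSES[name]
        outcomes = pair_locus_offspring_distribution(gm, gf)
        oracle = sum(a != b for a, b in outcomes) / 4
        assert pair_expected_heterozygosity(gm, gf) == oracle
        assert pair_expected_heterozygosity(gm, gf) in (0, .25, .5, .75, 1)

    @pytest.mark.parametrize("name", SHAPE_CLASSES)
    def test_allele_count(self, name):
        gm, gf = SHAPE_CLASSES[name]
        oracle = len({a for gt in (gm, gf) for a in gt})
        assert pair_allele_count(gm, gf) == oracle
        assert 1 <= oracle <= 4

    @pytest.mark.parametrize("name,weak", [
        ("AAxAA", False), ("AAxAB", True), ("AAxBB", False),
        ("AAxBC", False), ("ABxAB", False), ("ABxAC", False),
        ("ABxCD", False)])
    def test_weak_pattern_is_exactly_three_to_one(self, name, weak):
        gm, gf = SHAPE_CLASSES[name]
        assert is_weak_pattern(gm, gf) is weak
        # oracle: two distinct alleles with copy counts {3, 1}
        counts = sorted(Counter(list(gm) + list(gf)).values())
        assert (counts == [1, 3]) is weak

    def test_spot_values(self):
        assert pair_expected_heterozygosity((1, 1), (1, 1)) == 0.0
        assert pair_expected_heterozygosity((1, 2), (3, 4)) == 1.0
        assert pair_expected_heterozygosity((1, 1), (1, 2)) == 0.5
        assert pair_allele_count((1, 1), (1, 2)) == 2


allele = st.integers(min_value=1, max_value=400)
called_genotype = st.tuples(allele, allele).map(lambda t: tuple(sorted(t)))


class TestClosedFormProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(gm=called_genotype, gf=called_genotype)
    def test_closed_forms_equal_enumeration_for_any_alleles(self, gm, gf):
        outcomes = pair_locus_offspring_distribution(gm, gf)
        assert pair_expected_heterozygosity(gm, gf) == \
            sum(a != b for a, b in outcomes) / 4
        assert pair_allele_count(gm, gf) == len(set(gm) | set(gf))
        assert is_weak_pattern(gm, gf) == \
            (sorted(Counter(gm + gf).values()) == [1, 3])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(gm=called_genotype, gf=called_genotype)
    def test_statistics_invariant_to_allele_order_and_parent_swap(self, gm,
                                                                  gf):
        rev_m, rev_f = (gm[1], gm[0]), (gf[1], gf[0])
        assert pair_expected_heterozygosity(rev_m, rev_f) == \
            pair_expected_heterozygosity(gm, gf)
        assert pair_expected_heterozygosity(gf, gm) == \
            pair_expected_heterozygosity(gm, gf)
        assert pair_allele_count(gf, gm) == pair_allele_count(gm, gf)
        assert is_weak_pattern(gf, gm) == is_weak_pattern(gm, gf)


class TestWeakHetShare:
    def test_all_identical_homozygotes(self):
        panel = make_panel(["L1", "L2"],
                           [("M1", "male", [(1, 1), (1, 1)]),
                            ("F1", "female", [(1, 1), (1, 1)])])
        assert pair_weak_het_share(panel.individual("M1"),
                                   panel.individual("F1")) == 0.0

    def test_single_weak_locus(self):
        panel = make_panel(["L"], [("M1", "male", [(1, 1)]),
                                   ("F1", "female", [(1, 2)])])
        assert pair_weak_het_share(panel.individual("M1"),
                                   panel.individual("F1")) == 0.5

    def test_two_two_pattern_is_not_weak(self):
        panel = make_panel(["L"], [("M1", "male", [(1, 2)]),
                                   ("F1", "female", [(1, 2)])])
        assert pair_weak_het_share(panel.individual("M1"),
                                   panel.individual("F1")) == 0.0

    def test_no_evaluable_locus(self):
        panel = make_panel(["L"], [("M1", "male", [(0, 0)]),
                                   ("F1", "female", [(1, 2)])])
        with pytest.raises(UndefinedStatisticError):
            pair_weak_het_share(panel.individual("M1"),
                                panel.individual("F1"))


class TestPredictPair:
    def test_identical_homozygous_profiles(self):
        panel = make_panel(["L1", "L2", "L3"],
                           [("M1", "male", [(1, 1), (2, 2), (3, 3)]),
                            ("F1", "female", [(1, 1), (2, 2), (3, 3)])])
        p = predict_pair(panel, "M1", "F1")
        assert p.H_mean == 0.0
        assert p.ar_total == 3  # one allele per locus

    def test_all_distinct_everywhere(self):
        loci = [f"L{k}" for k in range(13)]
        panel = make_panel(loci, [("M1", "male", [(1, 2)] * 13),
                                  ("F1", "female", [(3, 4)] * 13)])
        p = predict_pair(panel, "M1", "F1")
        assert p.ar_total == 52
        assert p.H_mean == 1.0

    def test_missing_locus_excluded_from_aggregates(self):
        panel = make_panel(["L1", "L2"],
                           [("M1", "male", [(1, 2), (0, 0)]),
                            ("F1", "female", [(3, 4), (5, 6)])])
        p = predict_pair(panel, "M1", "F1")
        assert p.n_evaluable == 1
        assert p.per_locus["L2"] is None
        assert p.H_mean == 1.0
        assert p.ar_total == 4

    def test_same_sex_pairing_rejected(self, tiny_panel):
        with pytest.raises(UsageError):
            predict_pair(tiny_panel, "M1", "M2")
        with pytest.raises(UsageError):
            predict_pair(tiny_panel, "F1", "M1")

    def test_unknown_id(self, tiny_panel):
        with pytest.raises(UsageError, match="unknown"):
            predict_pair(tiny_panel, "M1", "ghost")

    @pytest.mark.parametrize("seed", range(6))
    def test_aggregates_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, 2, 2, 6)
        male = panel.males()[0]
        female = panel.females()[0]
        p = predict_pair(panel, male.id, female.id)
        hs, ars = [], []
        for gm, gf in zip(male.genotypes, female.genotypes):
            outcomes = pair_locus_offspring_distribution(gm, gf)
            hs.append(sum(a != b for a, b in outcomes) / 4)
            ars.append(len({a for gt in (gm, gf) for a in gt}))
        assert p.H_mean == pytest.approx(sum(hs) / len(hs))
        assert p.ar_total == sum(ars)
        assert p.ar_total <= 4 * panel.n_loci


class TestPredictGroup:
    @pytest.mark.parametrize("seed", range(6))
    def test_singleton_group_reduces_to_pair(self, seed):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, 3, 3, 5)
        male = panel.males()[0]
        female = panel.females()[0]
        pair = predict_pair(panel, male.id, female.id)
        group = predict_group(panel, [male.id], [female.id])
        assert group.H_mean == pytest.approx(pair.H_mean)
        assert group.ar_total == pair.ar_total
        assert group.wh_share == pytest.approx(pair.wh_share)

    def test_fixed_cross_block(self):
        panel = make_panel(["L"], [("M1", "male", [(1, 1)]),
                                   ("M2", "male", [(1, 1)]),
                                   ("F1", "female", [(2, 2)]),
                                   ("F2", "female", [(2, 2)])])
        g = predict_group(panel, ["M1", "M2"], ["F1", "F2"])
        assert g.per_locus["L"].H_exp == 1.0
        assert g.per_locus["L"].alleles_transmitted == 2

    def test_usage_errors(self, tiny_panel):
        with pytest.raises(UsageError):
            predict_group(tiny_panel, [], ["F1"])
        with pytest.raises(UsageError):
            predict_group(tiny_panel, ["M1"], ["M2"])  # male listed as female
        with pytest.raises(UsageError):
            predict_group(tiny_panel, ["M1", "M1"], ["F1"])

    @pytest.mark.parametrize("seed", [3, 17])
    def test_matches_monte_carlo_offspring_simulation(self, seed):
        """Equal-contribution H_exp vs >=1e5 simulated offspring draws."""
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, 3, 4, 4)
        male_ids = [m.id for m in panel.males()]
        female_ids = [f.id for f in panel.females()]
        g = predict_group(panel, male_ids, female_ids)

        n_draws = 100_000
        sim = np.random.default_rng(seed + 1)
        for k, locus in enumerate(panel.locus_names):
            m_gts = [panel.individual(i).genotypes[k] for i in male_ids]
            f_gts = [panel.individual(i).genotypes[k] for i in female_ids]
            m_gts = [g_ for g_ in m_gts if g_ is not None]
            f_gts = [g_ for g_ in f_gts if g_ is not None]
            if not m_gts or not f_gts:
                continue
            sires = sim.integers(0, len(m_gts), n_draws)
            dams = sim.integers(0, len(f_gts), n_draws)
            ma = np.array(m_gts)[sires, sim.integers(0, 2, n_draws)]
            fa = np.array(f_gts)[dams, sim.integers(0, 2, n_draws)]
            het = float(np.mean(ma != fa))
            h = g.per_locus[locus].H_exp
            se = max((h * (1 - h) / n_draws) ** 0.5, 1e-4)
            assert abs(het - h) < 3 * se

    @pytest.mark.parametrize("seed", range(4))
    def test_adding_parent_never_decreases_transmitted_alleles(self, seed):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, 4, 4, 4)
        males = [m.id for m in panel.males()]
        females = [f.id for f in panel.females()]
        base = predict_group(panel, males[:2], females[:2])
        for extra in males[2:]:
            grown = predict_group(panel, males[:2] + [extra], females[:2])
            for locus in panel.locus_names:
                assert (grown.per_locus[locus].alleles_transmitted
                        >= base.per_locus[locus].alleles_transmitted)
        for extra in females[2:]:
            grown = predict_group(panel, males[:2], females[:2] + [extra])
            for locus in panel.locus_names:
                assert (grown.per_locus[locus].alleles_transmitted
                        >= base.per_locus[locus].alleles_transmitted)
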