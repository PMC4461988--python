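"""Mating oracle: enumeration exactness, pedigree match rates, equilibrium."""

import numpy as np
import pytest

from csdpop.mating import (
    SexGenotype,
    enumerate_mating_table,
    offspring_distribution,
    simulate_generations,
    simulate_matings,
)
from csdpop.model import CSDModelSpec, dmp_2l, dmp_sl, fis_from_sibmating


class TestEnumeration:
    def test_probabilities_sum_to_one(self):
        for spec in (
            CSDModelSpec(n_sex_loci=1, k=7, alpha=0.3),
            CSDModelSpec(n_sex_loci=2, k=5, l=9, alpha=0.7),
        ):
            assert enumerate_mating_table(spec).total_probability() == pytest.approx(
                1.0, abs=1e-12
            )

    def test_k2_random_all_matched(self):
        t = enumerate_mating_table(CSDModelSpec(n_sex_loci=1, k=2, alpha=0.0))
        assert t.matched_probability() == pytest.approx(1.0)
        assert t.expected_dmp() == pytest.approx(0.5)

    def test_theta_two_over_k(self):
        t = enumerate_mating_table(CSDModelSpec(n_sex_loci=1, k=10, alpha=0.0))
        assert t.matched_probability() == pytest.approx(0.2)

    def test_two_locus_expected_dmp(self):
        t = enumerate_mating_table(CSDModelSpec(n_sex_loci=2, k=9, l=9, alpha=0.081))
        assert t.expected_dmp() == pytest.approx(0.019446, abs=1e-6)

    def test_matched_rows_are_the_productive_rows(self):
        t = enumerate_mating_table(CSDModelSpec(n_sex_loci=2, k=6, l=4, alpha=0.4))
        for row in t.rows:
            if row.dm_fraction > 0:
                assert all(row.match_pattern)
            assert row.dm_fraction in (0.0, 0.25, 0.5)

    @pytest.mark.parametrize("alpha", [0.0, 0.081, 0.5, 1.0])
    def test_oracle_equals_closed_forms(self, alpha):
        """Enumeration must reproduce the closed forms to machine precision."""
        for k in range(2, 31):
            sl = enumerate_mating_table(CSDModelSpec(n_sex_loci=1, k=k, alpha=alpha))
            assert sl.expected_dmp() == pytest.approx(dmp_sl(alpha, k), abs=1e-12)
            tl = enumerate_mating_table(
                CSDModelSpec(n_sex_loci=2, k=k, l=k, alpha=alpha)
            )
            assert tl.expected_dmp() == pytest.approx(dmp_2l(alpha, k, k), abs=1e-12)


class TestOffspringDistribution:
    def test_matched_sl_mating_half_diploid_males(self):
        d = offspring_distribution(((1, 2),), (1,), fertilization_prob=1.0)
        assert d["diploid_male"] == pytest.approx(0.5)
        assert d["diploid_female"] == pytest.approx(0.5)

    def test_double_het_matched_both_loci_quarter(self):
        d = offspring_distribution(((1, 2), (3, 4)), (1, 3), fertilization_prob=1.0)
        assert d["diploid_male"] == pytest.approx(0.25)

    def test_no_fertilization_all_haploid(self):
        d = offspring_distribution(((1, 2),), (5,), fertilization_prob=0.0)
        assert d["haploid_male"] == 1.0

    def test_distribution_sums_to_one(self):
        d = offspring_distribution(((1, 2), (3, 3)), (2, 3), fertilization_prob=0.7)
        assert sum(d.values()) == pytest.approx(1.0)

    def test_allele_label_validation(self):
        with pytest.raises(ValueError):
            offspring_distribution(((0, 2),), (1,))

    def test_sex_genotype_rejects_all_hom_female(self):
        with pytest.raises(ValueError):
            SexGenotype(female_alleles=((1, 1), (2, 2)), male_alleles=(1, 2))


class TestMonteCarloMatings:
    def test_sib_matched_half_under_sl(self):
        """Half of sibmatings with het mothers and unmatched fathers are matched."""
        r = simulate_matings(
            CSDModelSpec(n_sex_loci=1, k=10, alpha=1.0),
            n=100_000,
            mode="pedigree",
            seed=11,
            mother_class="het",
            father_matched=False,
        )
        se = np.sqrt(0.25 / r.n_matings)
        assert abs(r.sib_matched_freq - 0.5) < 3 * se

    def test_sib_matched_quarter_double_het(self):
        r = simulate_matings(
            CSDModelSpec(n_sex_loci=2, k=9, l=9, alpha=1.0),
            n=100_000,
            mode="pedigree",
            seed=12,
            mother_class="het-both",
            father_matched=False,
        )
        se = np.sqrt(0.25 * 0.75 / r.n_matings)
        assert abs(r.sib_matched_freq - 0.25) < 3 * se

    def test_hom_daughter_match_rate_depends_on_origin(self):
        """Daughters homozygous at locus 1 are matched by brothers at 1/4
        when the homozygosity came from a heterozygous mother plus a matched
        father, but at 1/2 when the mother herself was homozygous — the
        closed form assumes 1/2 for all homozygous females, and the pedigree
        simulator reports the deviation rather than correcting it."""
        common = dict(n=100_000, mode="pedigree", seed=13, daughter_class="hom1",
                      father_matched=(True, False))
        via_het_mother = simulate_matings(
            CSDModelSpec(n_sex_loci=2, k=9, l=9, alpha=1.0),
            mother_class="het-both", **common,
        )
        via_hom_mother = simulate_matings(
            CSDModelSpec(n_sex_loci=2, k=9, l=9, alpha=1.0),
            mother_class="hom1", **common,
        )
        se = np.sqrt(0.25 / 100_000)
        assert abs(via_het_mother.sib_matched_freq - 0.25) < 4 * se
        assert abs(via_hom_mother.sib_matched_freq - 0.5) < 4 * se

    def test_random_mating_limit(self):
        r = simulate_matings(
            CSDModelSpec(n_sex_loci=1, k=50, alpha=0.0),
            n=100_000,
            mode="conditional",
            seed=14,
        )
        se = np.sqrt((1 / 50) * (1 - 1 / 50) / r.n_matings)
        assert abs(r.dmp - 1 / 50) < 3 * se

    def test_seed_reproducibility(self):
        a = simulate_matings(
            CSDModelSpec(n_sex_loci=2, k=9, l=9, alpha=0.3), n=5000, seed=7
        )
        b = simulate_matings(
            CSDModelSpec(n_sex_loci=2, k=9, l=9, alpha=0.3), n=5000, seed=7
        )
        assert a == b

    def test_seed_required(self):
        with pytest.raises(ValueError):
            simulate_matings(CSDModelSpec(n_sex_loci=1, k=5), n=10)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            simulate_matings(CSDModelSpec(n_sex_loci=1, k=5), n=10, mode="x", seed=1)

    def test_convergence_to_enumeration(self):
        """MC estimates approach the enumeration expectation at 1/sqrt(n)."""
        spec = CSDModelSpec(n_sex_loci=2, k=9, l=9, alpha=0.3)
        expected = enumerate_mating_table(spec).expected_dmp()
        r = simulate_matings(spec, n=200_000, mode="conditional", seed=21)
        assert abs(r.dmp - expected) < 5 / np.sqrt(r.n_matings)


class TestGenerations:
    def test_fis_near_zero_without_sibmating(self):
        s = simulate_generations(
            CSDModelSpec(n_sex_loci=2, k=20, l=20, alpha=0.0),
            n_females=300,
            n_generations=8,
            n_neutral_loci=60,
            seed=31,
        )
        assert abs(np.mean(s.fis[-4:])) < 0.02

    def test_fis_equilibrium_under_sibmating(self):
        vals = [
            np.mean(
                simulate_generations(
                    CSDModelSpec(n_sex_loci=2, k=20, l=20, alpha=0.081),
                    n_females=500,
                    n_generations=10,
                    n_neutral_loci=100,
                    seed=seed,
                ).fis[-5:]
            )
            for seed in range(10)
        ]
        target = fis_from_sibmating(0.081)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - target) < 3 * se + 1e-3

    def test_series_lengths_and_allele_counts(self):
        s = simulate_generations(
            CSDModelSpec(n_sex_loci=1, k=2, alpha=0.0),
            n_females=100,
            n_generations=5,
            n_neutral_loci=20,
            seed=32,
        )
        assert len(s.fis) == len(s.dmp) == len(s.sex_allele_counts) == 5
        # with k=2 both alleles persist or the run flags extinction
        assert s.extinct or all(c[0] in (1, 2) for c in s.sex_allele_counts)

    def test_k2_dmp_near_half_matched_rate(self):
        s = simulate_generations(
            CSDModelSpec(n_sex_loci=1, k=2, alpha=0.0),
            n_females=400,
            n_generations=6,
            n_neutral_loci=10,
            seed=33,
        )
        if not s.extinct:
            # every mating is matched when k=2, so half of diploid eggs are male
            assert np.mean(s.dmp) == pytest.approx(0.5, abs=0.05)

    def test_seed_required(self):
        with pytest.raises(ValueError):
            simulate_generations(CSDModelSpec(n_sex_loci=1, k=5), n_females=50)
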