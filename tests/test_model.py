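"""Closed-form CSD load model: worked values, inverses, and shape properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csdpop.model import (
    CSDModelSpec,
    consistent_allele_range,
    dmp_2l,
    dmp_band,
    dmp_sl,
    female_class_freqs,
    fis_from_sibmating,
    matched_mating_freqs,
    min_alleles_required,
    sibmating_from_fis,
)


class TestSibmatingFromFis:
    @pytest.mark.parametrize(
        "fis,expected",
        [
            (0.0, 0.0),
            (1.0, 1.0),
            (0.021, 0.084 / 1.063),
            (0.042, 0.168 / 1.126),
        ],
    )
    def test_values(self, fis, expected):
        assert sibmating_from_fis(fis) == pytest.approx(expected, abs=1e-12)

    def test_negative_fis_floors_at_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert sibmating_from_fis(-0.05) == 0.0
        assert "floored" in caplog.text

    @pytest.mark.parametrize("fis", [-1.0, -1 / 3, 1.5])
    def test_domain_errors(self, fis):
        with pytest.raises(ValueError):
            sibmating_from_fis(fis)

    def test_roundtrip_identity(self):
        for alpha in np.linspace(0, 1, 21):
            assert sibmating_from_fis(fis_from_sibmating(alpha)) == pytest.approx(
                alpha, abs=1e-12
            )

    def test_inverse_value(self):
        assert fis_from_sibmating(0.081) == pytest.approx(0.081 / 3.757, abs=1e-5)


class TestFemaleClassFreqs:
    def test_nine_alleles(self):
        f = female_class_freqs(9, 9)
        assert f.f_het_both == pytest.approx(0.8, abs=1e-12)
        assert f.f_hom_locus1 == pytest.approx(0.1, abs=1e-12)

    def test_two_alleles(self):
        assert female_class_freqs(2, 2).f_het_both == pytest.approx(1 / 3, abs=1e-12)

    def test_large_k_limit(self):
        assert female_class_freqs(10_000, 10_000).f_het_both == pytest.approx(
            1.0, abs=1e-3
        )

    def test_classes_sum_to_one(self):
        for k in (2, 3, 9, 50):
            f = female_class_freqs(k, k + 1)
            assert f.f_het_both + f.f_hom_locus1 + f.f_hom_locus2 == pytest.approx(
                1.0, abs=1e-12
            )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            female_class_freqs(1, 9)


class TestMatchedMatingFreqs:
    def test_single_locus_theta(self):
        m = matched_mating_freqs(CSDModelSpec(n_sex_loci=1, k=10))
        assert m.theta == pytest.approx(0.2, abs=1e-12)
        assert m.p_hom == 0.0

    def test_two_alleles_every_male_matches(self):
        assert matched_mating_freqs(CSDModelSpec(n_sex_loci=1, k=2)).theta == 1.0

    def test_two_locus_components(self):
        m = matched_mating_freqs(CSDModelSpec(n_sex_loci=2, k=9, l=9))
        assert m.p_het == pytest.approx(0.039506, abs=1e-6)
        assert m.p_hom == pytest.approx(0.0049383, abs=1e-7)
        assert m.theta == pytest.approx(m.p_het + m.p_hom, abs=1e-12)


class TestDMP:
    def test_sl_headline(self):
        # 8.1% sibmating with 100 sex alleles still leaves ~3% diploid males
        assert dmp_sl(0.081, 100) == pytest.approx(0.02944, abs=1e-5)
        assert round(dmp_sl(0.081, 100), 2) == 0.03

    def test_sl_limits(self):
        assert dmp_sl(0.0, 2) == pytest.approx(0.5)
        for k in (2, 5, 100):
            assert dmp_sl(1.0, k) == pytest.approx(0.25)

    def test_2l_values(self):
        assert dmp_2l(0.081, 9, 9) == pytest.approx(0.019446, abs=1e-6)
        assert dmp_2l(0.081, 20, 20) == pytest.approx(0.008807, abs=1e-6)

    def test_2l_vanishes_outbred_high_diversity(self):
        assert dmp_2l(0.0, 500, 500) < 1e-4

    def test_survival_adjustment(self):
        # s = 1 is the identity; s = 0 removes diploid males entirely
        assert dmp_sl(0.1, 10, dm_survival=1.0) == pytest.approx(0.115)
        assert dmp_sl(0.1, 10, dm_survival=0.0) == 0.0
        m = 0.115
        s = 0.5
        assert dmp_sl(0.1, 10, dm_survival=s) == pytest.approx(
            s * m / (s * m + 1 - m)
        )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        alpha=st.floats(0, 1),
        k=st.integers(2, 30),
        l=st.integers(2, 30),
    )
    def test_second_locus_never_increases_load(self, alpha, k, l):
        assert dmp_2l(alpha, k, l) <= dmp_sl(alpha, min(k, l)) + 1e-12

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(alpha=st.floats(0, 1), k=st.integers(2, 99))
    def test_monotone_in_k(self, alpha, k):
        assert dmp_sl(alpha, k + 1) <= dmp_sl(alpha, k) + 1e-12
        assert dmp_2l(alpha, k + 1, k + 1) <= dmp_2l(alpha, k, k) + 1e-12

    def test_affine_in_alpha(self):
        # endpoints of dmp_band must equal a dense-grid min/max
        for n_loci, k in [(1, 10), (2, 9), (1, 3), (2, 3)]:
            spec = CSDModelSpec(n_sex_loci=n_loci, k=k, l=k)
            band = dmp_band(0.0, 0.151, spec)
            grid = [
                dmp_sl(a, k) if n_loci == 1 else dmp_2l(a, k, k)
                for a in np.linspace(0, 0.151, 201)
            ]
            assert band.band_low == pytest.approx(min(grid), abs=1e-12)
            assert band.band_high == pytest.approx(max(grid), abs=1e-12)


class TestBandsAndInverseQueries:
    def test_degenerate_band(self):
        spec = CSDModelSpec(n_sex_loci=1, k=10, alpha=0.2)
        band = dmp_band(0.2, 0.2, spec)
        assert band.band_low == band.band_high == pytest.approx(dmp_sl(0.2, 10))

    def test_sl_band_endpoints(self):
        # endpoints are direct evaluations: 1/100 and 0.25*0.151 + 0.849/100
        band = dmp_band(0.0, 0.151, CSDModelSpec(n_sex_loci=1, k=100))
        assert band.band_low == pytest.approx(0.01, abs=1e-12)
        assert band.band_high == pytest.approx(0.04624, abs=1e-12)

    def test_band_order_error(self):
        with pytest.raises(ValueError):
            dmp_band(0.5, 0.1, CSDModelSpec(n_sex_loci=1, k=10))

    def test_consistent_range_is_nine_to_twenty(self):
        ks = consistent_allele_range(
            0.014, 0.0, 0.151, range(3, 101), CSDModelSpec(n_sex_loci=2, k=9, l=9)
        )
        assert ks == set(range(9, 21))

    def test_dmp_one_never_reached(self):
        assert (
            consistent_allele_range(
                1.0, 0.0, 0.151, range(3, 101), CSDModelSpec(n_sex_loci=2, k=9, l=9)
            )
            == set()
        )

    def test_band_endpoint_inclusive(self):
        spec = CSDModelSpec(n_sex_loci=1, k=10)
        band = dmp_band(0.0, 0.2, spec)
        ks = consistent_allele_range(
            band.band_low, 0.0, 0.2, [10], CSDModelSpec(n_sex_loci=1, k=10)
        )
        assert 10 in ks

    def test_empty_k_values(self):
        with pytest.raises(ValueError):
            consistent_allele_range(0.014, 0, 0.1, [], CSDModelSpec(n_sex_loci=1, k=9))

    def test_min_alleles_sl(self):
        # the sibmating term alone (0.25 * 0.081 = 0.02025) exceeds 1.4%
        assert min_alleles_required(0.014, 0.081, model=1, k_max=1000) is None
        assert min_alleles_required(0.014, 0.0, model=1, k_max=100) == 72
        assert min_alleles_required(0.5, 0.0, model=1, k_max=100) == 2
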