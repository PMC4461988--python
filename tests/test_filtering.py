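"""Multiple-testing correction, locus filtering, panel selection, Ti/Tv."""

import numpy as np
import pandas as pd
import pytest

from csdpop.filtering import (
    filter_loci,
    select_snp_panel,
    sequential_bonferroni,
    titv_ratio,
)
from csdpop.genotypes import GenotypeMatrix
from csdpop.synth import SyntheticSpec, gen_structured_genotypes


class TestSequentialBonferroni:
    def test_all_rejected(self):
        flags = sequential_bonferroni([0.001, 0.02, 0.03], alpha=0.05)
        assert flags.tolist() == [True, True, True]

    def test_none_rejected(self):
        flags = sequential_bonferroni([0.04, 0.04, 0.04], alpha=0.05)
        assert flags.tolist() == [False, False, False]

    def test_single_p(self):
        assert sequential_bonferroni([0.049], alpha=0.05).tolist() == [True]

    def test_stops_at_first_failure(self):
        # 0.001 < 0.05/3 but 0.03 > 0.05/2, so 0.04 is never examined
        flags = sequential_bonferroni([0.04, 0.001, 0.03], alpha=0.05)
        assert flags.tolist() == [False, True, False]

    def test_empty_and_invalid(self):
        assert sequential_bonferroni([]).size == 0
        with pytest.raises(ValueError):
            sequential_bonferroni([1.2])


def _ld_matrix(seed=0, n=60):
    """Three loci where L1 and L2 are copies (maximal LD), L3 independent."""
    rng = np.random.default_rng(seed)
    g1 = np.sort(rng.integers(1, 3, size=(n, 2)), axis=1)
    g3 = np.sort(rng.integers(1, 3, size=(n, 2)), axis=1)
    calls = np.stack([g1, g1, g3], axis=1).astype(np.int16)
    ids = [f"i{j}" for j in range(n)]
    return GenotypeMatrix(
        calls, ids, ["L1", "L2", "L3"],
        {i: "f" for i in ids}, {"f": "all"},
    )


class TestFilterLoci:
    def test_clean_data_all_retained(self):
        m = gen_structured_genotypes(
            SyntheticSpec(seed=9, n_loci=6, individuals_per_field=10,
                          target_fis=0.0, missing_rate=0.0)
        )
        res = filter_loci(m, seed=1, chain_steps=20_000, dememorization=2_000,
                          n_permutations=99)
        # well-behaved random-mating data should rarely lose loci; the
        # reports must agree with the retained list either way
        excluded = set(res.reports.loc[res.reports.excluded_reason != "none", "locus_id"])
        assert set(res.retained) == set(m.locus_ids) - excluded

    def test_duplicated_locus_pair_breaks_ld(self):
        m = _ld_matrix()
        res = filter_loci(m, seed=3, chain_steps=20_000, dememorization=2_000,
                          n_permutations=199)
        # exactly one of the duplicated pair is removed for LD
        removed = {r.locus_id for r in res.reports.itertuples() if r.excluded_reason == "ld"}
        assert len(removed & {"L1", "L2"}) == 1
        assert "L3" in res.retained

    def test_removal_reproducible_under_seed(self):
        m = _ld_matrix()
        kw = dict(chain_steps=10_000, dememorization=1_000, n_permutations=99)
        r1 = filter_loci(m, seed=11, **kw)
        r2 = filter_loci(m, seed=11, **kw)
        assert r1.retained == r2.retained

    def test_min_cover_removes_chain_hub(self):
        """For a chain A-B, B-C of significant pairs, min-cover removes only B."""
        rng = np.random.default_rng(1)  # both loci comfortably inside HWE
        g = np.sort(rng.integers(1, 3, size=(80, 2)), axis=1)
        g3 = np.sort(rng.integers(1, 3, size=(80, 2)), axis=1)
        # A == B == C: a significance triangle whose minimum cover has 2 loci
        calls = np.stack([g, g, g, g3], axis=1).astype(np.int16)
        ids = [f"i{j}" for j in range(80)]
        m = GenotypeMatrix(calls, ids, ["A", "B", "C", "D"],
                           {i: "f" for i in ids}, {"f": "all"})
        res = filter_loci(m, seed=7, chain_steps=10_000, dememorization=1_000,
                          n_permutations=199, removal="min-cover")
        removed = {r.locus_id for r in res.reports.itertuples() if r.excluded_reason == "ld"}
        # triangle A-B-C needs 2 removals (the brute-force minimum); D stays
        assert len(removed) == 2
        assert "D" in res.retained


def _toy_candidates():
    rows = [
        # scaffold, pos, alleles, maf, quality — bins fill in ascending
        # MAF order, ranked by quality, one SNP per scaffold overall
        ("s1", 100, ["A", "G"], 0.45, 900),   # bin 3 — scaffold taken by s1@5000
        ("s1", 5000, ["C", "T"], 0.35, 800),  # bin 2, 2nd best quality: selected
        ("s2", 200, ["A", "C"], 0.42, 700),   # bin 3, best available: selected
        ("s3", 300, ["A", "G"], 0.33, 950),   # bin 2, best quality: selected
        ("s4", 400, ["A", "G", "T"], 0.40, 999),  # tri-allelic: excluded
        ("s5", 500, ["C", "T"], 0.15, 990),   # below MAF floor: excluded
        ("s6", 600, ["A", "T"], 0.25, 500),   # bin 1: selected
        ("s7", 700, ["C", "G"], 0.28, 400),   # bin 1, second: selected
        ("s8", 800, ["A", "G"], 0.36, 300),   # bin 2, behind quota of 2
        ("s9", 900, ["A", "G"], 0.48, 100),   # bin 3, fills second slot
    ]
    return pd.DataFrame(
        rows, columns=["scaffold_id", "position", "alleles", "maf", "quality"]
    )


class TestPanelSelection:
    def test_hand_checked_selection(self):
        df = _toy_candidates()
        sel = select_snp_panel(df, bin_quotas=(2, 2, 2))
        picked = set(zip(sel["scaffold_id"], sel["position"]))
        assert picked == {
            ("s6", 600), ("s7", 700),    # bin (0.2, 0.3]
            ("s3", 300), ("s1", 5000),   # bin (0.3, 0.4]
            ("s2", 200), ("s9", 900),    # bin (0.4, 0.5]
        }

    def test_close_pair_both_excluded(self):
        df = pd.DataFrame(
            [
                ("s1", 100, ["A", "G"], 0.4, 900),
                ("s1", 130, ["C", "T"], 0.4, 800),
                ("s2", 500, ["A", "G"], 0.4, 500),
            ],
            columns=["scaffold_id", "position", "alleles", "maf", "quality"],
        )
        sel = select_snp_panel(df, bin_quotas=(3, 3, 3))
        assert list(sel["scaffold_id"]) == ["s2"]

    def test_one_snp_per_scaffold(self):
        sel = select_snp_panel(_toy_candidates(), bin_quotas=(5, 5, 5))
        assert sel["scaffold_id"].is_unique

    def test_quota_shortfall_warns(self, caplog):
        df = _toy_candidates()
        with caplog.at_level("WARNING"):
            select_snp_panel(df, bin_quotas=(20, 40, 40))
        assert "available" in caplog.text

    def test_malformed_table(self):
        with pytest.raises(ValueError):
            select_snp_panel(pd.DataFrame({"maf": [0.3]}))


class TestTiTv:
    def test_two_to_one(self):
        df = pd.DataFrame({"alleles": [["A", "G"], ["C", "T"], ["A", "C"]]})
        assert titv_ratio(df) == pytest.approx(2.0)

    def test_undefined_without_transversions(self):
        df = pd.DataFrame({"alleles": [["A", "G"], ["A", "G"]]})
        assert np.isnan(titv_ratio(df))

    def test_random_pairs_approach_half(self):
        rng = np.random.default_rng(1)
        pairs = [sorted(rng.choice(list("ACGT"), 2, replace=False)) for _ in range(4000)]
        df = pd.DataFrame({"alleles": pairs})
        assert titv_ratio(df) == pytest.approx(0.5, abs=0.06)

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            titv_ratio(pd.DataFrame({"alleles": [["1", "2"]]}))
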