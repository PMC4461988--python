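"""Synthetic-data generators for every pipeline input.

The default dimensions emulate the study system this package was built
around: ~139 diploid females from 8 fields nested in 4 regions, genotyped
at ~81 biallelic SNPs with minor allele frequency >= 0.2, weak population
structure (F_ST ~ 0.05), mild inbreeding (F_IS ~ 0.02) and ~2.5% missing
calls.  Structured allele frequencies follow the Balding–Nichols Beta
model; within-field genotypes add a homozygote excess of F_IS.  A separate
generator produces genotypes from an explicit haplodiploid sibmating
pedigree (via :func:`csdpop.mating.simulate_generations`) so the
F_IS-to-sibmating mapping can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmp import PloidyCounts
from .genotypes import MISSING, GenotypeMatrix
from .mating import CSDModelSpec, simulate_generations

__all__ = [
    "SyntheticSpec",
    "gen_structured_genotypes",
    "gen_sibmating_genotypes",
    "gen_snp_candidates",
    "gen_ploidy_counts",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Dimensions and targets of a synthetic genotype dataset."""

    n_regions: int = 4
    fields_per_region: int = 2
    individuals_per_field: int = 17
    n_loci: int = 81
    target_fst: float = 0.05
    target_fis: float = 0.02
    maf_floor: float = 0.2
    missing_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_regions", "fields_per_region", "individuals_per_field", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("target_fst", "target_fis", "maf_floor", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")


def _hierarchy(spec: SyntheticSpec) -> tuple[list[str], dict[str, str], dict[str, str]]:
    """Individual ids plus field and region maps for the spec's layout."""
    individual_ids: list[str] = []
    field_of: dict[str, str] = {}
    region_of: dict[str, str] = {}
    f = 0
    for r in range(spec.n_regions):
        region = f"region{r + 1}"
        for _ in range(spec.fields_per_region):
            f += 1
            fld = f"field{f}"
            region_of[fld] = region
            for i in range(spec.individuals_per_field):
                ind = f"{fld}_ind{i + 1}"
                individual_ids.append(ind)
                field_of[ind] = fld
    return individual_ids, field_of, region_of


def gen_structured_genotypes(spec: SyntheticSpec) -> GenotypeMatrix:
    """Structured diploid genotypes under the Balding–Nichols model.

    Ancestral allele frequencies are uniform on [maf_floor, 0.5]; each
    field's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with F the target
    F_ST (or the ancestral frequency itself when F = 0).  Within fields,
    genotypes have a homozygote excess of the target F_IS:
    P(hom ref) = p^2 + F_IS p(1-p).  Missing calls are dropped uniformly
    at the missing rate.  Alleles are coded 1 and 2.
    """
    rng = np.random.default_rng(spec.seed)
    ids, field_of, region_of = _hierarchy(spec)
    n_fields = spec.n_regions * spec.fields_per_region
    n_ind = len(ids)
    L = spec.n_loci

    p_anc = rng.uniform(spec.maf_floor, 0.5, size=L)
    if spec.target_fst > 0:
        F = spec.target_fst
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_field = rng.beta(a, b, size=(n_fields, L))
    else:
        p_field = np.tile(p_anc, (n_fields, 1))

    field_idx = np.repeat(np.arange(n_fields), spec.individuals_per_field)
    p = p_field[field_idx]  # (n_ind, L)
    fis = spec.target_fis
    p_hom1 = p**2 + fis * p * (1 - p)
    p_het = 2 * p * (1 - p) * (1 - fis)
    u = rng.random((n_ind, L))
    calls = np.empty((n_ind, L, 2), dtype=np.int16)
    hom1 = u < p_hom1
    het = (~hom1) & (u < p_hom1 + p_het)
    calls[:, :, 0] = np.where(hom1 | het, 1, 2)
    calls[:, :, 1] = np.where(hom1, 1, 2)

    miss = rng.random((n_ind, L)) < spec.missing_rate
    calls[miss] = MISSING

    locus_ids = [f"snp{j + 1}" for j in range(L)]
    return GenotypeMatrix(calls, ids, locus_ids, field_of, region_of)


def gen_sibmating_genotypes(
    alpha: float,
    generations: int = 10,
    spec: SyntheticSpec | None = None,
    n_females: int | None = None,
) -> tuple[GenotypeMatrix, "object"]:
    """Genotypes of females from an explicit haplodiploid sibmating pedigree.

    Runs the individual-based population simulator at sibmating rate
    ``alpha`` for ``generations`` generations and returns the final
    females' neutral-locus genotypes as a single-field matrix, together
    with the per-generation series (F_IS, DMP, sex-allele counts).
    Realized F_IS converges toward the equilibrium alpha/(4 - 3 alpha).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if generations < 5:
        raise ValueError(f"generations must be >= 5, got {generations}")
    spec = spec or SyntheticSpec()
    n = n_females or max(spec.n_regions * spec.fields_per_region * spec.individuals_per_field, 10)
    model = CSDModelSpec(n_sex_loci=2, k=20, l=20, alpha=alpha)
    series = simulate_generations(
        model,
        n_females=n,
        n_generations=generations,
        n_neutral_loci=spec.n_loci,
        seed=spec.seed,
        neutral_maf_low=spec.maf_floor,
    )
    if series.extinct:
        raise RuntimeError("pedigree population went extinct before sampling")
    genos = series.final_neutral_genotypes + 1  # code alleles 1/2
    ids = [f"ped_ind{i + 1}" for i in range(genos.shape[0])]
    matrix = GenotypeMatrix(
        calls=genos.astype(np.int16),
        individual_ids=ids,
        locus_ids=[f"snp{j + 1}" for j in range(genos.shape[1])],
        field_of={i: "pedigree" for i in ids},
        region_of={"pedigree": "pedigree"},
    )
    return matrix, series


def gen_snp_candidates(
    n: int,
    seed: int | None = None,
    n_scaffolds: int | None = None,
    tri_allelic_fraction: float = 0.05,
    close_pair_fraction: float = 0.05,
    titv: float = 2.18,
) -> pd.DataFrame:
    """Synthetic SNP candidate table for panel-selection testing.

    Candidates are placed on scaffolds with length-weighted density; MAF
    is uniform on (0, 0.5]; quality scores are lognormal around the
    typical range of variant callers; a controlled fraction of rows are
    tri-allelic and a controlled fraction form within-50-bp pairs.
    Biallelic allele pairs are drawn so transitions outnumber
    transversions ``titv``-fold.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    n_scaffolds = n_scaffolds or max(n // 5, 1)
    lengths = rng.integers(17_000, 58_000, size=n_scaffolds)
    scaffold_p = lengths / lengths.sum()

    transitions = [("A", "G"), ("C", "T")]
    transversions = [("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]
    p_ti = titv / (1 + titv)

    rows = []
    for i in range(n):
        s = int(rng.choice(n_scaffolds, p=scaffold_p))
        pos = int(rng.integers(1, lengths[s] + 1))
        if rng.random() < tri_allelic_fraction:
            alleles = list(rng.choice(list("ACGT"), size=3, replace=False))
        else:
            pool = transitions if rng.random() < p_ti else transversions
            alleles = list(pool[rng.integers(len(pool))])
        rows.append(
            {
                "scaffold_id": f"scaffold{s + 1}",
                "position": pos,
                "alleles": alleles,
                "maf": float(rng.uniform(0.0, 0.5)),
                "quality": float(rng.lognormal(5.5, 0.5)),
                "depth": int(rng.poisson(60)),
            }
        )
    df = pd.DataFrame(rows)
    # force a fraction of close pairs by duplicating positions nearby
    n_close = int(close_pair_fraction * n)
    for i in rng.choice(n, size=n_close, replace=False):
        j = int(rng.integers(n))
        df.loc[j, "scaffold_id"] = df.loc[i, "scaffold_id"]
        df.loc[j, "position"] = max(1, int(df.loc[i, "position"]) + int(rng.integers(-50, 51)))
    return df


def gen_ploidy_counts(
    n_fields: int = 8,
    true_dmp: float = 0.014,
    females_per_field: int = 185,
    assay_fraction: float = 2.0 / 3.0,
    seed: int | None = None,
) -> list[PloidyCounts]:
    """Synthetic per-field ploidy assay counts.

    Each field gets ``females_per_field`` females (Poisson-dispersed) and
    a male count matching a near-even sex ratio; diploid males arise
    binomially so that the expected diploid male proportion among diploids
    is ``true_dmp``; a fraction ``assay_fraction`` of males is assayed and
    ~2% of assays are inconclusive (unknown ploidy).
    """
    if not 0.0 <= true_dmp < 1.0:
        raise ValueError("true_dmp must be in [0, 1)")
    if not 0.0 < assay_fraction <= 1.0:
        raise ValueError("assay_fraction must be in (0, 1]")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    out = []
    for f in range(n_fields):
        n_fem = int(rng.poisson(females_per_field))
        # diploid males: among n_fem + x diploids, expect fraction true_dmp
        n_dm_total = int(rng.binomial(n_fem, true_dmp / (1 - true_dmp))) if true_dmp else 0
        n_hap_total = int(rng.poisson(n_fem))  # sex ratio ~ 0.5
        n_males = n_hap_total + n_dm_total
        assayed_dm = int(rng.binomial(n_dm_total, assay_fraction)) if n_dm_total else 0
        assayed_hap = int(rng.binomial(n_hap_total, assay_fraction)) if n_hap_total else 0
        n_assayed = assayed_dm + assayed_hap
        n_unknown = int(rng.binomial(n_assayed, 0.02)) if n_assayed else 0
        # unknowns taken proportionally from the haploid pool
        n_unknown = min(n_unknown, assayed_hap)
        out.append(
            PloidyCounts(
                field_id=f"field{f + 1}",
                n_males_assayed=n_assayed,
                n_haploid=assayed_hap - n_unknown,
                n_diploid_males=assayed_dm,
                n_unknown=n_unknown,
                n_females=n_fem,
            )
        )
    return out
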