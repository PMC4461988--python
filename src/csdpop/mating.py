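"""Exact enumeration and Monte-Carlo simulation of haplodiploid CSD matings.

This module is the brute-force counterpart of :mod:`csdpop.model`: it
enumerates the joint distribution of female genotype class and per-locus
match pattern, mixing sibmating and random mating, and its expected diploid
male proportion must agree with the closed forms to machine precision.  It
also provides stochastic simulators — a "conditional" mode that
samples mating classes at the model's stated conditional probabilities, a
"pedigree" mode that builds explicit two-generation families and measures
realized match rates, and a multi-generation population simulator used to
check the equilibrium relation between sibmating and F_IS.

Conventions: sex alleles are labelled 1..k (locus 1) and 1..l (locus 2);
males are haploid (one allele per locus); a diploid is male iff homozygous
at every sex locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CSDModelSpec, dmp, female_class_freqs

__all__ = [
    "SexGenotype",
    "MatingRow",
    "MatingTable",
    "MatingSimResult",
    "GenerationSeries",
    "enumerate_mating_table",
    "offspring_distribution",
    "simulate_matings",
    "simulate_generations",
]


@dataclass(frozen=True)
class SexGenotype:
    """Sex-locus genotypes of a mated pair.

    ``female_alleles``: per-locus unordered pairs, e.g. ((1, 2), (3, 3)).
    ``male_alleles``: per-locus single alleles, e.g. (1, 2).
    """

    female_alleles: tuple[tuple[int, int], ...]
    male_alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.female_alleles) != len(self.male_alleles):
            raise ValueError("female and male genotypes must span the same loci")
        if all(a == b for a, b in self.female_alleles):
            raise ValueError(
                "a diploid homozygous at every sex locus is male, not female"
            )


@dataclass(frozen=True)
class MatingRow:
    female_class: str  # 'het' (sl) or 'het-both'/'hom1'/'hom2' (2l)
    origin: str  # 'sib' or 'random'
    match_pattern: tuple[bool, ...]  # per-locus matched flag
    probability: float
    dm_fraction: float  # expected diploid males among diploid offspring


@dataclass
class MatingTable:
    """Exact joint distribution of mating classes with diploid-male yields."""

    spec: CSDModelSpec
    rows: list[MatingRow] = field(default_factory=list)

    def total_probability(self) -> float:
        return sum(r.probability for r in self.rows)

    def matched_probability(self) -> float:
        """Probability a mating is matched (can produce diploid males)."""
        return sum(r.probability for r in self.rows if r.dm_fraction > 0)

    def expected_dmp(self) -> float:
        """Expected diploid male proportion among diploids.

        Broods are assumed to contribute equal numbers of diploid offspring
        regardless of mating class, so the population DMP is the
        probability-weighted mean diploid-male fraction.
        """
        m = sum(r.probability * r.dm_fraction for r in self.rows)
        s = self.spec.dm_survival
        if s == 1.0:
            return m
        denom = s * m + (1.0 - m)
        return s * m / denom if denom > 0 else 0.0


@dataclass(frozen=True)
class MatingSimResult:
    n_matings: int
    matched_freq: float
    dmp: float
    sib_matched_freq: float
    seed: int


@dataclass
class GenerationSeries:
    """Per-generation output of the multi-generation population simulator."""

    fis: list[float]
    dmp: list[float]
    sex_allele_counts: list[tuple[int, ...]]
    extinct: bool = False
    final_neutral_genotypes: np.ndarray | None = None  # (n_females, L, 2) 0/1

    @property
    def n_generations(self) -> int:
        return len(self.fis)


def enumerate_mating_table(spec: CSDModelSpec) -> MatingTable:
    """Exact mating-class enumeration for a CSD model.

    The sibmating component uses the model's conditional match
    probabilities (1/2 for sl-CSD females and for females homozygous at one
    locus; 1/4 for double heterozygotes matched at both loci); the random
    component uses equal allele frequencies (2/alleles per heterozygous
    locus, 1/alleles per homozygous locus).
    """
    a = spec.alpha
    table = MatingTable(spec=spec)
    if spec.n_sex_loci == 1:
        k = spec.k
        table.rows = [
            MatingRow("het", "sib", (True,), a * 0.5, 0.5),
            MatingRow("het", "sib", (False,), a * 0.5, 0.0),
            MatingRow("het", "random", (True,), (1 - a) * (2.0 / k), 0.5),
            MatingRow("het", "random", (False,), (1 - a) * (1 - 2.0 / k), 0.0),
        ]
        return table

    k, l = spec.k, spec.l
    freqs = female_class_freqs(k, l)
    classes = {
        "het-both": (freqs.f_het_both, (2.0 / k, 2.0 / l), 0.25, 0.25),
        "hom1": (freqs.f_hom_locus1, (1.0 / k, 2.0 / l), 0.5, 0.5),
        "hom2": (freqs.f_hom_locus2, (2.0 / k, 1.0 / l), 0.5, 0.5),
    }
    rows: list[MatingRow] = []
    for name, (f_class, match_p, sib_match, dm_when_matched) in classes.items():
        # sibmating: matched means matched at every locus
        rows.append(
            MatingRow(name, "sib", (True, True), a * f_class * sib_match, dm_when_matched)
        )
        rows.append(
            MatingRow(name, "sib", (False, False), a * f_class * (1 - sib_match), 0.0)
        )
        # random mating: per-locus matches are independent
        for m1 in (True, False):
            for m2 in (True, False):
                p1 = match_p[0] if m1 else 1 - match_p[0]
                p2 = match_p[1] if m2 else 1 - match_p[1]
                dm = dm_when_matched if (m1 and m2) else 0.0
                rows.append(
                    MatingRow(name, "random", (m1, m2), (1 - a) * f_class * p1 * p2, dm)
                )
    table.rows = rows
    return table


def offspring_distribution(
    mother: tuple[tuple[int, int], ...] | SexGenotype,
    father: tuple[int, ...] | None = None,
    fertilization_prob: float = 1.0,
) -> dict[str, float]:
    """Offspring class probabilities for one mating.

    Unfertilized eggs (probability ``1 - fertilization_prob``) develop as
    haploid males; fertilized eggs are diploid and develop as males iff
    homozygous at every sex locus.  Returns probabilities for
    ``haploid_male``, ``diploid_male`` and ``diploid_female``.
    """
    if isinstance(mother, SexGenotype):
        father = mother.male_alleles
        mother = mother.female_alleles
    if father is None:
        raise ValueError("father alleles required")
    if len(mother) != len(father):
        raise ValueError("mother and father genotypes must span the same loci")
    if not 0.0 <= fertilization_prob <= 1.0:
        raise ValueError(f"fertilization_prob must be in [0, 1], got {fertilization_prob}")
    for (m1, m2), f in zip(mother, father):
        for allele in (m1, m2, f):
            if allele < 1:
                raise ValueError(f"allele labels must be >= 1, got {allele}")
    p_hom = 1.0
    for (m1, m2), f in zip(mother, father):
        p_hom *= ((m1 == f) + (m2 == f)) / 2.0
    return {
        "haploid_male": 1.0 - fertilization_prob,
        "diploid_male": fertilization_prob * p_hom,
        "diploid_female": fertilization_prob * (1.0 - p_hom),
    }


def _allele_numbers(spec: CSDModelSpec) -> tuple[int, ...]:
    return (spec.k,) if spec.n_sex_loci == 1 else (spec.k, spec.l)


def _draw_female_genotypes(
    spec: CSDModelSpec, n: int, rng: np.random.Generator,
    mother_class: str | None = None,
) -> np.ndarray:
    """Draw n viable female sex genotypes, shape (n, n_loci, 2).

    Genotypes follow random-mating proportions with equal allele
    frequencies, conditioned on viability (not homozygous at all loci);
    ``mother_class`` restricts the draw to one genotype class.
    """
    sizes = _allele_numbers(spec)
    n_loci = len(sizes)
    out = np.empty((n, n_loci, 2), dtype=np.int64)
    need = np.arange(n)
    while need.size:
        for j, size in enumerate(sizes):
            out[need, j, 0] = rng.integers(1, size + 1, size=need.size)
            out[need, j, 1] = rng.integers(1, size + 1, size=need.size)
        hom = out[need, :, 0] == out[need, :, 1]
        if mother_class is None or mother_class == "het":
            bad = hom.all(axis=1)
        elif mother_class == "het-both":
            bad = hom.any(axis=1)
        elif mother_class == "hom1":
            bad = ~(hom[:, 0] & ~hom[:, 1])
        elif mother_class == "hom2":
            bad = ~(~hom[:, 0] & hom[:, 1])
        else:
            raise ValueError(f"unknown mother_class {mother_class!r}")
        need = need[bad]
    return out


def _draw_males(
    spec: CSDModelSpec,
    females: np.ndarray,
    rng: np.random.Generator,
    matched: bool | None | tuple,
) -> np.ndarray:
    """Draw one male haplotype per female, shape (n, n_loci).

    ``matched=None`` draws uniformly; ``True``/``False`` conditions the
    male to carry / not carry an allele of the female at every locus; a
    tuple applies one of these per locus.
    """
    n, n_loci, _ = females.shape
    sizes = _allele_numbers(spec)
    per_locus = (
        tuple(matched)
        if isinstance(matched, tuple)
        else tuple(matched for _ in sizes)
    )
    out = np.empty((n, n_loci), dtype=np.int64)
    for j, size in enumerate(sizes):
        matched = per_locus[j]
        if matched is None:
            out[:, j] = rng.integers(1, size + 1, size=n)
        elif matched:
            pick = rng.integers(0, 2, size=n)
            out[:, j] = females[np.arange(n), j, pick]
        else:
            het = females[:, j, 0] != females[:, j, 1]
            if size == 2 and het.any():
                raise ValueError(
                    "no unmatched male exists for a heterozygous locus with 2 alleles"
                )
            # rejection against the female's (at most 2) alleles
            col = rng.integers(1, size + 1, size=n)
            bad = (col == females[:, j, 0]) | (col == females[:, j, 1])
            while bad.any():
                idx = np.flatnonzero(bad)
                col[idx] = rng.integers(1, size + 1, size=idx.size)
                bad = (col == females[:, j, 0]) | (col == females[:, j, 1])
            out[:, j] = col
    return out


def _dm_fractions(females: np.ndarray, males: np.ndarray) -> np.ndarray:
    """Per-mating expected diploid-male fraction among diploid offspring."""
    hits = (females[:, :, 0] == males) + (females[:, :, 1] == males)
    return np.prod(hits / 2.0, axis=1)


def _simulate_conditional(
    spec: CSDModelSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (matched, dm_fraction) pairs and sib flags at stated rates."""
    sib = rng.random(n) < spec.alpha
    if spec.n_sex_loci == 1:
        p_match = np.where(sib, 0.5, 2.0 / spec.k)
        matched = rng.random(n) < p_match
        dm = np.where(matched, 0.5, 0.0)
        return sib, dm
    freqs = female_class_freqs(spec.k, spec.l)
    cls = rng.choice(
        3, size=n, p=[freqs.f_het_both, freqs.f_hom_locus1, freqs.f_hom_locus2]
    )
    het_both = cls == 0
    sib_match_p = np.where(het_both, 0.25, 0.5)
    m1p = np.where(cls == 1, 1.0 / spec.k, 2.0 / spec.k)
    m2p = np.where(cls == 2, 1.0 / spec.l, 2.0 / spec.l)
    rand_match_p = m1p * m2p
    matched = rng.random(n) < np.where(sib, sib_match_p, rand_match_p)
    dm = np.where(matched, np.where(het_both, 0.25, 0.5), 0.0)
    return sib, dm


def simulate_matings(
    spec: CSDModelSpec,
    n: int,
    mode: str = "conditional",
    fertilization_prob: float = 0.5,
    seed: int | None = None,
    mother_class: str | None = None,
    father_matched: bool | None | tuple = None,
    daughter_class: str | None = None,
) -> MatingSimResult:
    """Monte-Carlo simulation of CSD matings.

    ``conditional`` mode samples female classes and match events at
    the closed-form model's conditional probabilities.  ``pedigree`` mode
    constructs explicit two-generation families: a founder female (drawn
    from the viable-female class distribution, or restricted via
    ``mother_class``) mates a founder male (uniform, or conditioned via
    ``father_matched`` — a bool for every locus or a per-locus tuple);
    with probability alpha the focal daughter mates a brother drawn from
    the same sibship, else a random male — and realized match rates are
    measured, which need not equal the conditional assumptions.  In
    particular, daughters homozygous at a sex locus inherited from a
    heterozygous mother are matched by brothers at half the rate the
    closed form assumes for homozygous females; ``daughter_class``
    restricts the focal daughters so this deviation can be measured (it is
    reported, never corrected).

    Reported ``dmp`` is the mean expected diploid-male fraction over
    matings (equal diploid brood sizes); ``sib_matched_freq`` is the
    matched frequency among sib matings (NaN if none occurred).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if seed is None:
        raise ValueError("seed is required for simulation")
    rng = np.random.default_rng(seed)

    if mode == "conditional":
        sib, dm = _simulate_conditional(spec, n, rng)
        matched = dm > 0
    elif mode == "pedigree":
        mothers = _draw_female_genotypes(spec, n, rng, mother_class=mother_class)
        fathers = _draw_males(spec, mothers, rng, matched=father_matched)
        n_loci = mothers.shape[1]
        # focal daughter: one maternal allele + the paternal allele per
        # locus, redrawn until viable (not homozygous at all loci)
        daughters = np.empty_like(mothers)
        need = np.arange(n)
        tries = 0
        while need.size:
            pick = rng.integers(0, 2, size=(need.size, n_loci))
            daughters[need, :, 0] = np.take_along_axis(
                mothers[need], pick[:, :, None], axis=2
            )[:, :, 0]
            daughters[need, :, 1] = fathers[need]
            hom = daughters[need, :, 0] == daughters[need, :, 1]
            if daughter_class is None:
                bad = hom.all(axis=1)
            elif daughter_class == "het-both":
                bad = hom.any(axis=1)
            elif daughter_class == "hom1":
                bad = ~(hom[:, 0] & ~hom[:, 1])
            elif daughter_class == "hom2":
                bad = ~(~hom[:, 0] & hom[:, 1])
            else:
                raise ValueError(f"unknown daughter_class {daughter_class!r}")
            need = need[bad]
            tries += 1
            if tries > 10_000 and need.size:
                raise ValueError(
                    f"daughter_class {daughter_class!r} unreachable for these parents"
                )
        sib = rng.random(n) < spec.alpha
        # brother: haploid son of the same mother (maternal alleles only)
        pick = rng.integers(0, 2, size=(n, n_loci))
        brothers = np.take_along_axis(mothers, pick[:, :, None], axis=2)[:, :, 0]
        randoms = _draw_males(spec, daughters, rng, matched=None)
        mates = np.where(sib[:, None], brothers, randoms)
        dm = _dm_fractions(daughters, mates)
        matched = dm > 0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    sib_matched = float(matched[sib].mean()) if sib.any() else float("nan")
    return MatingSimResult(
        n_matings=n,
        matched_freq=float(matched.mean()),
        dmp=float(dm.mean()),
        sib_matched_freq=sib_matched,
        seed=seed,
    )


def _heterozygosity_fis(genotypes: np.ndarray) -> float:
    """Multi-locus F_IS = 1 - sum(Ho)/sum(He) over polymorphic loci.

    ``genotypes``: (n, L, 2) biallelic calls coded 0/1.
    """
    n = genotypes.shape[0]
    p = genotypes.mean(axis=(0, 2))
    poly = (p > 0) & (p < 1)
    if not poly.any():
        return 0.0
    ho = (genotypes[:, poly, 0] != genotypes[:, poly, 1]).mean(axis=0)
    he = 2.0 * p[poly] * (1.0 - p[poly]) * (2 * n) / (2 * n - 1)
    return float(1.0 - ho.sum() / he.sum())


def simulate_generations(
    spec: CSDModelSpec,
    n_females: int = 500,
    n_generations: int = 10,
    n_neutral_loci: int = 100,
    seed: int | None = None,
    neutral_maf_low: float = 0.2,
) -> GenerationSeries:
    """Multi-generation individual-based haplodiploid population simulator.

    Discrete non-overlapping generations of ``n_females`` mated females.
    Each next-generation female is a viable daughter of a random current
    family; she mates a brother (a haploid son of her own mother) with
    probability alpha, else a son of a random family.  Diploid males are
    reproductive dead ends and are simply never recruited.  Unlinked
    neutral biallelic loci are transmitted alongside the sex loci and the
    per-generation series reports their multi-locus F_IS, the number of
    surviving sex alleles per locus, and the diploid male proportion
    realized among diploid eggs that generation.

    If sex-allele diversity collapses so far that no viable daughters can
    be produced, the series is truncated and flagged ``extinct``.
    """
    if n_females < 10:
        raise ValueError(f"n_females must be >= 10, got {n_females}")
    if seed is None:
        raise ValueError("seed is required for simulation")
    rng = np.random.default_rng(seed)
    alpha = spec.alpha
    sizes = _allele_numbers(spec)
    n_sex = len(sizes)
    L = n_neutral_loci

    # founders: viable females with uniform sex alleles, mates uniform
    fem_sex = _draw_female_genotypes(spec, n_females, rng)
    mate_sex = _draw_males(spec, fem_sex, rng, matched=None)
    freqs = rng.uniform(neutral_maf_low, 0.5, size=L)
    fem_neu = (rng.random((n_females, L, 2)) < freqs[None, :, None]).astype(np.int8)
    mate_neu = (rng.random((n_females, L)) < freqs).astype(np.int8)

    series = GenerationSeries(fis=[], dmp=[], sex_allele_counts=[])
    for _ in range(n_generations):
        mother_idx = rng.integers(0, n_females, size=n_females)
        new_fem_sex = np.empty_like(fem_sex)
        new_fem_neu = np.empty_like(fem_neu)
        need = np.arange(n_females)
        n_draws = 0
        n_dm = 0
        stalled = 0
        while need.size:
            m = mother_idx[need]
            pick = rng.integers(0, 2, size=(need.size, n_sex))
            egg_sex = np.take_along_axis(fem_sex[m], pick[:, :, None], axis=2)[:, :, 0]
            child_sex = np.stack([egg_sex, mate_sex[m]], axis=2)
            hom = child_sex[:, :, 0] == child_sex[:, :, 1]
            male = hom.all(axis=1)
            n_draws += need.size
            n_dm += int(male.sum())
            ok = ~male
            ok_rows = need[ok]
            new_fem_sex[ok_rows] = child_sex[ok]
            pickn = rng.integers(0, 2, size=(ok_rows.size, L))
            eggn = np.take_along_axis(
                fem_neu[mother_idx[ok_rows]], pickn[:, :, None], axis=2
            )[:, :, 0]
            new_fem_neu[ok_rows, :, 0] = eggn
            new_fem_neu[ok_rows, :, 1] = mate_neu[mother_idx[ok_rows]]
            need = need[male]
            stalled = stalled + 1 if ok_rows.size == 0 else 0
            if stalled > 1000:
                series.extinct = True
                return series

        # mates for the new females: brothers with probability alpha
        sib = rng.random(n_females) < alpha
        mate_mother = np.where(sib, mother_idx, rng.integers(0, n_females, size=n_females))
        pick = rng.integers(0, 2, size=(n_females, n_sex))
        new_mate_sex = np.take_along_axis(
            fem_sex[mate_mother], pick[:, :, None], axis=2
        )[:, :, 0]
        pickn = rng.integers(0, 2, size=(n_females, L))
        new_mate_neu = np.take_along_axis(
            fem_neu[mate_mother], pickn[:, :, None], axis=2
        )[:, :, 0]

        fem_sex, fem_neu = new_fem_sex, new_fem_neu
        mate_sex, mate_neu = new_mate_sex, new_mate_neu

        series.fis.append(_heterozygosity_fis(fem_neu))
        series.dmp.append(n_dm / n_draws if n_draws else 0.0)
        counts = tuple(
            len(np.unique(np.concatenate([fem_sex[:, j, :].ravel(), mate_sex[:, j]])))
            for j in range(n_sex)
        )
        series.sex_allele_counts.append(counts)
    series.final_neutral_genotypes = fem_neu.copy()
    return series
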