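"""Closed-form genetic-load model for complementary sex determination (CSD).

Under CSD, diploids that are homozygous at every sex locus develop as
(low-fitness) males.  The proportion of diploid males among diploids (DMP)
depends on the number of sex loci, the sex-allele diversity at each locus,
and the rate of sibmating.  This module provides the closed-form predictions
for one-locus (sl-CSD) and two-locus (2l-CSD) systems with partial
sibmating, the mapping between the inbreeding coefficient F_IS and the
sibmating rate, prediction bands over an interval of sibmating rates, and
inverse queries (which allele numbers are consistent with an observed DMP).

Assumptions: sex alleles are equally frequent at each locus (so a random
male matches a heterozygous locus with probability 2/k and a homozygous
locus with probability 1/k), loci are unlinked, and the random-mating female
genotype-class frequencies are conditioned on female viability (diploids
homozygous at all sex loci are male and therefore never observed as
females).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = [
    "CSDModelSpec",
    "FemaleClassFreqs",
    "MatchedMatingFreqs",
    "DMPPrediction",
    "sibmating_from_fis",
    "fis_from_sibmating",
    "female_class_freqs",
    "matched_mating_freqs",
    "dmp_sl",
    "dmp_2l",
    "dmp",
    "dmp_band",
    "consistent_allele_range",
    "min_alleles_required",
]


@dataclass(frozen=True)
class CSDModelSpec:
    """Parameters of a CSD load model.

    Parameters
    ----------
    n_sex_loci
        1 for sl-CSD, 2 for two-locus CSD.
    k
        Number of (equally frequent) sex alleles at the first locus.
    l
        Number of sex alleles at the second locus; ignored for sl-CSD.
    alpha
        Sibmating rate (proportion of matings between full siblings).
    dm_survival
        Developmental survival of diploid males relative to females.
        The default 1 treats diploid males as fully viable.
    """

    n_sex_loci: int = 2
    k: int = 10
    l: int = 10
    alpha: float = 0.0
    dm_survival: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sex_loci not in (1, 2):
            raise ValueError(f"n_sex_loci must be 1 or 2, got {self.n_sex_loci}")
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.n_sex_loci == 2 and self.l < 2:
            raise ValueError(f"l must be >= 2 for a two-locus model, got {self.l}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.dm_survival <= 1.0:
            raise ValueError(f"dm_survival must be in [0, 1], got {self.dm_survival}")


@dataclass(frozen=True)
class FemaleClassFreqs:
    """Random-mating female genotype-class frequencies (two-locus model).

    ``f_het_both`` is the frequency of females heterozygous at both sex
    loci; ``f_hom_locus1``/``f_hom_locus2`` are females homozygous at one
    locus (and necessarily heterozygous at the other).  Frequencies are
    conditioned on female viability, so they sum to one.
    """

    f_het_both: float
    f_hom_locus1: float
    f_hom_locus2: float

    def __post_init__(self) -> None:
        total = self.f_het_both + self.f_hom_locus1 + self.f_hom_locus2
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"female class frequencies must sum to 1, got {total}")


@dataclass(frozen=True)
class MatchedMatingFreqs:
    """Matched-mating frequencies under random mating.

    ``theta`` is the overall probability that a random mating is matched
    (the male's sex allele(s) occur in the female's genotype at every
    locus); ``p_het`` and ``p_hom`` split it by female class (double
    heterozygotes vs single-locus homozygotes).  For sl-CSD, ``p_hom`` is 0.
    """

    theta: float
    p_het: float
    p_hom: float


@dataclass(frozen=True)
class DMPPrediction:
    """A DMP point prediction together with a band over a sibmating interval."""

    spec: CSDModelSpec
    dmp: float
    band_low: float
    band_high: float

    def contains(self, value: float) -> bool:
        """Inclusive band membership."""
        return self.band_low <= value <= self.band_high


def sibmating_from_fis(fis: float) -> float:
    """Estimate the sibmating rate alpha from an inbreeding coefficient.

    Uses the equilibrium relation alpha = 4*F_IS / (3*F_IS + 1) for partial
    full-sib mating.  Negative F_IS (heterozygote excess) is floored at
    alpha = 0 with a warning, since a sibmating rate cannot be negative.

    Raises
    ------
    ValueError
        If ``fis <= -1/3`` (the relation's denominator is non-positive) or
        ``fis > 1``.
    """
    if fis <= -1.0 / 3.0:
        raise ValueError(f"fis must exceed -1/3, got {fis}")
    if fis > 1.0:
        raise ValueError(f"fis must be <= 1, got {fis}")
    if fis < 0.0:
        logger.warning("negative F_IS (%g): sibmating rate floored at 0", fis)
        return 0.0
    return min(4.0 * fis / (3.0 * fis + 1.0), 1.0)


def fis_from_sibmating(alpha: float) -> float:
    """Equilibrium inbreeding coefficient under partial sibmating.

    Algebraic inverse of :func:`sibmating_from_fis`:
    F_IS = alpha / (4 - 3*alpha).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha / (4.0 - 3.0 * alpha)


def female_class_freqs(k: int, l: int) -> FemaleClassFreqs:
    """Female genotype-class frequencies under random mating (two loci).

    With k (l) equally frequent alleles, a random diploid is heterozygous
    at locus 1 with probability 1 - 1/k, independently across loci.
    Diploids homozygous at both loci are males, so the three female classes
    are renormalized by 1 - 1/(k*l).
    """
    if k < 2 or l < 2:
        raise ValueError(f"k and l must be >= 2, got k={k}, l={l}")
    p_hom1 = 1.0 / k
    p_hom2 = 1.0 / l
    viable = 1.0 - p_hom1 * p_hom2
    return FemaleClassFreqs(
        f_het_both=(1.0 - p_hom1) * (1.0 - p_hom2) / viable,
        f_hom_locus1=p_hom1 * (1.0 - p_hom2) / viable,
        f_hom_locus2=(1.0 - p_hom1) * p_hom2 / viable,
    )


def matched_mating_freqs(spec: CSDModelSpec) -> MatchedMatingFreqs:
    """Matched-mating frequencies under random mating for a model spec.

    A random male matches a heterozygous locus with probability 2/alleles
    and a homozygous locus with probability 1/alleles; a mating is matched
    (can yield diploid males) only if matched at every sex locus.
    """
    if spec.n_sex_loci == 1:
        theta = 2.0 / spec.k
        return MatchedMatingFreqs(theta=theta, p_het=theta, p_hom=0.0)
    k, l = spec.k, spec.l
    freqs = female_class_freqs(k, l)
    p_het = freqs.f_het_both * (2.0 / k) * (2.0 / l)
    p_hom = freqs.f_hom_locus1 * (1.0 / k) * (2.0 / l) + freqs.f_hom_locus2 * (
        2.0 / k
    ) * (1.0 / l)
    return MatchedMatingFreqs(theta=p_het + p_hom, p_het=p_het, p_hom=p_hom)


def _survival_adjust(m: float, s: float) -> float:
    """DMP among surviving diploids when diploid males survive at rate s."""
    if s == 1.0:
        return m
    denom = s * m + (1.0 - m)
    return s * m / denom if denom > 0 else 0.0


def dmp_sl(alpha: float, k: int, dm_survival: float = 1.0) -> float:
    """Predicted diploid male proportion under single-locus CSD.

    Half of sibmatings are matched and matched matings yield 50% diploid
    males among diploid offspring, giving the sibmating term 0.25*alpha;
    random matings are matched with probability theta = 2/k, giving the
    outbreeding term (1 - alpha)/k.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not 0.0 <= dm_survival <= 1.0:
        raise ValueError(f"dm_survival must be in [0, 1], got {dm_survival}")
    base = 0.25 * alpha + (1.0 - alpha) / k
    return _survival_adjust(base, dm_survival)


def dmp_2l(alpha: float, k: int, l: int, dm_survival: float = 1.0) -> float:
    """Predicted diploid male proportion under two-locus CSD.

    Mixes four mating classes: sibmatings with double-heterozygous mothers
    (matched at both loci 1/4 of the time, 25% diploid males when matched:
    0.0625*alpha*f_HET), sibmatings with single-locus-homozygous mothers
    (matched half the time, 50% diploid males: 0.25*alpha*(1 - f_HET)),
    and random matings with each female class at the random matched-mating
    frequencies p_HET and p_HOM.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    freqs = female_class_freqs(k, l)
    matched = matched_mating_freqs(
        CSDModelSpec(n_sex_loci=2, k=k, l=l, alpha=alpha, dm_survival=dm_survival)
    )
    f_het = freqs.f_het_both
    base = (
        0.0625 * alpha * f_het
        + 0.25 * alpha * (1.0 - f_het)
        + 0.25 * (1.0 - alpha) * matched.p_het
        + 0.5 * (1.0 - alpha) * matched.p_hom
    )
    return _survival_adjust(base, dm_survival)


def dmp(spec: CSDModelSpec, alpha: float | None = None) -> float:
    """Predicted DMP for a model spec (optionally overriding alpha)."""
    a = spec.alpha if alpha is None else alpha
    if spec.n_sex_loci == 1:
        return dmp_sl(a, spec.k, spec.dm_survival)
    return dmp_2l(a, spec.k, spec.l, spec.dm_survival)


def dmp_band(alpha_low: float, alpha_high: float, spec: CSDModelSpec) -> DMPPrediction:
    """DMP prediction band over an interval of sibmating rates.

    For full diploid-male survival the prediction is affine in alpha, so
    the band endpoints are the predictions at the interval endpoints
    (sorted; the slope is negative for small k).  Reduced survival applies
    a monotone transform, which preserves the endpoint property.
    """
    if not 0.0 <= alpha_low <= alpha_high <= 1.0:
        raise ValueError(
            f"need 0 <= alpha_low <= alpha_high <= 1, got [{alpha_low}, {alpha_high}]"
        )
    lo = dmp(spec, alpha_low)
    hi = dmp(spec, alpha_high)
    point = dmp(spec)
    return DMPPrediction(
        spec=spec, dmp=point, band_low=min(lo, hi), band_high=max(lo, hi)
    )


def consistent_allele_range(
    dmp_obs: float,
    alpha_low: float,
    alpha_high: float,
    k_values: list[int] | range,
    spec_template: CSDModelSpec,
) -> set[int]:
    """Allele numbers whose prediction band contains an observed DMP.

    For the two-locus model, k = l is imposed at each grid value.
    Containment is inclusive at the band endpoints.
    """
    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values must be nonempty")
    consistent: set[int] = set()
    for k in k_values:
        if k < 2:
            raise ValueError(f"every k must be >= 2, got {k}")
        spec = CSDModelSpec(
            n_sex_loci=spec_template.n_sex_loci,
            k=k,
            l=k if spec_template.n_sex_loci == 2 else spec_template.l,
            alpha=spec_template.alpha,
            dm_survival=spec_template.dm_survival,
        )
        band = dmp_band(alpha_low, alpha_high, spec)
        if band.contains(dmp_obs):
            consistent.add(k)
    return consistent


def min_alleles_required(
    dmp_obs: float,
    alpha: float,
    model: int = 1,
    k_max: int = 1000,
    dm_survival: float = 1.0,
) -> int | None:
    """Smallest allele number predicting DMP at or below an observed value.

    Returns None if no k up to ``k_max`` suffices — e.g. under sl-CSD when
    the sibmating term 0.25*alpha alone already exceeds ``dmp_obs``.
    """
    if k_max < 2:
        raise ValueError(f"k_max must be >= 2, got {k_max}")
    if model not in (1, 2):
        raise ValueError(f"model must be 1 or 2, got {model}")
    for k in range(2, k_max + 1):
        value = (
            dmp_sl(alpha, k, dm_survival)
            if model == 1
            else dmp_2l(alpha, k, k, dm_survival)
        )
        if value <= dmp_obs:
            return k
    return None
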