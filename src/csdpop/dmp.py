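"""Diploid male proportion (DMP) estimation from field ploidy counts.

DMP is defined as diploid males / (diploid males + females): it is the
proportion of diploids that developed as males, so haploid males and males
of unknown ploidy do not enter the estimate.  Confidence intervals are
Clopper–Pearson (exact binomial).  The module also computes per-field
collection summaries (infestation, parasitism rate, sex ratio) as weighted
means with standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PloidyCounts",
    "DMPEstimate",
    "dmp_estimate",
    "aggregate_dmp",
    "weighted_mean_se",
    "field_summaries",
]


@dataclass(frozen=True)
class PloidyCounts:
    """Per-field counts of assayed males by ploidy class, plus females."""

    field_id: str
    n_males_assayed: int
    n_haploid: int
    n_diploid_males: int
    n_unknown: int
    n_females: int

    def __post_init__(self) -> None:
        counts = (
            self.n_males_assayed,
            self.n_haploid,
            self.n_diploid_males,
            self.n_unknown,
            self.n_females,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_haploid + self.n_diploid_males + self.n_unknown != self.n_males_assayed:
            raise ValueError(
                "haploid + diploid + unknown males must equal males assayed"
            )


@dataclass(frozen=True)
class DMPEstimate:
    dmp: float
    ci_low: float
    ci_high: float
    n_diploid_males: int
    n_females: int
    ci_level: float


def _clopper_pearson(x: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def dmp_estimate(counts: PloidyCounts, ci_level: float = 0.95) -> DMPEstimate:
    """Point estimate and Clopper–Pearson CI of the diploid male proportion."""
    x = counts.n_diploid_males
    n = x + counts.n_females
    if n == 0:
        raise ValueError(
            f"field {counts.field_id}: no diploids (diploid males + females = 0)"
        )
    lo, hi = _clopper_pearson(x, n, ci_level)
    return DMPEstimate(x / n, lo, hi, x, counts.n_females, ci_level)


def aggregate_dmp(counts_list: list[PloidyCounts], ci_level: float = 0.95) -> DMPEstimate:
    """Pooled DMP across fields (summed numerators and denominators)."""
    if not counts_list:
        raise ValueError("counts_list must be nonempty")
    x = sum(c.n_diploid_males for c in counts_list)
    females = sum(c.n_females for c in counts_list)
    pooled = PloidyCounts("pooled", x, 0, x, 0, females)
    return dmp_estimate(pooled, ci_level)


def weighted_mean_se(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted mean and its standard error (reliability weights).

    Weights are normalized; the SE uses the unbiased weighted sample
    variance Var = sum w (x - m)^2 / (1 - sum w^2) and
    SE^2 = Var * sum w^2.  A single observation gives SE 0.
    """
    values = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if values.shape != w.shape or values.size == 0:
        raise ValueError("values and weights must be equal-length and nonempty")
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mean = float(np.sum(w * values))
    if values.size == 1 or np.isclose(np.sum(w**2), 1.0):
        return mean, 0.0
    var = float(np.sum(w * (values - mean) ** 2) / (1.0 - np.sum(w**2)))
    return mean, float(np.sqrt(var * np.sum(w**2)))


def field_summaries(
    plants: pd.DataFrame,
    ploidy: list[PloidyCounts] | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-field collection summaries.

    ``plants`` columns: field, n_hosts (unparasitized host larvae),
    n_cocoons (parasitoid cocoons), n_adult_males, n_adult_females, one
    row per sampled plant.  Infestation per plant is hosts + cocoons;
    parasitism per plant is cocoons / (hosts + cocoons), averaged with
    infestation weights; sex ratio (proportion male among emerged adults)
    is averaged with adult-count weights.  DMP columns are added for
    fields present in ``ploidy``.
    """
    required = {"field", "n_hosts", "n_cocoons", "n_adult_males", "n_adult_females"}
    if not required.issubset(plants.columns):
        raise ValueError(f"plants table must have columns {sorted(required)}")
    dmp_by_field = {}
    if ploidy:
        dmp_by_field = {c.field_id: dmp_estimate(c, ci_level) for c in ploidy}
    rows = []
    for fid, grp in plants.groupby("field", sort=False):
        if len(grp) == 0:
            logger.warning("field %s has no plants; skipped", fid)
            continue
        infest = (grp["n_hosts"] + grp["n_cocoons"]).to_numpy(dtype=float)
        inf_mean = float(infest.mean())
        inf_se = float(infest.std(ddof=1) / np.sqrt(len(infest))) if len(infest) > 1 else 0.0
        with np.errstate(invalid="ignore"):
            parasitism = grp["n_cocoons"].to_numpy(dtype=float) / infest
        ok = infest > 0
        par_mean, par_se = weighted_mean_se(parasitism[ok], infest[ok])
        adults = (grp["n_adult_males"] + grp["n_adult_females"]).to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            sexratio = grp["n_adult_males"].to_numpy(dtype=float) / adults
        ok = adults > 0
        sr_mean, sr_se = weighted_mean_se(sexratio[ok], adults[ok])
        row = {
            "field": fid,
            "n_plants": len(grp),
            "infestation_mean": inf_mean,
            "infestation_se": inf_se,
            "parasitism_rate": par_mean,
            "parasitism_se": par_se,
            "sex_ratio": sr_mean,
            "sex_ratio_se": sr_se,
        }
        if fid in dmp_by_field:
            est = dmp_by_field[fid]
            row.update(dmp=est.dmp, dmp_ci_low=est.ci_low, dmp_ci_high=est.ci_high)
        rows.append(row)
    return pd.DataFrame(rows)
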