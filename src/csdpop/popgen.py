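"""Population-genetic statistics on diploid genotype matrices.

Heterozygosity, Weir–Cockerham variance-component F-statistics with
bootstrap confidence intervals, pairwise F_ST with permutation tests, and
a three-level locus-by-locus AMOVA on allelic distances.

Missing data are handled pairwise-complete per locus; within a group a
locus needs at least 2 non-missing individuals (4 gene copies) to
contribute to that group's components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FStatResult",
    "heterozygosity",
    "per_field_fis",
    "wc_variance_components",
    "global_fstats",
    "pairwise_fst",
    "amova",
]

_MIN_INDIVIDUALS = 2  # per group per locus (= 4 gene copies)


@dataclass
class FStatResult:
    """Weir–Cockerham multi-locus F-statistics with bootstrap CIs.

    Combined statistics are ratios of variance components summed over
    loci, so (1 - F_IT) = (1 - F_IS)(1 - F_ST) holds by construction.
    """

    f_is: float
    f_st: float
    f_it: float
    components: pd.DataFrame  # per locus: a (among groups), b, c
    ci: dict[str, tuple[float, float]]
    n_bootstrap: int

    def __repr__(self) -> str:  # compact, CI-aware
        parts = []
        for name, val in [("F_IS", self.f_is), ("F_ST", self.f_st), ("F_IT", self.f_it)]:
            lo, hi = self.ci.get(name.lower(), (float("nan"), float("nan")))
            parts.append(f"{name}={val:.4f} (95% CI {lo:.4f}-{hi:.4f})")
        return "FStatResult(" + ", ".join(parts) + ")"


# ---------------------------------------------------------------------------
# heterozygosity


def heterozygosity(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus observed and unbiased expected heterozygosity.

    Ho is the fraction of heterozygous calls among non-missing calls.
    He is the unbiased gene diversity n/(n-1) * (1 - sum p^2) with n the
    number of non-missing gene copies.  Loci with all calls missing are
    excluded with a warning; monomorphic loci have Ho = He = 0.
    """
    rows = []
    for j, locus in enumerate(matrix.locus_ids):
        obs = matrix.locus_calls(j)
        if obs.shape[0] == 0:
            logger.warning("locus %s has no non-missing calls; excluded", locus)
            continue
        ho = float((obs[:, 0] != obs[:, 1]).mean())
        copies = obs.ravel()
        n = copies.size
        _, counts = np.unique(copies, return_counts=True)
        p = counts / n
        he = n / (n - 1) * (1.0 - float(np.sum(p**2))) if n > 1 else 0.0
        rows.append(
            {
                "locus_id": locus,
                "n": obs.shape[0],
                "ho": ho,
                "he": he,
                "monomorphic": len(counts) < 2,
            }
        )
    return pd.DataFrame(rows)


def _het_summary(df: pd.DataFrame) -> dict[str, float]:
    out = {}
    for col in ("ho", "he"):
        vals = df[col].to_numpy(dtype=float)
        out[f"{col}_mean"] = float(vals.mean())
        out[f"{col}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return out


def per_field_fis(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-field multi-locus F_IS = 1 - sum(Ho)/sum(He), with Ho/He means.

    Monomorphic loci (within the field) contribute nothing to either sum.
    """
    rows = []
    for f in matrix.field_labels():
        sub = matrix.field_subset(f)
        het = heterozygosity(sub)
        poly = het[~het["monomorphic"]]
        fis = float(1.0 - poly["ho"].sum() / poly["he"].sum()) if len(poly) else float("nan")
        summ = _het_summary(het)
        rows.append(
            {
                "field": f,
                "n": sub.n_individuals,
                "monomorphic_loci": int(het["monomorphic"].sum()),
                "ho_mean": summ["ho_mean"],
                "ho_se": summ["ho_se"],
                "he_mean": summ["he_mean"],
                "he_se": summ["he_se"],
                "f_is": fis,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir–Cockerham variance components


def _wc_locus(calls: np.ndarray, pop_idx: np.ndarray, n_pops: int) -> tuple[float, float, float] | None:
    """Weir–Cockerham components (a, b, c) for one locus, summed over alleles.

    ``calls``: (n, 2) with MISSING rows allowed; ``pop_idx``: population
    index per individual.  Returns None if fewer than 2 populations have
    enough data or the locus is monomorphic.
    """
    keep = calls[:, 0] != MISSING
    calls = calls[keep]
    pop_idx = pop_idx[keep]
    pops, inv = np.unique(pop_idx, return_inverse=True)
    sizes = np.bincount(inv)
    ok = sizes >= _MIN_INDIVIDUALS
    if ok.sum() < 2:
        return None
    keep2 = ok[inv]
    calls = calls[keep2]
    inv = np.unique(inv[keep2], return_inverse=True)[1]
    r = int(inv.max()) + 1
    n_i = np.bincount(inv).astype(float)

    alleles = np.unique(calls)
    if alleles.size < 2:
        return None

    n_bar = n_i.mean()
    n_total = n_i.sum()
    n_c = (n_total - np.sum(n_i**2) / n_total) / (r - 1)

    a = b = c = 0.0
    for al in alleles:
        hits = (calls == al).sum(axis=1)  # copies of allele per individual
        p_i = np.bincount(inv, weights=hits) / (2 * n_i)
        h_i = np.bincount(inv, weights=(hits == 1).astype(float)) / n_i
        p_bar = float(np.sum(n_i * p_i) / n_total)
        h_bar = float(np.sum(n_i * h_i) / n_total)
        s2 = float(np.sum(n_i * (p_i - p_bar) ** 2) / ((r - 1) * n_bar))
        a += (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
        )
        b += (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c += h_bar / 2.0
    return a, b, c


def wc_variance_components(
    matrix: GenotypeMatrix, grouping: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-locus Weir–Cockerham components a, b, c (grouping by field)."""
    if grouping is None:
        grouping = matrix.fields
    _, pop_idx = np.unique(grouping, return_inverse=True)
    n_pops = int(pop_idx.max()) + 1
    rows = []
    for j, locus in enumerate(matrix.locus_ids):
        comp = _wc_locus(matrix.calls[:, j, :], pop_idx, n_pops)
        if comp is None:
            logger.debug("locus %s skipped for F-statistics", locus)
            continue
        rows.append({"locus_id": locus, "a": comp[0], "b": comp[1], "c": comp[2]})
    return pd.DataFrame(rows)


def _ratios(components: np.ndarray) -> tuple[float, float, float]:
    a, b, c = components.sum(axis=0)
    tot = a + b + c
    f_st = a / tot if tot else float("nan")
    f_is = b / (b + c) if (b + c) else float("nan")
    f_it = (a + b) / tot if tot else float("nan")
    return f_is, f_st, f_it


def global_fstats(
    matrix: GenotypeMatrix,
    grouping: np.ndarray | None = None,
    n_bootstrap: int = 20_000,
    seed: int | None = None,
) -> FStatResult:
    """Multi-locus Weir–Cockerham F-statistics with bootstrap-over-loci CIs.

    Requires at least 2 groups and at least 2 polymorphic loci.  The 95%
    CI is the percentile interval over ``n_bootstrap`` locus resamples
    (skipped when ``n_bootstrap`` is 0).
    """
    if grouping is None:
        grouping = matrix.fields
    if len(np.unique(grouping)) < 2:
        raise ValueError("F_ST requires at least 2 groups; use per_field_fis for one")
    comp_df = wc_variance_components(matrix, grouping)
    if len(comp_df) < 2:
        raise ValueError("need at least 2 usable polymorphic loci")
    comps = comp_df[["a", "b", "c"]].to_numpy()
    f_is, f_st, f_it = _ratios(comps)

    ci: dict[str, tuple[float, float]] = {}
    if n_bootstrap > 0:
        if seed is None:
            raise ValueError("seed is required for bootstrap CIs")
        rng = np.random.default_rng(seed)
        L = comps.shape[0]
        idx = rng.integers(0, L, size=(n_bootstrap, L))
        sums = comps[idx].sum(axis=1)  # (B, 3)
        tot = sums.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot = {
                "f_st": sums[:, 0] / tot,
                "f_is": sums[:, 1] / (sums[:, 1] + sums[:, 2]),
                "f_it": (sums[:, 0] + sums[:, 1]) / tot,
            }
        for name, vals in boot.items():
            vals = vals[np.isfinite(vals)]
            ci[name] = (
                float(np.percentile(vals, 2.5)),
                float(np.percentile(vals, 97.5)),
            )
    return FStatResult(
        f_is=f_is,
        f_st=f_st,
        f_it=f_it,
        components=comp_df,
        ci=ci,
        n_bootstrap=n_bootstrap,
    )


# ---------------------------------------------------------------------------
# pairwise F_ST


def _theta_for_pair(calls: np.ndarray, pop_idx: np.ndarray) -> float:
    """Multi-locus theta for a two-population subset."""
    a_sum = tot = 0.0
    for j in range(calls.shape[1]):
        comp = _wc_locus(calls[:, j, :], pop_idx, 2)
        if comp is None:
            continue
        a_sum += comp[0]
        tot += sum(comp)
    return a_sum / tot if tot else float("nan")


def pairwise_fst(
    matrix: GenotypeMatrix,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Weir–Cockerham F_ST between fields with permutation p-values.

    p = (#{permuted F_ST >= observed} + 1) / (n_permutations + 1), where
    permutations shuffle individuals between the two fields.
    """
    fields = matrix.field_labels()
    if len(fields) < 2:
        raise ValueError("pairwise F_ST requires at least 2 fields")
    if n_permutations > 0 and seed is None:
        raise ValueError("seed is required for permutation tests")
    rng = np.random.default_rng(seed)
    field_arr = matrix.fields
    fst = pd.DataFrame(np.nan, index=fields, columns=fields)
    pval = pd.DataFrame(np.nan, index=fields, columns=fields)
    for i, f1 in enumerate(fields):
        for f2 in fields[i + 1 :]:
            sel = np.flatnonzero((field_arr == f1) | (field_arr == f2))
            calls = matrix.calls[sel]
            labels = (field_arr[sel] == f2).astype(int)
            obs = _theta_for_pair(calls, labels)
            fst.loc[f1, f2] = fst.loc[f2, f1] = obs
            if n_permutations > 0:
                exceed = 0
                perm = labels.copy()
                for _ in range(n_permutations):
                    rng.shuffle(perm)
                    if _theta_for_pair(calls, perm) >= obs:
                        exceed += 1
                p = (exceed + 1) / (n_permutations + 1)
                pval.loc[f1, f2] = pval.loc[f2, f1] = p
    return fst, pval


# ---------------------------------------------------------------------------
# AMOVA


def _ss_groups(copies_allele: np.ndarray, group_idx: np.ndarray) -> float:
    """Sum over groups of within-group SS (allelic mismatch distance)."""
    ss = 0.0
    for g in np.unique(group_idx):
        sub = copies_allele[group_idx == g]
        n = sub.size
        if n == 0:
            continue
        _, counts = np.unique(sub, return_counts=True)
        ss += (n - np.sum(counts**2) / n) / 2.0
    return ss


def amova(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Three-level locus-by-locus AMOVA on allelic distances.

    Partitions variance between regions, between fields within regions,
    and within fields, treating each gene copy as a unit with distance 1
    between different alleles.  Sums of squares and variance components
    are computed per locus (pairwise-complete) and summed; degrees of
    freedom are reported for the complete design (gene-copy level:
    regions-1, fields-regions, 2N-fields).
    """
    fields = matrix.fields
    regions = matrix.regions
    field_labels = matrix.field_labels()
    region_labels = matrix.region_labels()
    R, F = len(region_labels), len(field_labels)
    if R < 2:
        raise ValueError("AMOVA requires at least 2 regions")
    counts_per_region = pd.Series(
        [matrix.region_of[f] for f in field_labels]
    ).value_counts()
    if (counts_per_region < 2).all():
        raise ValueError("AMOVA requires at least one region with 2+ fields")

    ss = np.zeros(3)  # among regions, among fields within regions, within fields
    var = np.zeros(3)
    for j in range(matrix.n_loci):
        col = matrix.calls[:, j, :]
        keep = col[:, 0] != MISSING
        if keep.sum() < 2:
            continue
        copies = col[keep].ravel()
        if np.unique(copies).size < 2:
            continue
        f_idx = np.repeat(fields[keep], 2)
        r_idx = np.repeat(regions[keep], 2)
        N = copies.size
        _, cnt = np.unique(copies, return_counts=True)
        ss_tot = (N - np.sum(cnt**2) / N) / 2.0
        ss_wf = _ss_groups(copies, f_idx)
        ss_wr = _ss_groups(copies, r_idx)
        ss_ar = ss_tot - ss_wr
        ss_af = ss_wr - ss_wf
        ss += (ss_ar, ss_af, ss_wf)

        # sample-size coefficients of the nested design at this locus
        n_f = pd.Series(f_idx).value_counts()
        n_r = pd.Series(r_idx).value_counts()
        region_of_field = {f: matrix.region_of[f] for f in n_f.index}
        sum_nf2_over_nr = sum(
            n_f[f] ** 2 / n_r[region_of_field[f]] for f in n_f.index
        )
        F_l = len(n_f)
        G_l = len(n_r)
        if F_l <= G_l or G_l < 2:
            continue
        n1 = (N - sum_nf2_over_nr) / (F_l - G_l)
        n2 = (sum_nf2_over_nr - np.sum(n_f.to_numpy() ** 2) / N) / (G_l - 1)
        n3 = (N - np.sum(n_r.to_numpy() ** 2) / N) / (G_l - 1)
        ms_w = ss_wf / (N - F_l)
        ms_b = ss_af / (F_l - G_l)
        ms_a = ss_ar / (G_l - 1)
        sig_c = ms_w
        sig_b = (ms_b - sig_c) / n1
        sig_a = (ms_a - sig_c - n2 * sig_b) / n3
        var += (sig_a, sig_b, sig_c)

    total_var = var.sum()
    percent = 100.0 * var / total_var if total_var else np.full(3, np.nan)
    df = [R - 1, F - R, 2 * matrix.n_individuals - F]
    out = pd.DataFrame(
        {
            "df": df + [sum(df)],
            "ss": list(ss) + [ss.sum()],
            "variance": list(var) + [total_var],
            "percent": list(percent) + [100.0],
        },
        index=[
            "between_regions",
            "between_fields_within_regions",
            "within_fields",
            "total",
        ],
    )
    return out
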