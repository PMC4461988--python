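"""Locus quality-control filtering and SNP panel selection.

Implements the marker-vetting workflow for a de-novo SNP panel: exact
Hardy–Weinberg tests per locus, pairwise likelihood-ratio LD tests with a
sequential Bonferroni correction, removal of HWE-deviant loci and of one
randomly chosen member of each significant LD pair (iterated until no
significant pair remains), plus the upstream candidate-panel selection
rules (MAF floor, biallelic, minimum spacing, MAF-bin quotas, one SNP per
scaffold) and the transition:transversion sanity ratio.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .hwe import hwe_test
from .ld import ld_test

logger = logging.getLogger(__name__)

__all__ = [
    "sequential_bonferroni",
    "FilterResult",
    "filter_loci",
    "select_snp_panel",
    "titv_ratio",
]

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def sequential_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm's sequential Bonferroni rejection flags (original order).

    Sort p-values ascending, compare the i-th smallest (1-based) against
    alpha/(m - i + 1), and stop at the first non-significant one.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject


@dataclass
class FilterResult:
    retained: list[str]
    reports: pd.DataFrame  # locus_id, ho, he, hwe_p, monomorphic, excluded_reason
    ld_pairs: pd.DataFrame  # locus_a, locus_b, lrt, p, significant


def _min_vertex_cover(edges: list[tuple[str, str]]) -> set[str]:
    """Brute-force minimum vertex cover (small graphs only)."""
    nodes = sorted({v for e in edges for v in e})
    for size in range(len(nodes) + 1):
        for combo in itertools.combinations(nodes, size):
            cover = set(combo)
            if all(a in cover or b in cover for a, b in edges):
                return cover
    return set(nodes)


def filter_loci(
    matrix: GenotypeMatrix,
    hwe_alpha: float = 0.05,
    ld_alpha: float = 0.05,
    seed: int | None = None,
    hwe_bonferroni: bool = False,
    ld_bonferroni: bool = True,
    chain_steps: int = 100_000,
    dememorization: int = 10_000,
    n_permutations: int = 200,
    em_starts: int = 5,
    removal: str = "random",
) -> FilterResult:
    """HWE and LD locus filtering.

    Loci deviating from HWE (at raw ``hwe_alpha`` by default, or after
    sequential Bonferroni with ``hwe_bonferroni=True``) are removed first.
    Pairwise LD p-values among the remaining loci are corrected by
    sequential Bonferroni (default) and one randomly chosen locus of each
    remaining significant pair is removed iteratively until no significant
    pair is left.  ``removal='min-cover'`` instead removes a minimum
    vertex cover of the significance graph (fewest loci; brute force for
    up to 20 involved loci, greedy beyond).
    """
    if seed is None:
        raise ValueError("seed is required (HWE chain, LD permutations, removal)")
    rng = np.random.default_rng(seed)

    from .popgen import heterozygosity

    het = heterozygosity(matrix).set_index("locus_id")
    reports = []
    hwe_p: dict[str, float] = {}
    for locus in matrix.locus_ids:
        calls = matrix.locus_calls(locus)
        mono = bool(het.loc[locus, "monomorphic"]) if locus in het.index else True
        p = float("nan")
        if not mono:
            p = hwe_test(
                calls,
                chain_steps=chain_steps,
                dememorization=dememorization,
                seed=int(rng.integers(2**31)),
            )
            hwe_p[locus] = p
        reports.append(
            {
                "locus_id": locus,
                "ho": float(het.loc[locus, "ho"]) if locus in het.index else float("nan"),
                "he": float(het.loc[locus, "he"]) if locus in het.index else float("nan"),
                "hwe_p": p,
                "monomorphic": mono,
                "excluded_reason": "none",
            }
        )
    rep = pd.DataFrame(reports).set_index("locus_id")

    tested = list(hwe_p)
    pvals = np.array([hwe_p[l] for l in tested])
    if hwe_bonferroni:
        out_of_hwe = set(np.array(tested)[sequential_bonferroni(pvals, hwe_alpha)])
    else:
        out_of_hwe = {l for l, p in hwe_p.items() if p < hwe_alpha}
    for locus in out_of_hwe:
        rep.loc[locus, "excluded_reason"] = "hwe"
    retained = [l for l in matrix.locus_ids if l not in out_of_hwe and not rep.loc[l, "monomorphic"]]

    # pairwise LD among retained loci
    pair_rows = []
    for la, lb in itertools.combinations(retained, 2):
        ca = matrix.calls[:, matrix.locus_ids.index(la), :]
        cb = matrix.calls[:, matrix.locus_ids.index(lb), :]
        keep = (ca[:, 0] != MISSING) & (cb[:, 0] != MISSING)
        ga, gb = ca[keep], cb[keep]
        if np.unique(ga).size < 2 or np.unique(gb).size < 2:
            continue
        lrt, p, _ = ld_test(
            ga,
            gb,
            n_permutations=n_permutations,
            em_starts=em_starts,
            seed=int(rng.integers(2**31)),
        )
        pair_rows.append({"locus_a": la, "locus_b": lb, "lrt": lrt, "p": p})
    pairs = pd.DataFrame(pair_rows, columns=["locus_a", "locus_b", "lrt", "p"])
    if len(pairs):
        if ld_bonferroni:
            pairs["significant"] = sequential_bonferroni(pairs["p"].to_numpy(), ld_alpha)
        else:
            pairs["significant"] = pairs["p"].to_numpy() < ld_alpha
    else:
        pairs["significant"] = pd.Series(dtype=bool)

    sig_edges = [
        (r.locus_a, r.locus_b) for r in pairs.itertuples() if r.significant
    ]
    removed_ld: set[str] = set()
    if sig_edges:
        if removal == "min-cover":
            involved = {v for e in sig_edges for v in e}
            if len(involved) <= 20:
                removed_ld = _min_vertex_cover(sig_edges)
            else:
                logger.warning("min-cover on >20 loci: falling back to greedy")
                edges = list(sig_edges)
                while edges:
                    degree = pd.Series([v for e in edges for v in e]).value_counts()
                    top = degree.index[0]
                    removed_ld.add(top)
                    edges = [e for e in edges if top not in e]
        elif removal == "random":
            edges = list(sig_edges)
            while edges:
                a, b = edges[0]
                drop = a if rng.random() < 0.5 else b
                removed_ld.add(drop)
                edges = [e for e in edges if drop not in e]
        else:
            raise ValueError(f"unknown removal mode {removal!r}")
    for locus in removed_ld:
        rep.loc[locus, "excluded_reason"] = "ld"
    retained = [l for l in retained if l not in removed_ld]
    return FilterResult(
        retained=retained, reports=rep.reset_index(), ld_pairs=pairs
    )


def select_snp_panel(
    candidates: pd.DataFrame,
    maf_floor: float = 0.2,
    spacing: int = 50,
    bin_edges: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5),
    bin_quotas: tuple[int, ...] = (20, 40, 40),
) -> pd.DataFrame:
    """Select a genotyping panel from a SNP candidate table.

    Exclusion rules: MAF below ``maf_floor``; more than two alleles; any
    other candidate within ``spacing`` bp up- or downstream on the same
    scaffold (both members of a close pair are dropped — the neighbour
    spoils assay primer design regardless of its own MAF or allele count,
    so spacing is checked against the full candidate list).  Survivors are
    binned by MAF (left-open intervals over ``bin_edges``), ranked by
    quality descending within bins, and picked up to each bin's quota with
    at most one SNP per scaffold across the whole panel.  A warning is
    logged when a bin cannot fill its quota.

    ``candidates`` columns: scaffold_id, position (1-based), alleles
    (list), maf, quality.
    """
    required = {"scaffold_id", "position", "alleles", "maf", "quality"}
    if not required.issubset(candidates.columns):
        raise ValueError(f"candidate table must have columns {sorted(required)}")
    if len(bin_quotas) != len(bin_edges) - 1:
        raise ValueError("bin_quotas must have one entry per MAF bin")
    df = candidates.copy()
    if (df["position"] <= 0).any():
        raise ValueError("positions must be positive (1-based)")
    if (df["maf"] > 0.5).any():
        raise ValueError("MAF cannot exceed 0.5")

    # spacing: drop every SNP with any neighbour within `spacing` bp,
    # judged against the full candidate list
    keep_idx = []
    for _, group in df.groupby("scaffold_id"):
        pos = group["position"].sort_values()
        diffs_prev = pos.diff()
        diffs_next = pos.diff(-1).abs()
        ok = ~((diffs_prev <= spacing) | (diffs_next <= spacing))
        keep_idx.extend(pos.index[ok])
    df = df.loc[sorted(keep_idx)]
    df = df[df["maf"] >= maf_floor]
    df = df[df["alleles"].map(len) == 2]

    selected = []
    used_scaffolds: set = set()
    for lo, hi, quota in zip(bin_edges[:-1], bin_edges[1:], bin_quotas):
        in_bin = df[(df["maf"] > lo) & (df["maf"] <= hi)].sort_values(
            ["quality", "scaffold_id", "position"], ascending=[False, True, True]
        )
        taken = 0
        for row in in_bin.itertuples():
            if taken >= quota:
                break
            if row.scaffold_id in used_scaffolds:
                continue
            selected.append(row.Index)
            used_scaffolds.add(row.scaffold_id)
            taken += 1
        if taken < quota:
            logger.warning(
                "MAF bin (%.1f, %.1f]: only %d of %d candidates available",
                lo, hi, taken, quota,
            )
    return candidates.loc[selected]


def titv_ratio(candidates: pd.DataFrame) -> float:
    """Transition:transversion ratio of biallelic nucleotide candidates.

    Transitions are A<->G and C<->T.  Returns NaN (with a warning) when no
    transversions are present.  Random allele pairs would give 1:2 (ratio
    0.5); real SNP calls typically exceed 2.
    """
    n_ti = n_tv = 0
    for alleles in candidates["alleles"]:
        pair = [str(a).upper() for a in alleles]
        if len(pair) != 2:
            continue
        if not set(pair) <= set("ACGT"):
            raise ValueError(f"non-nucleotide alleles: {pair}")
        if frozenset(pair) in _TRANSITIONS:
            n_ti += 1
        else:
            n_tv += 1
    if n_tv == 0:
        logger.warning("no transversions: Ti/Tv undefined")
        return float("nan")
    return n_ti / n_tv
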