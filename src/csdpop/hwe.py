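"""Exact tests of Hardy–Weinberg equilibrium.

The conditional null distribution of a genotype table given its allele
counts is

    P(table) = n! * prod_a(n_a!) * 2^H / ((2n)! * prod_{i<=j} n_ij!)

with H the number of heterozygotes.  The exact-test p-value is the total
probability of tables no more probable than the observed one.  Two routes
are provided: full enumeration for biallelic loci, and a Markov chain for
the general case.  The chain operates on random pairings of the labelled
allele copies — single-swap proposals with uniform stationary distribution
over pairings, which induces exactly the conditional null on tables — so
its estimate converges to the enumeration value.
"""

from __future__ import annotations

from math import lgamma

import numpy as np
from scipy.special import gammaln

__all__ = ["genotype_counts", "hwe_exact_biallelic", "hwe_test"]

_REL_TOL = 1e-9  # tables whose log-probability ties the observed one count


def genotype_counts(calls: np.ndarray) -> dict[tuple[int, int], int]:
    """Genotype count table from (n, 2) non-missing calls (sorted pairs)."""
    calls = np.asarray(calls)
    out: dict[tuple[int, int], int] = {}
    for a, b in np.sort(calls, axis=1):
        key = (int(a), int(b))
        out[key] = out.get(key, 0) + 1
    return out


def _log_table_stat(table: dict[tuple[int, int], int]) -> float:
    """log(2^H / prod n_ij!) — the table-dependent part of P(table)."""
    h = sum(n for (a, b), n in table.items() if a != b)
    return h * np.log(2.0) - sum(gammaln(n + 1) for n in table.values())


def hwe_exact_biallelic(calls: np.ndarray) -> float:
    """Exact HWE p-value for a biallelic locus by full enumeration.

    Enumerates every genotype table compatible with the observed allele
    counts (parameterized by the heterozygote count) and sums the
    probabilities of tables no more probable than the observed one.
    """
    calls = np.asarray(calls)
    alleles = np.unique(calls)
    if alleles.size != 2:
        raise ValueError(f"need exactly 2 alleles, got {alleles.size}")
    n = calls.shape[0]
    n_a = int((calls == alleles[0]).sum())
    n_b = 2 * n - n_a
    h_obs = int((calls[:, 0] != calls[:, 1]).sum())

    def log_prob(h: int) -> float:
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        return (
            h * np.log(2.0)
            - gammaln(naa + 1)
            - gammaln(h + 1)
            - gammaln(nbb + 1)
        )

    h_values = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    logs = np.array([log_prob(h) for h in h_values])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[list(h_values).index(h_obs)]
    return float(probs[probs <= obs * (1 + _REL_TOL)].sum())


def hwe_test(
    calls: np.ndarray,
    chain_steps: int = 1_000_000,
    dememorization: int = 100_000,
    seed: int | None = None,
) -> float:
    """Markov-chain exact HWE test for a locus with any number of alleles.

    ``calls``: (n, 2) non-missing genotype calls.  Raises on monomorphic
    loci (the test is undefined there).
    """
    calls = np.asarray(calls)
    if calls.ndim != 2 or calls.shape[1] != 2:
        raise ValueError("calls must have shape (n, 2)")
    alleles = np.unique(calls)
    if alleles.size < 2:
        raise ValueError("HWE test undefined for a monomorphic locus")
    if seed is None:
        raise ValueError("seed is required for the Markov chain")
    rng = np.random.default_rng(seed)

    obs_stat = _log_table_stat(genotype_counts(calls))

    # chain state: flat array of 2n allele copies; consecutive pairs are
    # genotypes.  Uniform random transpositions keep the uniform
    # distribution over labelled pairings, whose induced table law is the
    # conditional null.
    flat = calls.ravel().copy()
    n2 = flat.size
    table = genotype_counts(flat.reshape(-1, 2))
    stat = _log_table_stat(table)

    log2 = float(np.log(2.0))
    flat_list = [int(x) for x in flat]

    def remove(p: int) -> float:
        a, b = flat_list[2 * p], flat_list[2 * p + 1]
        g = (a, b) if a <= b else (b, a)
        n = table[g]
        if n == 1:
            del table[g]
        else:
            table[g] = n - 1
        return -(log2 if a != b else 0.0) + lgamma(n + 1) - lgamma(n)

    def add(p: int) -> float:
        a, b = flat_list[2 * p], flat_list[2 * p + 1]
        g = (a, b) if a <= b else (b, a)
        n = table.get(g, 0) + 1
        table[g] = n
        return (log2 if a != b else 0.0) - lgamma(n + 1) + lgamma(n)

    total_steps = dememorization + chain_steps
    picks = rng.integers(0, n2, size=(total_steps, 2))
    hits = 0
    threshold = obs_stat + abs(obs_stat) * _REL_TOL + 1e-12
    for t in range(total_steps):
        i, j = int(picks[t, 0]), int(picks[t, 1])
        pi, pj = i // 2, j // 2
        if pi != pj and flat_list[i] != flat_list[j]:
            stat += remove(pi) + remove(pj)
            flat_list[i], flat_list[j] = flat_list[j], flat_list[i]
            stat += add(pi) + add(pj)
        if t >= dememorization and stat <= threshold:
            hits += 1
    return hits / chain_steps
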