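"""Linkage-disequilibrium test for unphased genotypic data.

Haplotype frequencies for a pair of loci are estimated by
expectation–maximization over the unknown phases (best of several random
starts), and association is measured by the likelihood-ratio statistic
2*(logL(haplotype frequencies) - logL(allele-frequency product)).
Significance comes from permuting one locus's genotypes between
individuals, which preserves single-locus genotype frequencies while
destroying gametic association.

Individuals are aggregated into weighted two-locus genotype classes (at
most 9 for a pair of SNPs) before the EM, so each iteration costs O(number
of distinct genotype pairs) rather than O(sample size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EMResult", "em_haplotype_freqs", "ld_test"]


@dataclass
class EMResult:
    freqs: np.ndarray  # (k_a, k_b) haplotype frequency matrix
    loglik: float
    converged: bool
    alleles_a: np.ndarray
    alleles_b: np.ndarray


class _PairData:
    """Weighted genotype-class representation of a two-locus sample."""

    def __init__(self, ga: np.ndarray, gb: np.ndarray, ka: int, kb: int):
        # genotype code: sorted allele index pair
        ga = np.sort(ga, axis=1)
        gb = np.sort(gb, axis=1)
        code_a = ga[:, 0] * ka + ga[:, 1]
        code_b = gb[:, 0] * kb + gb[:, 1]
        joint = code_a * (kb * kb) + code_b
        classes, weights = np.unique(joint, return_counts=True)
        cb = classes % (kb * kb)
        ca = classes // (kb * kb)
        self.a1, self.a2 = ca // ka, ca % ka
        self.b1, self.b2 = cb // kb, cb % kb
        self.w = weights.astype(float)
        self.double_het = (self.a1 != self.a2) & (self.b1 != self.b2)
        self.n = ga.shape[0]
        self.ka, self.kb = ka, kb

    def loglik(self, h: np.ndarray) -> float:
        p1 = h[self.a1, self.b1] * h[self.a2, self.b2]
        p2 = h[self.a1, self.b2] * h[self.a2, self.b1]
        lik = np.where(self.double_het, p1 + p2, p1)
        return float(np.sum(self.w * np.log(np.maximum(lik, 1e-300))))

    def em(self, h: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, float, bool]:
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            p1 = h[self.a1, self.b1] * h[self.a2, self.b2]
            p2 = h[self.a1, self.b2] * h[self.a2, self.b1]
            tot = np.maximum(np.where(self.double_het, p1 + p2, p1), 1e-300)
            w1 = self.w * np.where(self.double_het, p1 / tot, 1.0)
            w2 = self.w * np.where(self.double_het, p2 / tot, 0.0)
            new = np.zeros_like(h)
            np.add.at(new, (self.a1, self.b1), w1)
            np.add.at(new, (self.a2, self.b2), w1)
            np.add.at(new, (self.a1, self.b2), w2)
            np.add.at(new, (self.a2, self.b1), w2)
            h = new / (2 * self.n)
            ll = self.loglik(h)
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        return h, self.loglik(h), converged

    def allele_freqs(self) -> tuple[np.ndarray, np.ndarray]:
        pa = np.zeros(self.ka)
        pb = np.zeros(self.kb)
        np.add.at(pa, self.a1, self.w)
        np.add.at(pa, self.a2, self.w)
        np.add.at(pb, self.b1, self.w)
        np.add.at(pb, self.b2, self.w)
        return pa / (2 * self.n), pb / (2 * self.n)


def _encode(genos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    alleles, inv = np.unique(genos, return_inverse=True)
    return alleles, inv.reshape(genos.shape)


def _best_em(
    pair: _PairData, n_starts: int, rng: np.random.Generator,
    tol: float = 1e-10, max_iter: int = 500,
) -> tuple[np.ndarray, float, bool]:
    """Best-likelihood EM solution over random starts plus the
    allele-frequency-product start."""
    pa, pb = pair.allele_freqs()
    inits = [np.outer(pa, pb)]
    for _ in range(n_starts):
        h0 = rng.random((pair.ka, pair.kb))
        inits.append(h0 / h0.sum())
    best = None
    for h0 in inits:
        h, ll, conv = pair.em(h0, tol, max_iter)
        if best is None or ll > best[1]:
            best = (h, ll, conv)
    return best


def em_haplotype_freqs(
    genos_a: np.ndarray,
    genos_b: np.ndarray,
    n_starts: int = 5,
    seed: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> EMResult:
    """EM estimate of two-locus haplotype frequencies from unphased calls.

    ``genos_a``/``genos_b``: (n, 2) non-missing calls at each locus for
    the same individuals.  On samples without double heterozygotes, phase
    is certain and the EM fixed point equals direct haplotype counting.
    """
    rng = np.random.default_rng(seed)
    al_a, ga = _encode(np.asarray(genos_a))
    al_b, gb = _encode(np.asarray(genos_b))
    pair = _PairData(ga, gb, al_a.size, al_b.size)
    h, ll, conv = _best_em(pair, n_starts, rng)
    return EMResult(h, ll, conv, al_a, al_b)


def _lrt(pair: _PairData, em_starts: int, rng: np.random.Generator) -> tuple[float, bool]:
    h, ll, conv = _best_em(pair, em_starts, rng)
    pa, pb = pair.allele_freqs()
    ll_indep = pair.loglik(np.outer(pa, pb))
    return 2.0 * (ll - ll_indep), conv


def ld_test(
    genos_a: np.ndarray,
    genos_b: np.ndarray,
    n_permutations: int = 1000,
    em_starts: int = 5,
    seed: int | None = None,
    perm_em_starts: int = 1,
) -> tuple[float, float, bool]:
    """Likelihood-ratio LD test between two loci (unknown phase).

    Returns (LRT statistic, permutation p-value, EM converged flag).
    p = (#{permuted LRT >= observed} + 1) / (n_permutations + 1);
    permutations shuffle locus-b genotypes between individuals.  The
    observed statistic uses ``em_starts`` random EM restarts; permuted
    replicates use the cheaper ``perm_em_starts`` (the allele-frequency
    product start is always included, and for two SNPs the likelihood is
    effectively unimodal).
    """
    genos_a = np.asarray(genos_a)
    genos_b = np.asarray(genos_b)
    al_a, ga = _encode(genos_a)
    al_b, gb = _encode(genos_b)
    if al_a.size < 2 or al_b.size < 2:
        raise ValueError("both loci must be polymorphic")
    if seed is None:
        raise ValueError("seed is required for the permutation test")
    rng = np.random.default_rng(seed)
    obs, converged = _lrt(_PairData(ga, gb, al_a.size, al_b.size), em_starts, rng)
    exceed = 0
    n = ga.shape[0]
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        stat, _ = _lrt(_PairData(ga, gb[perm], al_a.size, al_b.size), perm_em_starts, rng)
        if stat >= obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return obs, p, converged
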