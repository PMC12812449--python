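"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately written as plain scalar loops, straight
from the published definitions, sharing no code with the implementations
under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def pi_brute_force(alleles: list[int]) -> float:
    """Mean pairwise difference over an explicit chromosome list."""
    pairs = list(combinations(range(len(alleles)), 2))
    if not pairs:
        return float("nan")
    diff = sum(1 for i, j in pairs if alleles[i] != alleles[j])
    return diff / len(pairs)


def tajimas_d_textbook(S: int, pi_total: float, n: int) -> float:
    """Tajima's D via the published constant chain, scalar arithmetic."""
    if S < 1 or n < 4:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1.0))
    if denom == 0:
        return float("nan")
    return (pi_total - S / a1) / denom


def wc_fst_site(n_list, p_list, h_list):
    """Per-site Weir & Cockerham (1984) variance components (a, b, c).

    Scalar translation of the published estimator: n_list are diploid
    sample sizes, p_list allele frequencies, h_list observed heterozygote
    fractions, one entry per population (populations with n = 0 must be
    excluded by the caller).
    """
    r = len(n_list)
    nbar = sum(n_list) / r
    nc = (r * nbar - sum(n * n for n in n_list) / (r * nbar)) / (r - 1.0)
    pbar = sum(n * p for n, p in zip(n_list, p_list)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_list, p_list)) / ((r - 1.0) * nbar)
    hbar = sum(n * h for n, h in zip(n_list, h_list)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst_matrix(gt_by_pop: dict[str, np.ndarray]) -> np.ndarray:
    """Per-site theta-hat from 0/1/2/-1 genotype blocks, via wc_fst_site."""
    n_sites = next(iter(gt_by_pop.values())).shape[0]
    out = np.full(n_sites, np.nan)
    for i in range(n_sites):
        n_list, p_list, h_list = [], [], []
        for block in gt_by_pop.values():
            g = block[i]
            called = g[g >= 0]
            if len(called) == 0:
                continue
            n_list.append(float(len(called)))
            p_list.append(float(called.sum()) / (2.0 * len(called)))
            h_list.append(float((called == 1).sum()) / len(called))
        if len(n_list) < 2 or sum(n_list) / len(n_list) <= 1:
            continue
        a, b, c = wc_fst_site(n_list, p_list, h_list)
        if a + b + c != 0:
            out[i] = a / (a + b + c)
    return out


def anova_f_scipy(groups: dict[str, list[float]]):
    """Independent route for the one-way ANOVA F statistic."""
    from scipy.stats import f_oneway

    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    res = f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def wf_absorption_probability(two_n: int, start: int, generations: int) -> float:
    """P(not yet fixed or lost) after t generations, exact Markov chain.

    Brute-force transition matrix on the 2N+1 count states of a
    Wright-Fisher binomial update.
    """
    states = two_n + 1
    T = np.zeros((states, states))
    for i in range(states):
        p = i / two_n
        for j in range(states):
            T[i, j] = math.comb(two_n, j) * p**j * (1 - p) ** (two_n - j)
    v = np.zeros(states)
    v[start] = 1.0
    for _ in range(generations):
        v = v @ T
    return float(v[1:-1].sum())


def private_allele_sets(gt_by_pop: dict[str, np.ndarray]) -> dict[str, int]:
    """Explicit per-allele membership-set computation of private alleles."""
    n_sites = next(iter(gt_by_pop.values())).shape[0]
    counts = {pop: 0 for pop in gt_by_pop}
    for i in range(n_sites):
        for allele in (0, 1):
            holders = []
            for pop, block in gt_by_pop.items():
                g = block[i]
                called = g[g >= 0]
                n_allele = (
                    (2 * len(called) - called.sum()) if allele == 0 else called.sum()
                )
                if n_allele > 0:
                    holders.append(pop)
            if len(holders) == 1:
                counts[holders[0]] += 1
    return counts
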