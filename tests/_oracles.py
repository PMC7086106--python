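"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (enumeration, direct
summation) and deliberately shares no code with the package internals it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# marker summaries
# ---------------------------------------------------------------------------


def pic_direct(p) -> float:
    """PIC by the literal double sum over allele pairs."""
    p = list(p)
    k = len(p)
    out = 1.0 - sum(pi**2 for pi in p)
    for i in range(k):
        for j in range(i + 1, k):
            out -= 2.0 * p[i] ** 2 * p[j] ** 2
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (biallelic enumeration)
# ---------------------------------------------------------------------------


def hwe_exact_biallelic(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional HWE p-value for two alleles, enumerating every
    heterozygote count compatible with the observed allele counts."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def prob(het: int) -> float:
        aa = (n_a - het) // 2
        bb = n - aa - het
        num = (
            math.lgamma(n + 1)
            + math.lgamma(n_a + 1)
            + math.lgamma(2 * n - n_a + 1)
            + het * math.log(2.0)
        )
        den = (
            math.lgamma(2 * n + 1)
            + math.lgamma(aa + 1)
            + math.lgamma(het + 1)
            + math.lgamma(bb + 1)
        )
        return math.exp(num - den)

    p_obs = prob(n_ab)
    total = 0.0
    p_sum = 0.0
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        q = prob(het)
        total += q
        if q <= p_obs * (1 + 1e-9):
            p_sum += q
    return min(1.0, p_sum / total)


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by enumerating all 2x2 tables with the observed
    margins and summing hypergeometric probabilities <= the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        q = prob(x)
        if q <= p_obs * (1 + 1e-9):
            total += q
    return min(1.0, total)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (sign-pattern enumeration)
# ---------------------------------------------------------------------------


def wilcoxon_exact_enumeration(diffs) -> tuple[float, float]:
    """(W+, two-sided exact p) by enumerating all 2^n sign assignments of
    the absolute differences (requires no zero differences and no ties)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    order = np.argsort(np.abs(d))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    dev_obs = abs(w_obs - mean_w)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mean_w) >= dev_obs - 1e-9:
            count += 1
    return float(w_obs), count / 2.0**n


# ---------------------------------------------------------------------------
# dyadic likelihood: gene-level enumeration per IBD mode
# ---------------------------------------------------------------------------


def _match(g, pair) -> bool:
    return tuple(sorted(g)) == tuple(sorted(pair))


def dyad_locus_prob(g1, g2, p, weights) -> float:
    """P(G1, G2) under mode weights (k0, k1, k2) by direct summation over
    the underlying gene draws of each identity mode."""
    k0, k1, k2 = weights
    k = len(p)
    p0 = p1 = p2 = 0.0
    # k0: four independent genes
    for x, y, u, v in itertools.product(range(k), repeat=4):
        if _match(g1, (x, y)) and _match(g2, (u, v)):
            p0 += p[x] * p[y] * p[u] * p[v]
    # k1: one shared gene, one private gene each
    for x, y, z in itertools.product(range(k), repeat=3):
        if _match(g1, (x, y)) and _match(g2, (x, z)):
            p1 += p[x] * p[y] * p[z]
    # k2: both genes shared
    for x, y in itertools.product(range(k), repeat=2):
        if _match(g1, (x, y)) and _match(g2, (x, y)):
            p2 += p[x] * p[y]
    return k0 * p0 + k1 * p1 + k2 * p2


def dyad_loglik_enumeration(g1_calls, g2_calls, loci, weights) -> float:
    total = 0.0
    for li, locus in enumerate(loci):
        a = tuple(int(x) for x in g1_calls[li])
        b = tuple(int(x) for x in g2_calls[li])
        if a[0] < 0 or b[0] < 0:
            continue
        total += math.log(dyad_locus_prob(a, b, locus.frequencies, weights))
    return total


# ---------------------------------------------------------------------------
# trio likelihood: full state-space enumeration
# ---------------------------------------------------------------------------


def _hwe_prob(g, p) -> float:
    i, j = g
    return p[i] ** 2 if i == j else 2 * p[i] * p[j]


def _obs_prob(obs, true, p, dropout, misprint) -> float:
    """P(observed genotype | true genotype) under dropout then misprint."""
    i, j = true
    if i == j:
        drop = 1.0 if _match(obs, true) else 0.0
    else:
        if _match(obs, true):
            drop = 1.0 - dropout
        elif obs[0] == obs[1] and obs[0] in (i, j):
            drop = dropout / 2.0
        else:
            drop = 0.0
    return (1.0 - misprint) * drop + misprint * _hwe_prob(tuple(sorted(obs)), p)


def _transmit(allele, g) -> float:
    return ((g[0] == allele) + (g[1] == allele)) / 2.0


def trio_locus_lik(obs_o, obs_m, obs_f, p, dropout, misprint) -> float:
    """P(obs_o | obs_m, obs_f) summing over every true-genotype state of
    the trio, conditioning the parents on their own observations."""
    k = len(p)
    genos = [(i, j) for i in range(k) for j in range(i, k)]

    def posterior(obs):
        if obs is None:
            return {g: _hwe_prob(g, p) for g in genos}
        w = {g: _hwe_prob(g, p) * _obs_prob(obs, g, p, dropout, misprint) for g in genos}
        z = sum(w.values())
        return {g: v / z for g, v in w.items()}

    post_m = posterior(obs_m)
    post_f = posterior(obs_f)
    total = 0.0
    for gm in genos:
        for gf in genos:
            for go in genos:
                a, b = go
                trans = _transmit(a, gm) * _transmit(b, gf)
                if a != b:
                    trans += _transmit(b, gm) * _transmit(a, gf)
                total += (
                    post_m[gm]
                    * post_f[gf]
                    * trans
                    * _obs_prob(obs_o, go, p, dropout, misprint)
                )
    return total


def trio_loglik_enumeration(o_calls, m_calls, f_calls, loci, dropout, misprint) -> float:
    total = 0.0
    for li, locus in enumerate(loci):
        obs_o = tuple(int(x) for x in o_calls[li])
        if obs_o[0] < 0:
            continue
        obs_m = tuple(int(x) for x in m_calls[li]) if m_calls is not None else None
        obs_f = tuple(int(x) for x in f_calls[li])
        if obs_m is not None and obs_m[0] < 0:
            obs_m = None
        if obs_f[0] < 0:
            obs_f = None
        lik = trio_locus_lik(obs_o, obs_m, obs_f, locus.frequencies, dropout, misprint)
        if lik == 0.0:
            return -math.inf
        total += math.log(lik)
    return total


# ---------------------------------------------------------------------------
# Nonacs' B and its exact null
# ---------------------------------------------------------------------------


def nonacs_b_direct(benefits, residence, n_max) -> float:
    """B evaluated symbol by symbol from the printed formula."""
    K = sum(benefits)
    N_t = sum(residence)
    N_bar = N_t / n_max
    b = 0.0
    for x, n_i in zip(benefits, residence):
        b += (x / K - n_i / N_t) ** 2
    return b - (1.0 - 1.0 / N_bar) / K


def nonacs_exact_p(benefits, residence, n_max) -> float:
    """One-tailed P(B_null >= B_obs) by exhaustive enumeration of the
    multinomial allocation of K benefits (tiny K, N only)."""
    K = int(sum(benefits))
    N = len(benefits)
    pi = np.asarray(residence, dtype=float)
    pi = pi / pi.sum()
    b_obs = nonacs_b_direct(benefits, residence, n_max)
    p = 0.0
    for combo in itertools.product(range(K + 1), repeat=N):
        if sum(combo) != K:
            continue
        logq = math.lgamma(K + 1)
        for x, q in zip(combo, pi):
            logq += x * math.log(q) - math.lgamma(x + 1)
        if nonacs_b_direct(list(combo), residence, n_max) >= b_obs - 1e-12:
            p += math.exp(logq)
    return p


# ---------------------------------------------------------------------------
# OLS slope
# ---------------------------------------------------------------------------


def ols_slope(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    return float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
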