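"""Independent brute-force oracles used only by the test suite.

These are deliberately written as plain per-site scalar transcriptions of
the published formulas (loops, no vectorisation, no shared code with the
package) so they can serve as an independent check of the production
implementations.
"""

from __future__ import annotations

import math


def brute_wc_site(genos_a: list[int], genos_b: list[int]):
    """Weir & Cockerham (1984) a, b, c for one biallelic site and two diploid
    population samples; genotypes are alt-allele counts, -1 = missing.

    Returns (a, b, c) or None when the site is unusable (a population with no
    called genotype, or average sample size of one).
    """
    ga = [g for g in genos_a if g >= 0]
    gb = [g for g in genos_b if g >= 0]
    n1, n2 = len(ga), len(gb)
    if n1 < 1 or n2 < 1:
        return None
    r = 2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return None
    p1 = sum(ga) / (2 * n1)
    p2 = sum(gb) / (2 * n2)
    h1 = sum(1 for g in ga if g == 1) / n1
    h2 = sum(1 for g in gb if g == 1) / n2
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    ssq = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        ssq - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ssq * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ssq * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def brute_pbs(fst_ab: float, fst_ac: float, fst_bc: float) -> float:
    """Direct transcription of the branch-statistic formula."""

    def t(f):
        f = min(max(f, 0.0), 1 - 1e-8)
        return -math.log(1 - f)

    return (t(fst_ab) + t(fst_ac) - t(fst_bc)) / 2


def busing_jackknife(num_blocks: list[float], den_blocks: list[float],
                     m_blocks: list[int]):
    """Weighted delete-one block jackknife (Busing et al. 1999) for a ratio
    statistic, written from the published formulas."""
    g = len(num_blocks)
    n = sum(m_blocks)
    tot_n, tot_d = sum(num_blocks), sum(den_blocks)
    theta = tot_n / tot_d
    theta_j = [(tot_n - num_blocks[j]) / (tot_d - den_blocks[j]) for j in range(g)]
    h = [n / m_blocks[j] for j in range(g)]
    theta_jack = g * theta - sum((1 - m_blocks[j] / n) * theta_j[j] for j in range(g))
    var = 0.0
    for j in range(g):
        tau = h[j] * theta - (h[j] - 1) * theta_j[j]
        var += (tau - theta_jack) ** 2 / (h[j] - 1)
    var /= g
    return theta, math.sqrt(var)


def brute_r2(x: list[float], y: list[float]) -> float:
    """Squared Pearson correlation via the textbook sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return (sxy * sxy) / (sxx * syy)
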