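"""Independent brute-force oracles used to validate the vectorized
implementations.  Each oracle is written against the defining formulas with
no shared code path: exact rational arithmetic where the definition is
exact, plain double loops where it is combinatorial.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def wc_theta_exact(counts1: tuple[int, int, int], counts2: tuple[int, int, int]
                   ) -> Fraction | None:
    """Weir-Cockerham (1984) two-population theta from genotype counts
    (ref-hom, het, alt-hom) using exact rational arithmetic; None when the
    locus is monomorphic in both populations (a+b+c = 0)."""
    n1, n2 = Fraction(sum(counts1)), Fraction(sum(counts2))
    p1 = Fraction(counts1[1] + 2 * counts1[2], 2 * sum(counts1))
    p2 = Fraction(counts2[1] + 2 * counts2[2], 2 * sum(counts2))
    h1 = Fraction(counts1[1], sum(counts1))
    h2 = Fraction(counts2[1], sum(counts2))
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * Fraction(r - 1, r) - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * Fraction(r - 1, r)
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        return None
    return a / denom


def di_bruteforce(theta: np.ndarray) -> np.ndarray:
    """Per-locus d_i by plain loops: per reference column compute mean/sd over
    defined (finite) entries, then sum the standardized terms, skipping
    undefined entries."""
    n_loci, n_pairs = theta.shape
    means, sds = [], []
    for k in range(n_pairs):
        col = [theta[j, k] for j in range(n_loci) if np.isfinite(theta[j, k])]
        m = sum(col) / len(col)
        var = sum((x - m) ** 2 for x in col) / (len(col) - 1)
        means.append(m)
        sds.append(var ** 0.5)
    di = np.zeros(n_loci)
    for j in range(n_loci):
        for k in range(n_pairs):
            if np.isfinite(theta[j, k]) and sds[k] > 0:
                di[j] += (theta[j, k] - means[k]) / sds[k]
    return di


def empirical_p_bruteforce(di: np.ndarray) -> np.ndarray:
    """O(N^2) tail proportion: P_E(j) = #{k : d_k >= d_j} / N."""
    n = len(di)
    return np.array([sum(1 for k in range(n) if di[k] >= di[j]) / n for j in range(n)])


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by exhaustive enumeration
    of all tables with the observed margins, summing the exact hypergeometric
    probabilities of tables as or less probable than observed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p_x <= p_obs:
            total += p_x
    return total


def overlap_bruteforce(positions: list[int],
                       intervals: list[tuple[int, int, float]]
                       ) -> list[tuple[bool, float | None]]:
    """All-pairs scan: 1-based pos overlaps 0-based half-open [s, e)."""
    out = []
    for pos in positions:
        hit = None
        for s, e, score in intervals:
            if s <= pos - 1 < e:
                hit = score
                break
        out.append((hit is not None, hit))
    return out


def pair_r2_bruteforce(x: np.ndarray, y: np.ndarray, missing: int = -1) -> float:
    """Single-pair squared correlation from first principles."""
    pairs = [(float(a), float(b)) for a, b in zip(x, y) if a != missing and b != missing]
    n = len(pairs)
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a, _ in pairs)
    syy = sum((b - my) ** 2 for _, b in pairs)
    if sxx == 0 or syy == 0:
        return float("nan")
    return (sxy * sxy) / (sxx * syy)
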