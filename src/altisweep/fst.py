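"""Per-locus unbiased pairwise F_ST via Weir & Cockerham (1984) variance
components, plus the per-pair genome-wide moments that standardize the
breed-differentiation statistic.

For two populations with sample sizes n_1, n_2 diploids, alt-allele
frequencies p_1, p_2 and observed heterozygote frequencies h_1, h_2 at a
biallelic locus, with r = 2,

    n_bar = (n_1 + n_2) / 2
    n_c   = (r*n_bar - sum n_i^2 / (r*n_bar)) / (r - 1)
    p_bar = sum n_i p_i / (r*n_bar)
    s2    = sum n_i (p_i - p_bar)^2 / ((r-1)*n_bar)
    h_bar = sum n_i h_i / (r*n_bar)

    a = (n_bar/n_c) * [s2 - (p_bar(1-p_bar) - s2*(r-1)/r - h_bar/4) / (n_bar-1)]
    b = (n_bar/(n_bar-1)) * [p_bar(1-p_bar) - s2*(r-1)/r - h_bar*(2n_bar-1)/(4n_bar)]
    c = h_bar / 2

and theta = a / (a + b + c).  Negative per-locus theta values are retained
(not truncated at zero), since truncation would bias the moments used for
standardization.  A locus monomorphic for the same allele in both
populations has a + b + c = 0 and is undefined, flagged rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class FstComponents:
    """Weir-Cockerham variance components and their ratio for one locus."""

    a: float
    b: float
    c: float
    theta: float
    defined: bool = True


def _components_arrays(n1, p1, h1, n2, p2, h2):
    """Vectorized two-population components; inputs are broadcastable arrays of
    diploid counts, alt frequencies and observed heterozygote frequencies."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1, h1 = np.asarray(p1, dtype=float), np.asarray(h1, dtype=float)
    p2, h2 = np.asarray(p2, dtype=float), np.asarray(h2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r
                                     - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0.0, a / np.where(denom != 0.0, denom, 1.0), np.nan)
    return a, b, c, theta


def wc_fst_locus(counts1: tuple[int, int, int], counts2: tuple[int, int, int]) -> FstComponents:
    """Components from genotype counts (n_ref_hom, n_het, n_alt_hom) per population.

    Raises on an empty population; a locus monomorphic for the same allele in
    both populations returns an undefined sentinel.
    """
    n1, n2 = sum(counts1), sum(counts2)
    if n1 == 0 or n2 == 0:
        raise ValueError("each population needs at least one genotyped diploid")
    p1 = (counts1[1] + 2 * counts1[2]) / (2 * n1)
    p2 = (counts2[1] + 2 * counts2[2]) / (2 * n2)
    h1, h2 = counts1[1] / n1, counts2[1] / n2
    a, b, c, theta = _components_arrays(n1, p1, h1, n2, p2, h2)
    defined = bool(np.isfinite(theta))
    return FstComponents(float(a), float(b), float(c),
                         float(theta) if defined else float("nan"), defined)


@dataclass
class PairwiseFstTable:
    """Per-locus theta (and components) of one focal population against each reference."""

    focal: str
    references: list[str]
    locus_ids: list[str]
    theta: np.ndarray        # loci x references, NaN where undefined
    a: np.ndarray            # same shape; variance components for ratio-of-sums
    abc: np.ndarray          # a + b + c

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.theta)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.theta, columns=self.references)
        df.insert(0, "locus", self.locus_ids)
        return df


def _pop_locus_stats(matrix: GenotypeMatrix, population: str):
    """Per-locus (n diploids, alt frequency, het frequency) for one population."""
    d = matrix.dosage[matrix.sample_indices(population), :]
    present = d != MISSING
    n = present.sum(axis=0).astype(float)
    alt = np.where(present, d, 0).sum(axis=0)
    het = np.where(present, d == 1, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def pairwise_fst_table(matrix: GenotypeMatrix, focal: str,
                       references: list[str]) -> PairwiseFstTable:
    """Per-locus Weir-Cockerham theta for the focal population against every
    reference; missing genotypes are dropped per locus per population."""
    if focal in references:
        raise ValueError("focal population may not appear among references")
    if not references:
        raise ValueError("at least one reference population required")
    nf, pf, hf = _pop_locus_stats(matrix, focal)
    theta = np.empty((matrix.n_loci, len(references)))
    a_arr = np.empty_like(theta)
    abc_arr = np.empty_like(theta)
    for k, ref in enumerate(references):
        nr, pr, hr = _pop_locus_stats(matrix, ref)
        if not np.any(nr >= 2):
            raise ValueError(f"reference {ref!r} has <2 genotyped diploids at every locus")
        ok = (nf > 0) & (nr > 0)
        a, b, c, th = _components_arrays(np.where(ok, nf, 1), np.where(ok, pf, 0.5),
                                         np.where(ok, hf, 0.5), np.where(ok, nr, 1),
                                         np.where(ok, pr, 0.5), np.where(ok, hr, 0.5))
        theta[:, k] = np.where(ok, th, np.nan)
        a_arr[:, k] = np.where(ok, a, np.nan)
        abc_arr[:, k] = np.where(ok, a + b + c, np.nan)
    return PairwiseFstTable(focal=focal, references=list(references),
                            locus_ids=[l.id for l in matrix.loci],
                            theta=theta, a=a_arr, abc=abc_arr)


@dataclass(frozen=True)
class FstMoments:
    """Genome-wide mean and sample standard deviation of per-locus theta for
    each (focal, reference) pair, over defined loci only."""

    references: list[str]
    mean_fst: np.ndarray
    sd_fst: np.ndarray
    n_defined: np.ndarray


def fst_moments(table: PairwiseFstTable) -> FstMoments:
    mask = table.defined_mask
    n_def = mask.sum(axis=0)
    if np.any(n_def < 2):
        bad = [table.references[k] for k in np.flatnonzero(n_def < 2)]
        raise ValueError(f"pairs with <2 defined loci: {bad}")
    means = np.nanmean(table.theta, axis=0)
    sds = np.nanstd(table.theta, axis=0, ddof=1)
    return FstMoments(references=list(table.references), mean_fst=means,
                      sd_fst=sds, n_defined=n_def)


def multilocus_fst(table: PairwiseFstTable, reference: str) -> float:
    """Genome-wide ratio-of-sums estimator sum(a) / sum(a+b+c) over defined
    loci for one reference pair — not the mean of per-locus ratios."""
    k = table.references.index(reference)
    mask = table.defined_mask[:, k]
    if not mask.any():
        raise ValueError("no defined loci for this pair")
    return float(np.nansum(table.a[mask, k]) / np.nansum(table.abc[mask, k]))


def multilocus_fst_matrix(matrix: GenotypeMatrix, pop1: str, pop2: str) -> float:
    """Ratio-of-sums theta for an arbitrary population pair of a genotype matrix."""
    table = pairwise_fst_table(matrix, pop1, [pop2])
    return multilocus_fst(table, pop2)
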