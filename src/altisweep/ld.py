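"""Linkage disequilibrium utilities: pairwise genotype r^2, sliding-window
pruning, and distance-binned decay curves.

All statistics are genotype-based (composite) r^2 — the squared Pearson
correlation of alt-allele dosage vectors — since no phased haplotypes are
available for array data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, minor_allele_frequencies

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDResult:
    locus_i: str
    locus_j: str
    r2: float
    distance_bp: int | None
    defined: bool = True


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors after dropping pairs
    with any missing value; NaN when either vector is monomorphic."""
    keep = (x != MISSING) & (y != MISSING)
    x, y = x[keep].astype(float), y[keep].astype(float)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_r2(matrix: GenotypeMatrix, locus_i: str, locus_j: str,
          population: str | None = None) -> LDResult:
    """Genotype r^2 between two loci, over one population or all samples.

    Monomorphic loci (after dropping incomplete pairs) yield an undefined,
    flagged result rather than an exception.
    """
    ji, jj = matrix.locus_index(locus_i), matrix.locus_index(locus_j)
    rows = matrix.sample_indices(population) if population else np.arange(matrix.n_samples)
    r2 = _pair_r2(matrix.dosage[rows, ji], matrix.dosage[rows, jj])
    li, lj = matrix.loci[ji], matrix.loci[jj]
    dist = abs(li.pos - lj.pos) if li.chrom == lj.chrom else None
    return LDResult(locus_i, locus_j, r2, dist, defined=not np.isnan(r2))


def ld_prune(matrix: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5,
             r2_threshold: float = 0.2) -> list[str]:
    """Sliding-window LD pruning in map order (PLINK ``--indep-pairwise`` style).

    Within each window of ``window_snps`` retained loci (advanced by
    ``step_snps``), while any retained pair has r^2 > ``r2_threshold`` one
    member is removed: the one with the lower minor allele frequency, ties
    going to the later locus in map order.  Returns retained locus ids; after
    completion no retained pair inside any window exceeds the threshold.
    """
    if step_snps > window_snps:
        raise ValueError(f"step_snps {step_snps} > window_snps {window_snps}")
    maf = minor_allele_frequencies(matrix.dosage)
    keep = np.ones(matrix.n_loci, dtype=bool)
    for start in range(0, max(matrix.n_loci - window_snps + 1, 1), step_snps):
        idx = [j for j in range(start, min(start + window_snps, matrix.n_loci)) if keep[j]]
        changed = True
        while changed:
            changed = False
            for a in range(len(idx)):
                ja = idx[a]
                if not keep[ja]:
                    continue
                for b in range(a + 1, len(idx)):
                    jb = idx[b]
                    if not keep[jb]:
                        continue
                    if matrix.loci[ja].chrom != matrix.loci[jb].chrom:
                        continue
                    r2 = _pair_r2(matrix.dosage[:, ja], matrix.dosage[:, jb])
                    if not np.isnan(r2) and r2 > r2_threshold:
                        # drop the lower-MAF member; tie -> later in map order
                        drop = ja if maf[ja] < maf[jb] else jb
                        keep[drop] = False
                        changed = True
                        break
                if changed:
                    break
    retained = [matrix.loci[j].id for j in np.flatnonzero(keep)]
    logger.info("ld_prune: retained %d of %d loci", len(retained), matrix.n_loci)
    return retained


def ld_decay_curve(matrix: GenotypeMatrix, population: str | None,
                   distance_bins: np.ndarray) -> pd.DataFrame:
    """Mean genotype r^2 per physical-distance bin.

    Every same-chromosome locus pair contributes its r^2 to the bin of its bp
    distance (bins are ``distance_bins`` edges, right-open, final bin closed).
    Empty bins are reported with count 0 and NaN mean.
    """
    edges = np.asarray(distance_bins, dtype=float)
    rows = matrix.sample_indices(population) if population else np.arange(matrix.n_samples)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    by_chrom: dict[str, list[int]] = {}
    for j, l in enumerate(matrix.loci):
        by_chrom.setdefault(l.chrom, []).append(j)
    for chrom_loci in by_chrom.values():
        for a in range(len(chrom_loci)):
            for b in range(a + 1, len(chrom_loci)):
                ja, jb = chrom_loci[a], chrom_loci[b]
                dist = abs(matrix.loci[ja].pos - matrix.loci[jb].pos)
                k = np.searchsorted(edges, dist, side="right") - 1
                if k == len(edges) - 1 and dist == edges[-1]:
                    k -= 1
                if not 0 <= k < len(edges) - 1:
                    continue
                r2 = _pair_r2(matrix.dosage[rows, ja], matrix.dosage[rows, jb])
                if not np.isnan(r2):
                    sums[k] += r2
                    counts[k] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "bin_start": edges[:-1].astype(int),
        "bin_end": edges[1:].astype(int),
        "n_pairs": counts,
        "mean_r2": means,
    })
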