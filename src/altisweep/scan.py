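"""The breed-differentiation selection scan: the d_i statistic, empirical
p-values, top-fraction outlier calling and sweep-region merging.

For a focal population i and reference populations j, the per-locus statistic

    d_i = sum_j ( F_ST(i,j) - E[F_ST(i,j)] ) / sd[F_ST(i,j)]

standardizes each pairwise theta by that pair's genome-wide mean and
standard deviation and sums over references, so large d_i flags loci where
the focal population is unusually differentiated from many references at
once.  Significance is empirical: P_E(locus) is the fraction of loci whose
d_i is >= this locus's value, and loci with P_E strictly below the
significance proportion (default 0.005, the top 0.5%) are candidates.
Candidates within the merge gap (default 500 kb, inclusive) of each other on
a chromosome are chained into single sweep regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst import FstMoments, PairwiseFstTable, fst_moments, pairwise_fst_table
from .genotypes import GenotypeMatrix, minor_allele_frequencies

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    significance_proportion: float = 0.005
    merge_gap_bp: int = 500_000

    def __post_init__(self) -> None:
        if not 0.0 < self.significance_proportion < 1.0:
            raise ValueError("significance_proportion must be in (0, 1)")
        if self.merge_gap_bp < 0:
            raise ValueError("merge_gap_bp must be >= 0")


@dataclass
class DiScanResult:
    """Per-locus d_i, empirical p and significance flag for one focal population."""

    focal: str
    locus_ids: list[str]
    di: np.ndarray
    pe: np.ndarray
    significant: np.ndarray
    z_terms: np.ndarray = field(repr=False, default=None)  # loci x pairs, for audit

    def to_frame(self, matrix: GenotypeMatrix | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"locus": self.locus_ids, "di": self.di,
                           "pe": self.pe, "significant": self.significant})
        if matrix is not None:
            pos = {l.id: (l.chrom, l.pos) for l in matrix.loci}
            df.insert(1, "chrom", [pos[i][0] for i in self.locus_ids])
            df.insert(2, "pos", [pos[i][1] for i in self.locus_ids])
        return df


def di_statistic(table: PairwiseFstTable, moments: FstMoments) -> np.ndarray:
    """Per-locus d_i from a pairwise theta table and per-pair moments.

    Pairs with undefined theta at a locus contribute 0 to that locus's sum;
    a pair with zero genome-wide sd contributes 0 everywhere (with a warning)
    rather than aborting the scan.
    """
    if table.references != moments.references:
        raise ValueError("moments computed on different reference pairs than the table")
    sd = moments.sd_fst.copy()
    # a constant column can realize sd ~ 1e-17 through rounding; treat it as 0
    zero_sd = sd <= 1e-12 * np.maximum(1.0, np.abs(moments.mean_fst))
    if zero_sd.any():
        logger.warning("pairs with zero sd of F_ST contribute 0 to d_i: %s",
                       [table.references[k] for k in np.flatnonzero(zero_sd)])
        sd[zero_sd] = 1.0
    z = (table.theta - moments.mean_fst[None, :]) / sd[None, :]
    z[:, zero_sd] = 0.0
    z = np.where(np.isfinite(z), z, 0.0)  # undefined-theta pairs contribute 0
    return z.sum(axis=1), z


def empirical_p(di: np.ndarray) -> np.ndarray:
    """P_E(locus) = #{k : d_k >= d_locus} / N over the finite values.

    Ties share one P_E; non-finite inputs are excluded from N (with a
    warning) and get P_E = NaN.
    """
    di = np.asarray(di, dtype=float)
    finite = np.isfinite(di)
    if not finite.any():
        raise ValueError("no finite d_i values")
    if not finite.all():
        logger.warning("excluding %d non-finite d_i values from the empirical distribution",
                       int((~finite).sum()))
    vals = np.sort(di[finite])
    n = vals.size
    pe = np.full(di.shape, np.nan)
    # count of values >= d  ==  n - (index of first value >= d)
    pe[finite] = (n - np.searchsorted(vals, di[finite], side="left")) / n
    return pe


def significant_loci(pe: np.ndarray, config: ScanConfig = ScanConfig()) -> np.ndarray:
    """Boolean mask of loci with P_E strictly below the significance proportion.

    With N distinct values this selects the top k where k is the largest
    integer with k/N < proportion (219 of 43,835 at 0.005).
    """
    with np.errstate(invalid="ignore"):
        return np.asarray(pe) < config.significance_proportion


@dataclass(frozen=True)
class SweepRegion:
    chrom: str
    start_bp: int
    end_bp: int
    locus_ids: tuple[str, ...]

    @property
    def n_snps(self) -> int:
        return len(self.locus_ids)

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp


def merge_regions(loci: list[tuple[str, str, int]],
                  config: ScanConfig = ScanConfig()) -> list[SweepRegion]:
    """Single-linkage chaining of significant loci into sweep regions.

    ``loci`` is a list of (locus_id, chrom, pos).  Consecutive position-sorted
    loci on one chromosome whose gap is <= ``merge_gap_bp`` (inclusive) join
    one region; region bounds are the member min/max positions, so a
    singleton forms a width-0 region.  Output is sorted by (chrom, start).
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for lid, chrom, pos in loci:
        by_chrom.setdefault(chrom, []).append((pos, lid))
    regions: list[SweepRegion] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom])
        run: list[tuple[int, str]] = [members[0]]
        for pos, lid in members[1:]:
            if pos - run[-1][0] <= config.merge_gap_bp:
                run.append((pos, lid))
            else:
                regions.append(SweepRegion(chrom, run[0][0], run[-1][0],
                                           tuple(l for _, l in run)))
                run = [(pos, lid)]
        regions.append(SweepRegion(chrom, run[0][0], run[-1][0],
                                   tuple(l for _, l in run)))
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return regions


def scan_maf_filter(matrix: GenotypeMatrix, focal: str, references: list[str],
                    min_maf: float = 0.05) -> GenotypeMatrix:
    """Restrict to loci with pooled minor-allele frequency >= ``min_maf`` over
    the union of the scan populations (focal plus references)."""
    rows = np.concatenate([matrix.sample_indices(p) for p in [focal] + references])
    maf = minor_allele_frequencies(matrix.dosage[rows, :])
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= min_maf))
    return matrix.subset(locus_idx=keep)


def run_scan(matrix: GenotypeMatrix, focal: str, references: list[str],
             config: ScanConfig = ScanConfig(), min_scan_maf: float = 0.05,
             ) -> tuple[DiScanResult, list[SweepRegion]]:
    """End-to-end scan for one focal population: pooled-MAF filter, pairwise
    theta table, per-pair moments, d_i, empirical p, outlier calling and
    region merging.  Invariant to sample and locus order."""
    if not references:
        raise ValueError("at least one reference population required")
    m = scan_maf_filter(matrix, focal, references, min_scan_maf)
    table = pairwise_fst_table(m, focal, references)
    moments = fst_moments(table)
    di, z = di_statistic(table, moments)
    pe = empirical_p(di)
    sig = significant_loci(pe, config)
    result = DiScanResult(focal=focal, locus_ids=table.locus_ids, di=di, pe=pe,
                          significant=sig, z_terms=z)
    sig_loci = [(l.id, l.chrom, l.pos) for l, s in zip(m.loci, sig) if s]
    regions = merge_regions(sig_loci, config) if sig_loci else []
    return result, regions


def regions_to_bed(regions: list[SweepRegion]) -> pd.DataFrame:
    """BED-style frame (0-based half-open) from 1-based inclusive region bounds."""
    return pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [r.start_bp - 1 for r in regions],
        "end": [r.end_bp for r in regions],
        "n_snps": [r.n_snps for r in regions],
    })
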