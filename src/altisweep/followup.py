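"""Candidate-region follow-up on a dense re-sequencing panel: per-site group
allele counts from a VCF, a pooled-MAF site filter, Fisher's exact
group-divergence test, gene-model annotation, conserved-element overlap, and
an altitude-gradient allele-frequency summary.

Coordinate conventions: VCF and gene-model positions are 1-based; the
conservation track is 0-based half-open (BED), and a site at 1-based
position ``pos`` overlaps an interval [start, end) iff start <= pos-1 < end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteCounts:
    """Alt-allele copies and total non-missing chromosomes per group at one site."""

    pos: int
    ref: str
    alt: str
    alt1: int
    tot1: int
    alt2: int
    tot2: int

    def __post_init__(self) -> None:
        if self.alt1 > self.tot1 or self.alt2 > self.tot2:
            raise ValueError(f"site {self.pos}: alt copies exceed chromosomes")


@dataclass
class ResequencingPanel:
    """Re-sequencing variant panel over one region with two named sample groups."""

    region: tuple[str, int, int]
    group_names: tuple[str, str]
    group_sizes: tuple[int, int]          # diploids per group
    sites: list[SiteCounts]

    def __post_init__(self) -> None:
        chrom, start, end = self.region
        if start >= end:
            raise ValueError("region start must be < end")
        poss = [s.pos for s in self.sites]
        if poss != sorted(poss):
            raise ValueError("sites must be sorted by position")
        for s in self.sites:
            if not start <= s.pos <= end:
                raise ValueError(f"site {s.pos} outside region {start}-{end}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pos": [s.pos for s in self.sites],
            "ref": [s.ref for s in self.sites],
            "alt": [s.alt for s in self.sites],
            f"alt_{self.group_names[0]}": [s.alt1 for s in self.sites],
            f"tot_{self.group_names[0]}": [s.tot1 for s in self.sites],
            f"alt_{self.group_names[1]}": [s.alt2 for s in self.sites],
            f"tot_{self.group_names[1]}": [s.tot2 for s in self.sites],
        })


def read_panel_vcf(vcf_path: str, groups: dict[str, list[str]],
                   region: tuple[str, int, int] | None = None) -> ResequencingPanel:
    """Build a :class:`ResequencingPanel` from a VCF v4.x with GT fields.

    ``groups`` maps two group names to sample-id lists.  Missing genotypes are
    excluded from denominators; non-biallelic or non-SNV records are skipped
    with a log message.  Raises if an assigned sample is absent from the VCF.
    """
    from cyvcf2 import VCF

    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    idx: dict[str, np.ndarray] = {}
    for name, members in groups.items():
        missing = [s for s in members if s not in vcf_samples]
        if missing:
            raise ValueError(f"samples {missing} in group {name!r} absent from VCF")
        idx[name] = np.array([vcf_samples.index(s) for s in members])
    (g1, g2) = groups
    sites: list[SiteCounts] = []
    chrom_seen, min_pos, max_pos = None, None, None
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            logger.warning("skipping non-biallelic-SNV record at %s:%d", rec.CHROM, rec.POS)
            continue
        gt = np.asarray(rec.gt_types)  # 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        counts = []
        for name in (g1, g2):
            g = gt[idx[name]]
            ok = g != 3
            counts.append((int(g[ok].sum()), int(2 * ok.sum())))
        (a1, t1), (a2, t2) = counts
        sites.append(SiteCounts(pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
                                alt1=a1, tot1=t1, alt2=a2, tot2=t2))
        chrom_seen = rec.CHROM
        min_pos = rec.POS if min_pos is None else min(min_pos, rec.POS)
        max_pos = rec.POS if max_pos is None else max(max_pos, rec.POS)
    if region is None:
        region = (chrom_seen or "NA", (min_pos or 1) - 1 or 1, (max_pos or 2) + 1)
    return ResequencingPanel(region=region, group_names=(g1, g2),
                             group_sizes=(len(groups[g1]), len(groups[g2])),
                             sites=sites)


def site_maf_filter(panel: ResequencingPanel, min_maf: float = 0.05) -> ResequencingPanel:
    """Retain sites whose pooled minor-allele frequency across both groups is
    strictly greater than ``min_maf``."""
    kept = []
    for s in panel.sites:
        tot = s.tot1 + s.tot2
        if tot == 0:
            continue
        p = (s.alt1 + s.alt2) / tot
        if min(p, 1 - p) > min_maf:
            kept.append(s)
    return ResequencingPanel(region=panel.region, group_names=panel.group_names,
                             group_sizes=panel.group_sizes, sites=kept)


@dataclass(frozen=True)
class SiteTestResult:
    pos: int
    p_value: float
    freq1: float
    freq2: float
    significant: bool
    fixed_in_group1: bool
    segregating_in_group2: bool
    degenerate: bool = False


def fisher_exact_site(counts: SiteCounts, threshold: float = 0.001) -> SiteTestResult:
    """Two-sided Fisher's exact test of the 2x2 table (alt, ref) x (group1, group2).

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins that are as or less probable than the observed table.
    A zero margin (site monomorphic overall, or a group with no calls) gives
    p = 1 and is flagged degenerate.  "Fixed" means all chromosomes in the
    group carry one allele; "segregating" means both alleles are observed.
    """
    table = [[counts.alt1, counts.tot1 - counts.alt1],
             [counts.alt2, counts.tot2 - counts.alt2]]
    degenerate = (counts.alt1 + counts.alt2 == 0
                  or (counts.tot1 - counts.alt1) + (counts.tot2 - counts.alt2) == 0
                  or counts.tot1 == 0 or counts.tot2 == 0)
    if degenerate:
        p = 1.0
    else:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        p = min(p, 1.0)
    f1 = counts.alt1 / counts.tot1 if counts.tot1 else math.nan
    f2 = counts.alt2 / counts.tot2 if counts.tot2 else math.nan
    return SiteTestResult(
        pos=counts.pos, p_value=p, freq1=f1, freq2=f2,
        significant=p < threshold,
        fixed_in_group1=counts.tot1 > 0 and counts.alt1 in (0, counts.tot1),
        segregating_in_group2=0 < counts.alt2 < counts.tot2,
        degenerate=degenerate,
    )


def divergence_scan(panel: ResequencingPanel, threshold: float = 0.001
                    ) -> list[SiteTestResult]:
    """Fisher's exact test at every site of a (MAF-filtered) panel, sorted by
    position; significance is p strictly below ``threshold``.  Sites with all
    genotypes missing in a group are excluded with a log message."""
    out = []
    for s in panel.sites:
        if s.tot1 == 0 or s.tot2 == 0:
            logger.warning("site %d: a group has no called genotypes; excluded", s.pos)
            continue
        out.append(fisher_exact_site(s, threshold))
    return out


# ---------------------------------------------------------------------------
# Gene-model annotation and conservation overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: transcript span, exons and start-codon position (1-based)."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    start_codon_pos: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        lo, hi = self.span
        prev_end = None
        for s, e in self.exons:
            if not (lo <= s <= e <= hi):
                raise ValueError("exon outside transcript span")
            if prev_end is not None and s <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if not lo <= self.start_codon_pos <= hi:
            raise ValueError("start codon outside span")


def classify_site(model: GeneModel, chrom: str, pos: int, flank_bp: int = 5_000) -> tuple[str, int | None]:
    """Classify a 1-based position relative to a gene model.

    Returns (class, distance) where class is ``exonic``, ``intronic``,
    ``upstream``, ``downstream`` or ``intergenic``.  Upstream/downstream
    distances are measured from the start codon, respecting strand, and a
    site farther than ``flank_bp`` from the transcript span is intergenic.
    """
    if chrom != model.chrom:
        return "intergenic", None
    lo, hi = model.span
    if lo <= pos <= hi:
        for s, e in model.exons:
            if s <= pos <= e:
                return "exonic", None
        return "intronic", None
    if not (lo - flank_bp <= pos <= hi + flank_bp):
        return "intergenic", None
    before_codon = pos < model.start_codon_pos if model.strand == "+" else pos > model.start_codon_pos
    dist = abs(pos - model.start_codon_pos)
    return ("upstream", dist) if before_codon else ("downstream", dist)


@dataclass(frozen=True)
class ConservationTrack:
    """Sorted 0-based half-open conserved-element intervals with scores."""

    chrom: str
    intervals: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        prev = -1
        for s, e, _ in self.intervals:
            if s >= e:
                raise ValueError("interval start must be < end")
            if s < prev:
                raise ValueError("intervals must be sorted by start")
            prev = s


def overlap_conserved(positions: list[int], track: ConservationTrack
                      ) -> list[tuple[bool, float | None]]:
    """Per-site conserved-element overlap flag and score.

    A 1-based site ``pos`` overlaps interval [start, end) iff
    start <= pos-1 < end.
    """
    out: list[tuple[bool, float | None]] = []
    for pos in positions:
        z = pos - 1
        hit: float | None = None
        for s, e, score in track.intervals:
            if s > z:
                break
            if s <= z < e:
                hit = score
                break
        out.append((hit is not None, hit))
    return out


# ---------------------------------------------------------------------------
# Altitude gradient
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientReport:
    populations: list[str]
    altitude_ranks: list[float]
    frequencies: list[float]
    spearman_rho: float
    monotone_increasing: bool
    defined: bool = True


def altitude_gradient_summary(freq_by_population: dict[str, tuple[float, float]]
                              ) -> GradientReport:
    """Summarize an allele-frequency gradient across populations ordered by
    altitude.

    ``freq_by_population`` maps population name to (altitude_rank, frequency).
    Reports the populations sorted by altitude rank, the Spearman rank
    correlation between altitude and frequency (midranks for ties), and
    whether the sorted frequencies increase strictly.  Constant frequencies
    give an undefined correlation, flagged and reported as 0.
    """
    if len(freq_by_population) < 3:
        raise ValueError("need >= 3 populations with altitude ranks")
    items = sorted(freq_by_population.items(), key=lambda kv: kv[1][0])
    pops = [k for k, _ in items]
    ranks = [v[0] for _, v in items]
    freqs = [v[1] for _, v in items]
    if len(set(freqs)) == 1 or len(set(ranks)) == 1:
        return GradientReport(pops, ranks, freqs, 0.0, False, defined=False)
    rho = float(stats.spearmanr(ranks, freqs).statistic)
    increasing = all(a < b for a, b in zip(freqs, freqs[1:]))
    return GradientReport(pops, ranks, freqs, rho, increasing)
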