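"""Synthetic genotype panels and re-sequencing panels with the statistical
structure the selection scan assumes.

Array panels follow the Balding-Nichols drift model: each locus draws an
ancestral frequency p from a bounded law, each population then draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) — mean p, variance p(1-p)F — and
genotypes are two independent allele draws (Hardy-Weinberg within
population).  The drift parameter F of a population equals its expected
fixation index against the ancestral pool, so a pair of populations with
drift F each realizes pairwise Weir-Cockerham theta near F.  Designated
sweep loci override the highland-population frequencies with a target value,
emulating an allele driven toward fixation by positive selection.

Re-sequencing panels emulate a dense variant window around a candidate gene:
a chosen fraction of sites is fixed for the alternate allele in the highland
group while still segregating in the lowland group; the remainder share one
frequency across groups.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, LocusInfo, SampleInfo
from .followup import ResequencingPanel, SiteCounts


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: all draws flow from one root seed, but each stage is
    independently reproducible."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    altitude_class: str          # "high" | "low"
    n_diploids: int
    drift_F: float

    def __post_init__(self) -> None:
        if not 0.0 < self.drift_F < 1.0:
            raise ValueError(f"{self.name}: drift_F must be in (0, 1), got {self.drift_F}")
        if self.n_diploids < 1:
            raise ValueError(f"{self.name}: n_diploids must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Array-panel simulation parameters.

    Defaults emulate a multi-breed SNP-array study: 12 populations (4
    highland, 8 lowland) of 15-37 diploids, 45,000 loci spread over 26
    autosomes, moderate drift so pairwise theta lands in the 0.08-0.20 range,
    ancestral frequencies uniform on (0.05, 0.95), and no sweeps unless
    requested.
    """

    n_loci: int = 45_000
    populations: tuple[PopulationSpec, ...] = tuple(
        [PopulationSpec(f"highland_{i+1}", "high", n, 0.06)
         for i, n in enumerate((15, 21, 30, 37))]
        + [PopulationSpec(f"lowland_{i+1}", "low", n, 0.06)
           for i, n in enumerate((18, 20, 24, 25, 27, 30, 33, 36))]
    )
    ancestral_freq_bounds: tuple[float, float] = (0.05, 0.95)
    sweep_loci: tuple[tuple[int, float], ...] = ()
    # per-locus ancestral frequency overrides, e.g. to pin a sweep locus's
    # lowland background frequency: ((locus_index, ancestral_freq), ...)
    ancestral_freq_overrides: tuple[tuple[int, float], ...] = ()
    n_chromosomes: int = 26
    locus_spacing_bp: int = 50_000
    missing_rate: float = 0.0
    ld_block_size: int = 1       # >1 duplicates loci with noise to create LD blocks
    ld_block_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_freq_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_bounds must satisfy 0 < lo < hi < 1")
        for idx, target in self.sweep_loci:
            if not 0 <= idx < self.n_loci:
                raise ValueError(f"sweep locus index {idx} out of range")
            if not 0.0 <= target <= 1.0:
                raise ValueError(f"sweep target {target} outside [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for idx, p in self.ancestral_freq_overrides:
            if not 0 <= idx < self.n_loci:
                raise ValueError(f"override locus index {idx} out of range")
            if not 0.0 < p < 1.0:
                raise ValueError(f"ancestral override {p} must be in (0, 1)")


def _locus_layout(config: SimulationConfig) -> list[LocusInfo]:
    per_chrom = -(-config.n_loci // config.n_chromosomes)  # ceil
    loci = []
    for j in range(config.n_loci):
        chrom = str(j // per_chrom + 1)
        pos = (j % per_chrom + 1) * config.locus_spacing_bp
        loci.append(LocusInfo(id=f"snp_{j:06d}", chrom=chrom, pos=pos,
                              allele_a1="A", allele_a2="G"))
    return loci


def _hw_genotypes(rng: np.random.Generator, freq: np.ndarray, n: int) -> np.ndarray:
    """n diploids x loci dosage from Hardy-Weinberg at per-locus alt frequency."""
    return (rng.binomial(1, freq, size=(n, freq.size))
            + rng.binomial(1, freq, size=(n, freq.size))).astype(np.int8)


def simulate_panel(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate a multi-population SNP-array panel; returns the genotype
    matrix and a truth table of injected sweep loci."""
    rng_anc = stage_rng(config.seed, "ancestral")
    lo, hi = config.ancestral_freq_bounds
    n_core = -(-config.n_loci // config.ld_block_size)
    p_anc = rng_anc.uniform(lo, hi, size=n_core)
    for idx, p in config.ancestral_freq_overrides:
        p_anc[idx // config.ld_block_size] = p

    sweep_targets = dict(config.sweep_loci)
    loci = _locus_layout(config)
    samples: list[SampleInfo] = []
    blocks: list[np.ndarray] = []
    for spec in config.populations:
        rng_pop = stage_rng(config.seed, f"pop:{spec.name}")
        F = spec.drift_F
        alpha = p_anc * (1.0 - F) / F
        beta = (1.0 - p_anc) * (1.0 - F) / F
        freq_core = rng_pop.beta(alpha, beta)
        g = _hw_genotypes(rng_pop, freq_core, spec.n_diploids)
        if config.ld_block_size > 1:
            # block-copy mode: duplicated genotype columns with per-entry
            # resampling noise give within-block r^2 near 1
            freq = np.repeat(freq_core, config.ld_block_size)[: config.n_loci]
            g = np.repeat(g, config.ld_block_size, axis=1)[:, : config.n_loci]
            if config.ld_block_noise > 0:
                flip = rng_pop.random(g.shape) < config.ld_block_noise
                redraw = _hw_genotypes(rng_pop, freq, spec.n_diploids)
                g = np.where(flip, redraw, g).astype(np.int8)
        if spec.altitude_class == "high":
            for idx, target in sweep_targets.items():
                g[:, idx] = (rng_pop.binomial(1, target, spec.n_diploids)
                             + rng_pop.binomial(1, target, spec.n_diploids))
        if config.missing_rate > 0:
            mask = rng_pop.random(g.shape) < config.missing_rate
            g[mask] = -1
        blocks.append(g)
        samples += [SampleInfo(id=f"{spec.name}_s{k:03d}", population=spec.name,
                               altitude_class=spec.altitude_class)
                    for k in range(spec.n_diploids)]
    matrix = GenotypeMatrix(samples=samples, loci=loci, dosage=np.vstack(blocks))
    truth = pd.DataFrame(
        {"locus_index": [i for i, _ in config.sweep_loci],
         "locus_id": [loci[i].id for i, _ in config.sweep_loci],
         "target_freq": [t for _, t in config.sweep_loci]}
    )
    return matrix, truth


def inject_sweep(matrix: GenotypeMatrix, locus_id: str, highland_target_freq: float,
                 rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Redraw every highland population's genotypes at one locus from
    Hardy-Weinberg at the target alt-allele frequency; lowland untouched."""
    if not 0.0 <= highland_target_freq <= 1.0:
        raise ValueError("target frequency must be in [0, 1]")
    rng = rng or np.random.default_rng(0)
    j = matrix.locus_index(locus_id)
    high_pops = [p for p in matrix.populations if matrix.altitude_class_of(p) == "high"]
    if not high_pops:
        raise ValueError("no highland population present")
    dosage = matrix.dosage.copy()
    for pop in high_pops:
        rows = matrix.sample_indices(pop)
        dosage[rows, j] = (rng.binomial(1, highland_target_freq, rows.size)
                           + rng.binomial(1, highland_target_freq, rows.size))
    return GenotypeMatrix(samples=list(matrix.samples), loci=list(matrix.loci),
                          dosage=dosage)


# ---------------------------------------------------------------------------
# Re-sequencing panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReseqConfig:
    """Dense-panel simulation: a window with highland-fixed / lowland-
    segregating divergent sites among shared-frequency background sites.

    Defaults mirror a candidate-gene window: ~400 sites in a ~77-kb region,
    4 highland vs 8 lowland diploids.
    """

    region: tuple[str, int, int] = ("7", 57_774_972, 57_846_735)
    n_sites: int = 400
    group_sizes: tuple[int, int] = (4, 8)   # (highland, lowland) diploids
    fraction_divergent: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        chrom, start, end = self.region
        if start >= end:
            raise ValueError("region start must be < end")
        if self.n_sites > end - start:
            raise ValueError("n_sites exceeds region length")
        if min(self.group_sizes) < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0.0 <= self.fraction_divergent <= 1.0:
            raise ValueError("fraction_divergent must be in [0, 1]")


_BASES = np.array(list("ACGT"))


def simulate_reseq_panel(config: ReseqConfig, vcf_path: str | None = None
                         ) -> tuple[ResequencingPanel, pd.DataFrame]:
    """Simulate a re-sequencing panel; optionally write it as a VCF v4.2 with
    GT fields.  Returns the panel and a per-site truth table."""
    rng = stage_rng(config.seed, "reseq")
    chrom, start, end = config.region
    positions = np.sort(rng.choice(np.arange(start, end + 1), size=config.n_sites,
                                   replace=False))
    n_div = int(round(config.fraction_divergent * config.n_sites))
    divergent = np.zeros(config.n_sites, dtype=bool)
    if n_div:
        divergent[rng.choice(config.n_sites, size=n_div, replace=False)] = True
    n_hi, n_lo = config.group_sizes

    sites: list[SiteCounts] = []
    gts_hi = np.empty((config.n_sites, n_hi), dtype=np.int8)
    gts_lo = np.empty((config.n_sites, n_lo), dtype=np.int8)
    refs, alts = [], []
    for i in range(config.n_sites):
        ref, alt = rng.choice(4, size=2, replace=False)
        refs.append(_BASES[ref])
        alts.append(_BASES[alt])
        if divergent[i]:
            gts_hi[i] = 2
            f_lo = rng.uniform(0.2, 0.8)
            while True:
                g = rng.binomial(1, f_lo, n_lo) + rng.binomial(1, f_lo, n_lo)
                if 0 < g.sum() < 2 * n_lo:   # strictly polymorphic in lowland
                    break
            gts_lo[i] = g
        else:
            f = rng.uniform(0.1, 0.9)
            gts_hi[i] = rng.binomial(1, f, n_hi) + rng.binomial(1, f, n_hi)
            gts_lo[i] = rng.binomial(1, f, n_lo) + rng.binomial(1, f, n_lo)
        sites.append(SiteCounts(pos=int(positions[i]), ref=str(refs[-1]), alt=str(alts[-1]),
                                alt1=int(gts_hi[i].sum()), tot1=2 * n_hi,
                                alt2=int(gts_lo[i].sum()), tot2=2 * n_lo))
    panel = ResequencingPanel(region=config.region, group_names=("highland", "lowland"),
                              group_sizes=config.group_sizes, sites=sites)
    truth = pd.DataFrame({"pos": positions, "divergent": divergent})
    if vcf_path is not None:
        write_panel_vcf(vcf_path, chrom, positions, refs, alts, gts_hi, gts_lo)
    return panel, truth


def write_panel_vcf(path: str, chrom: str, positions: np.ndarray, refs, alts,
                    gts_hi: np.ndarray, gts_lo: np.ndarray) -> list[str]:
    """Write per-sample GT records as VCF v4.2; returns sample names
    (highland samples first)."""
    n_hi, n_lo = gts_hi.shape[1], gts_lo.shape[1]
    names = [f"HI{k:02d}" for k in range(n_hi)] + [f"LO{k:02d}" for k in range(n_lo)]
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for i, pos in enumerate(positions):
            gts = [gt_str[int(g)] for g in gts_hi[i]] + [gt_str[int(g)] for g in gts_lo[i]]
            fh.write(f"{chrom}\t{int(pos)}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return names
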