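"""Diploid SNP-array genotype container, PLINK PED/MAP text I/O, and quality control.

Genotypes are stored as alt-allele dosages: the number of copies of the
second-listed allele (``allele_a2``) carried by each diploid, with ``MISSING``
(-1) as a distinguished sentinel that is never conflated with dosage 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

AltitudeClass = Literal["high", "low"]


class GenotypeParseError(ValueError):
    """Raised when a PED/MAP file is malformed; message names the offending line."""


@dataclass(frozen=True)
class LocusInfo:
    """One biallelic SNP: identifier, 1-based position and its two alleles."""

    id: str
    chrom: str
    pos: int
    allele_a1: str
    allele_a2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus {self.id}: position must be >= 1, got {self.pos}")
        if self.allele_a1 == self.allele_a2:
            raise ValueError(f"locus {self.id}: alleles must differ")


@dataclass(frozen=True)
class SampleInfo:
    """One diploid individual with its population and altitude class."""

    id: str
    population: str
    altitude_class: AltitudeClass = "low"

    def __post_init__(self) -> None:
        if not self.population:
            raise ValueError(f"sample {self.id}: population must be non-empty")
        if self.altitude_class not in ("high", "low"):
            raise ValueError(f"sample {self.id}: bad altitude_class {self.altitude_class!r}")


@dataclass
class GenotypeMatrix:
    """Samples x loci alt-allele dosage matrix with metadata.

    ``dosage[i, j]`` counts copies of ``loci[j].allele_a2`` in sample ``i``
    (0, 1, 2) or ``MISSING``.
    """

    samples: list[SampleInfo]
    loci: list[LocusInfo]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or MISSING")
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")
        pop_class: dict[str, str] = {}
        for s in self.samples:
            prev = pop_class.setdefault(s.population, s.altitude_class)
            if prev != s.altitude_class:
                raise ValueError(f"population {s.population} maps to two altitude classes")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population names in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.array([i for i, s in enumerate(self.samples) if s.population == population])
        if idx.size == 0:
            raise KeyError(f"population {population!r} not present")
        return idx

    def locus_index(self, locus_id: str) -> int:
        for j, l in enumerate(self.loci):
            if l.id == locus_id:
                return j
        raise KeyError(f"locus {locus_id!r} not present")

    def altitude_class_of(self, population: str) -> str:
        for s in self.samples:
            if s.population == population:
                return s.altitude_class
        raise KeyError(f"population {population!r} not present")

    def subset(self, sample_idx: Sequence[int] | None = None,
               locus_idx: Sequence[int] | None = None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            loci=[self.loci[j] for j in li],
            dosage=self.dosage[np.ix_(si, li)].copy(),
        )

    def loci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [l.id for l in self.loci],
                "chrom": [l.chrom for l in self.loci],
                "pos": [l.pos for l in self.loci],
                "a1": [l.allele_a1 for l in self.loci],
                "a2": [l.allele_a2 for l in self.loci],
            }
        )


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    # numeric chromosome labels sort numerically, others lexically after them
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def sort_loci(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Return a copy with loci sorted by (chrom, pos)."""
    order = sorted(
        range(matrix.n_loci),
        key=lambda j: (_chrom_sort_key(matrix.loci[j].chrom), matrix.loci[j].pos),
    )
    return matrix.subset(locus_idx=order)


# ---------------------------------------------------------------------------
# PED/MAP I/O
# ---------------------------------------------------------------------------

_PED_MISSING = "0"


def read_genotypes(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeMatrix`.

    The MAP file gives one locus per line (chrom, id, cM, bp); allele columns
    in the PED are interpreted against each locus's observed alleles, and the
    dosage counts copies of the second-listed (a2) allele.  The PED family
    column is taken as the population name; altitude class is read from a
    ``#altitude`` comment block at the top of the MAP file if present
    (``#altitude <population> <high|low>`` lines), defaulting to "low".

    Allele order per locus is taken from ``#alleles <id> <a1> <a2>`` comment
    lines when present (written by :func:`write_genotypes`); otherwise a1 is
    the first allele observed in the PED.
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    loci_raw: list[tuple[str, str, int]] = []
    altitude: dict[str, str] = {}
    allele_order: dict[str, tuple[str, str]] = {}
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 3 and parts[0] == "altitude":
                    altitude[parts[1]] = parts[2]
                elif len(parts) == 4 and parts[0] == "alleles":
                    allele_order[parts[1]] = (parts[2], parts[3])
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise GenotypeParseError(f"{map_path}:{lineno}: expected 3-4 columns, got {len(parts)}")
            chrom, snp_id = parts[0], parts[1]
            try:
                pos = int(parts[-1])
            except ValueError as exc:
                raise GenotypeParseError(f"{map_path}:{lineno}: bad position {parts[-1]!r}") from exc
            loci_raw.append((chrom, snp_id, pos))
    ids = [sid for _, sid, _ in loci_raw]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise GenotypeParseError(f"{map_path}: duplicate locus id {dup!r}")

    n_loci = len(loci_raw)
    samples: list[SampleInfo] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_loci:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} columns, got {len(parts)}"
                )
            fam, iid = parts[0], parts[1]
            samples.append(SampleInfo(id=iid, population=fam,
                                      altitude_class=altitude.get(fam, "low")))
            allele_pairs.append(list(zip(parts[6::2], parts[7::2])))

    # establish per-locus allele coding: first-seen allele is a1, second is a2
    loci: list[LocusInfo] = []
    dosage = np.full((len(samples), n_loci), MISSING, dtype=np.int8)
    for j, (chrom, sid, pos) in enumerate(loci_raw):
        alleles = list(allele_order.get(sid, ()))
        for row in allele_pairs:
            for a in row[j]:
                if a != _PED_MISSING and a not in alleles:
                    alleles.append(a)
        if len(alleles) > 2:
            raise GenotypeParseError(f"{ped_path}: locus {sid} has >2 alleles {alleles}")
        while len(alleles) < 2:
            # monomorphic or fully missing locus: pad with placeholder alleles
            alleles.append(next(c for c in "ACGTN*" if c not in alleles))
        a1, a2 = alleles
        loci.append(LocusInfo(id=sid, chrom=chrom, pos=pos, allele_a1=a1, allele_a2=a2))
        for i, row in enumerate(allele_pairs):
            x, y = row[j]
            if x == _PED_MISSING or y == _PED_MISSING:
                continue
            dosage[i, j] = (x == a2) + (y == a2)
    return sort_loci(GenotypeMatrix(samples=samples, loci=loci, dosage=dosage))


def write_genotypes(matrix: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write ``matrix`` as a PLINK text PED/MAP pair (readable by :func:`read_genotypes`)."""
    with open(map_path, "w") as fh:
        for pop in matrix.populations:
            fh.write(f"#altitude {pop} {matrix.altitude_class_of(pop)}\n")
        for l in matrix.loci:
            fh.write(f"#alleles {l.id} {l.allele_a1} {l.allele_a2}\n")
        for l in matrix.loci:
            fh.write(f"{l.chrom}\t{l.id}\t0\t{l.pos}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(matrix.samples):
            cols = [s.population, s.id, "0", "0", "0", "-9"]
            for j, l in enumerate(matrix.loci):
                d = matrix.dosage[i, j]
                if d == MISSING:
                    cols += [_PED_MISSING, _PED_MISSING]
                else:
                    cols += [l.allele_a1] * (2 - d) + [l.allele_a2] * d
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleFrequency:
    """Allele frequency with its counts; ``defined`` is False when every genotype is missing."""

    frequency: float
    copies: int
    chromosomes: int
    defined: bool = True


def allele_frequency(matrix: GenotypeMatrix, population: str, locus_id: str,
                     allele: str) -> AlleleFrequency:
    """Frequency of ``allele`` in ``population`` at ``locus_id``.

    Counts allele copies among non-missing chromosomes; an all-missing
    population yields an undefined (flagged) result rather than zero.
    """
    j = matrix.locus_index(locus_id)
    locus = matrix.loci[j]
    if allele not in (locus.allele_a1, locus.allele_a2):
        raise ValueError(f"allele {allele!r} not one of {locus.allele_a1}/{locus.allele_a2}")
    d = matrix.dosage[matrix.sample_indices(population), j]
    d = d[d != MISSING]
    if d.size == 0:
        return AlleleFrequency(frequency=float("nan"), copies=0, chromosomes=0, defined=False)
    alt_copies = int(d.sum())
    total = 2 * d.size
    copies = alt_copies if allele == locus.allele_a2 else total - alt_copies
    return AlleleFrequency(frequency=copies / total, copies=copies, chromosomes=total)


def alt_allele_frequencies(dosage: np.ndarray) -> np.ndarray:
    """Per-locus a2 frequency over a samples x loci dosage block (NaN where all missing)."""
    present = dosage != MISSING
    n = present.sum(axis=0)
    copies = np.where(present, dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, copies / (2 * n), np.nan)


def minor_allele_frequencies(dosage: np.ndarray) -> np.ndarray:
    p = alt_allele_frequencies(dosage)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """Locus and sample filter thresholds; all rules use strict inequalities."""

    min_call_rate: float = 0.90
    min_maf: float = 0.05
    max_locus_missing: float = 0.10
    max_sample_missing: float = 0.10
    autosomes_only: bool = False
    autosomes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "max_locus_missing", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.autosomes_only and not self.autosomes:
            raise ValueError("autosomes_only requires an explicit autosome label list")


@dataclass
class QCReport:
    """Every removal with its triggering rule, plus summary counts."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_loci: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", i, r) for i, r in self.removed_samples]
        rows += [("locus", i, r) for i, r in self.removed_loci]
        return pd.DataFrame(rows, columns=["kind", "id", "rule"])


def qc_filter(matrix: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
              ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply QC in the fixed order: sample missingness, locus call rate and
    missingness, minor allele frequency, then autosome restriction.

    A locus is removed when call rate < ``min_call_rate``, missingness
    > ``max_locus_missing``, or MAF < ``min_maf`` (computed after sample
    removal); a sample is removed when its missing fraction
    > ``max_sample_missing``.
    """
    report = QCReport()
    d = matrix.dosage
    miss = d == MISSING

    sample_missing = miss.mean(axis=1) if matrix.n_loci else np.zeros(matrix.n_samples)
    keep_s = sample_missing <= thresholds.max_sample_missing
    for i in np.flatnonzero(~keep_s):
        report.removed_samples.append(
            (matrix.samples[i].id, f"sample_missing {sample_missing[i]:.4f} > {thresholds.max_sample_missing}"))
    m = matrix.subset(sample_idx=np.flatnonzero(keep_s))

    keep_l = np.ones(m.n_loci, dtype=bool)
    if m.n_samples:
        call_rate = (m.dosage != MISSING).mean(axis=0)
        for j in np.flatnonzero(call_rate < thresholds.min_call_rate):
            keep_l[j] = False
            report.removed_loci.append(
                (m.loci[j].id, f"call_rate {call_rate[j]:.4f} < {thresholds.min_call_rate}"))
        locus_missing = 1.0 - call_rate
        for j in np.flatnonzero(keep_l & (locus_missing > thresholds.max_locus_missing)):
            keep_l[j] = False
            report.removed_loci.append(
                (m.loci[j].id, f"locus_missing {locus_missing[j]:.4f} > {thresholds.max_locus_missing}"))
        maf = minor_allele_frequencies(m.dosage)
        low = keep_l & ~np.isnan(maf) & (maf < thresholds.min_maf)
        for j in np.flatnonzero(low):
            keep_l[j] = False
            report.removed_loci.append((m.loci[j].id, f"maf {maf[j]:.4f} < {thresholds.min_maf}"))
        undef = keep_l & np.isnan(maf)
        for j in np.flatnonzero(undef):
            keep_l[j] = False
            report.removed_loci.append((m.loci[j].id, "all genotypes missing"))
    if thresholds.autosomes_only:
        for j in range(m.n_loci):
            if keep_l[j] and m.loci[j].chrom not in thresholds.autosomes:
                keep_l[j] = False
                report.removed_loci.append((m.loci[j].id, f"non-autosomal chrom {m.loci[j].chrom}"))
    return m.subset(locus_idx=np.flatnonzero(keep_l)), report


def flip_alleles(matrix: GenotypeMatrix, locus_id: str) -> GenotypeMatrix:
    """Return a copy with a1/a2 swapped (dosage 2-d) at one locus; used for
    symmetry checks and strand harmonisation."""
    j = matrix.locus_index(locus_id)
    loci = list(matrix.loci)
    l = loci[j]
    loci[j] = replace(l, allele_a1=l.allele_a2, allele_a2=l.allele_a1)
    dosage = matrix.dosage.copy()
    col = dosage[:, j]
    dosage[:, j] = np.where(col == MISSING, MISSING, 2 - col)
    return GenotypeMatrix(samples=list(matrix.samples), loci=loci, dosage=dosage)
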