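import numpy as np
import pytest

import altisweep as aw


@pytest.fixture
def tiny_matrix() -> aw.GenotypeMatrix:
    """Two populations, four loci, hand-written dosages (no missing data)."""
    samples = (
        [aw.SampleInfo(f"h{i}", "highland", "high") for i in range(4)]
        + [aw.SampleInfo(f"l{i}", "lowland", "low") for i in range(4)]
    )
    loci = [
        aw.LocusInfo("s1", "1", 100, "A", "G"),
        aw.LocusInfo("s2", "1", 200, "C", "T"),
        aw.LocusInfo("s3", "2", 150, "A", "C"),
        aw.LocusInfo("s4", "2", 900, "G", "T"),
    ]
    dosage = np.array([
        [2, 1, 0, 1],
        [2, 0, 1, 1],
        [1, 1, 0, 2],
        [2, 2, 0, 1],
        [0, 1, 2, 0],
        [0, 0, 2, 1],
        [1, 1, 1, 0],
        [0, 2, 2, 0],
    ], dtype=np.int8)
    return aw.GenotypeMatrix(samples=samples, loci=loci, dosage=dosage)


@pytest.fixture
def random_matrix() -> aw.GenotypeMatrix:
    """A moderate random panel with three populations and some missing data."""
    rng = np.random.default_rng(42)
    pops = [("popA", "high", 15), ("popB", "low", 20), ("popC", "low", 12)]
    samples = [aw.SampleInfo(f"{p}_{i}", p, alt) for p, alt, n in pops for i in range(n)]
    n_loci = 60
    loci = [aw.LocusInfo(f"m{j}", str(j // 20 + 1), 1000 * (j % 20 + 1), "A", "G")
            for j in range(n_loci)]
    freq = rng.uniform(0.1, 0.9, n_loci)
    dosage = (rng.binomial(1, freq, (len(samples), n_loci))
              + rng.binomial(1, freq, (len(samples), n_loci))).astype(np.int8)
    miss = rng.random(dosage.shape) < 0.03
    dosage[miss] = aw.MISSING
    return aw.GenotypeMatrix(samples=samples, loci=loci, dosage=dosage)


@pytest.fixture
def scan_panel() -> tuple[aw.GenotypeMatrix, list[int]]:
    """Simulated 2-highland/4-lowland panel with two injected sweeps."""
    cfg = aw.SimulationConfig(
        n_loci=1200,
        populations=(
            aw.PopulationSpec("hi1", "high", 25, 0.05),
            aw.PopulationSpec("hi2", "high", 25, 0.05),
            aw.PopulationSpec("lo1", "low", 25, 0.05),
            aw.PopulationSpec("lo2", "low", 25, 0.05),
            aw.PopulationSpec("lo3", "low", 25, 0.05),
            aw.PopulationSpec("lo4", "low", 25, 0.05),
        ),
        sweep_loci=((100, 0.95), (700, 0.95)),
        ancestral_freq_overrides=((100, 0.1), (700, 0.1)),
        seed=7,
    )
    matrix, truth = aw.simulate_panel(cfg)
    return matrix, list(truth.locus_index)
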