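#!/usr/bin/env python
"""Simulate the study-scale genotype cohort used by the downstream analyses.

Generates a 12-population SNP-array panel (4 highland, 8 lowland breeds,
15-37 diploids each, 45,000 autosomal loci) under Balding-Nichols drift with
ten loci swept to high frequency in the highland breeds over a rare lowland
background, plus a dense re-sequencing panel over a 72-kb candidate window
(4 highland vs 8 lowland diploids, 400 sites, 5% divergent).  Writes the
sweep truth table, panel summaries and the VCF; the genotype matrix itself
is regenerated deterministically by later scripts (same seed) rather than
stored.
"""

import json
from pathlib import Path

import numpy as np

import altisweep as aw

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 20_240_101


def cohort_config(seed: int = SEED) -> aw.SimulationConfig:
    """The shared cohort definition: edit here, every script follows."""
    rng = np.random.default_rng([seed, 999])
    sweep_idx = tuple(int(i) for i in np.sort(rng.choice(45_000, 10, replace=False)))
    return aw.SimulationConfig(
        n_loci=45_000,
        sweep_loci=tuple((i, 0.95) for i in sweep_idx),
        ancestral_freq_overrides=tuple((i, 0.10) for i in sweep_idx),
        seed=seed,
    )


def reseq_config(seed: int = SEED) -> aw.ReseqConfig:
    return aw.ReseqConfig(seed=seed)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    cfg = cohort_config()
    matrix, truth = aw.simulate_panel(cfg)
    truth.to_csv(RESULTS / "cohort_sweep_truth.tsv", sep="\t", index=False)

    pops = {p: (matrix.altitude_class_of(p), int(matrix.sample_indices(p).size))
            for p in matrix.populations}
    summary = {
        "n_samples": matrix.n_samples,
        "n_loci": matrix.n_loci,
        "populations": pops,
        "n_sweep_loci": len(cfg.sweep_loci),
        "seed": cfg.seed,
    }
    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    panel, reseq_truth = aw.simulate_reseq_panel(
        reseq_config(), vcf_path=str(SCRATCH / "candidate_window.vcf"))
    reseq_truth.to_csv(RESULTS / "reseq_truth.tsv", sep="\t", index=False)

    print(f"cohort: {matrix.n_samples} diploids x {matrix.n_loci} loci, "
          f"{len(pops)} populations ({sum(v[0] == 'high' for v in pops.values())} highland)")
    print(f"injected sweeps at loci: {list(truth.locus_index)}")
    print(f"re-sequencing window: {panel.region[0]}:{panel.region[1]}-{panel.region[2]}, "
          f"{len(panel.sites)} sites, {int(reseq_truth.divergent.sum())} divergent")


if __name__ == "__main__":
    main()
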