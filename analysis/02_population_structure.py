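#!/usr/bin/env python
"""Population-structure companion analyses on the simulated cohort.

Regenerates the cohort, LD-prunes a subset of loci, and runs genotype PCA,
the genome-wide F_ST distance matrix and the neighbor-joining breed tree.
The tree should place the four highland breeds as a coherent neighborhood
only to the extent drift alone allows (all breeds here share one drift
parameter, so the expectation is a star-like topology); PCA should separate
populations along the leading axes.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import altisweep as aw

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module

cohort = import_module("01_simulate_cohort")

RESULTS = cohort.RESULTS


def main() -> None:
    matrix, _ = aw.simulate_panel(cohort.cohort_config())
    # structure analyses use a pruned subset; windowed pruning on a slice of
    # the panel is representative and keeps the pairwise-r^2 work tractable
    subset = matrix.subset(locus_idx=np.arange(0, matrix.n_loci, 15))
    kept = aw.ld_prune(subset, window_snps=50, step_snps=5, r2_threshold=0.2)
    pruned = subset.subset(locus_idx=[subset.locus_index(i) for i in kept])
    print(f"LD pruning: kept {pruned.n_loci} of {subset.n_loci} loci")

    coords, explained = aw.pca_genotypes(pruned, 4)
    pca = pd.DataFrame(coords, columns=[f"PC{k+1}" for k in range(4)])
    pca.insert(0, "sample", [s.id for s in pruned.samples])
    pca.insert(1, "population", [s.population for s in pruned.samples])
    pca.insert(2, "altitude", [s.altitude_class for s in pruned.samples])
    pca.to_csv(RESULTS / "pca_coordinates.tsv", sep="\t", index=False,
               float_format="%.4f")
    print("PCA explained variance:",
          ", ".join(f"PC{k+1} {v:.1%}" for k, v in enumerate(explained)))

    dm = aw.population_distance(pruned)
    pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(
        RESULTS / "population_fst_matrix.tsv", sep="\t", float_format="%.4f")
    off = dm.d[np.triu_indices(len(dm.labels), 1)]
    print(f"pairwise multilocus theta: min {off.min():.4f}, "
          f"median {np.median(off):.4f}, max {off.max():.4f}")

    tree = aw.nj_tree(dm)
    (RESULTS / "breed_nj_tree.nwk").write_text(tree.newick() + "\n")
    print("NJ tree written to results/breed_nj_tree.nwk")


if __name__ == "__main__":
    main()
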