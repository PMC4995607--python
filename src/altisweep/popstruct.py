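"""Companion population-structure analyses: centred-genotype PCA, a
population distance matrix from genome-wide pairwise theta, and Saitou-Nei
neighbor joining with Newick output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fst import multilocus_fst_matrix
from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_genotypes(matrix: GenotypeMatrix, n_components: int = 2,
                  standardize: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the centred dosage matrix.

    Missing dosages are mean-imputed per locus before centring; with
    ``standardize`` each locus is scaled by sqrt(p(1-p)) of its alt
    frequency.  Sign convention: within each component the loading of
    largest magnitude is made positive, so output is deterministic.

    Returns (sample coordinates [n_samples x n_components], explained
    variance fractions).
    """
    if n_components > matrix.n_samples:
        raise ValueError("more components requested than samples")
    d = matrix.dosage.astype(float)
    d[matrix.dosage == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(d))
    d[inds] = col_mean[inds[1]]
    x = d - col_mean
    if standardize:
        p = col_mean / 2.0
        scale = np.sqrt(np.clip(p * (1.0 - p), 1e-12, None))
        x = x / scale
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # fix signs by the largest-magnitude loading of each component
    for k in range(min(n_components, s.size)):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    coords = u[:, :n_components] * s[:n_components]
    total = float((s ** 2).sum())
    explained = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return coords, explained


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape inconsistent with labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.isfinite(d).all():
            raise ValueError("distance matrix entries must be finite")


def population_distance(matrix: GenotypeMatrix, method: str = "fst") -> DistanceMatrix:
    """Pairwise population distances from genome-wide allele-frequency data.

    ``fst`` (default) uses the ratio-of-sums Weir-Cockerham theta;
    ``nei`` uses Nei's (1972) standard genetic distance.  Negative theta
    estimates (sampling noise near zero differentiation) are clamped to 0.
    """
    pops = matrix.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if method == "fst":
                v = max(multilocus_fst_matrix(matrix, pops[i], pops[j]), 0.0)
            elif method == "nei":
                v = _nei_distance(matrix, pops[i], pops[j])
            else:
                raise ValueError(f"unknown method {method!r}")
            d[i, j] = d[j, i] = v
    return DistanceMatrix(labels=tuple(pops), d=d)


def _nei_distance(matrix: GenotypeMatrix, pop1: str, pop2: str) -> float:
    from .genotypes import alt_allele_frequencies

    p = alt_allele_frequencies(matrix.dosage[matrix.sample_indices(pop1), :])
    q = alt_allele_frequencies(matrix.dosage[matrix.sample_indices(pop2), :])
    ok = ~np.isnan(p) & ~np.isnan(q)
    p, q = p[ok], q[ok]
    jxy = float(np.sum(p * q + (1 - p) * (1 - q)))
    jx = float(np.sum(p ** 2 + (1 - p) ** 2))
    jy = float(np.sum(q ** 2 + (1 - q) ** 2))
    return float(-np.log(jxy / np.sqrt(jx * jy)))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Tree node; leaves carry a label, internal nodes carry children with
    branch lengths."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return self.label or ""
        parts = [f"{c._newick_inner()}:{bl:.6g}" for c, bl in self.children]
        return "(" + ",".join(parts) + ")"

    def leaf_path_lengths(self) -> dict[tuple[str, str], float]:
        """Pairwise path lengths between all leaves (for additivity checks)."""
        dists: dict[str, dict[str, float]] = {}

        def collect(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.label: 0.0}
            merged: dict[str, float] = {}
            groups = []
            for child, bl in node.children:
                sub = {k: v + bl for k, v in collect(child).items()}
                groups.append(sub)
                merged.update(sub)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, da in groups[gi].items():
                        for b, db in groups[gj].items():
                            dists.setdefault(a, {})[b] = da + db
                            dists.setdefault(b, {})[a] = da + db
            return merged

        collect(self)
        return {(a, b): v for a, row in dists.items() for b, v in row.items() if a < b}


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing the Q criterion
    Q(i,j) = (m-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); ties go to the
    lowest-index pair, so output is deterministic.  Negative branch lengths
    are clamped to 0 with a warning.  On an additive matrix the generating
    tree's topology and path lengths are recovered exactly.  Returns an
    unrooted tree represented with a trifurcating root for >= 3 leaves.
    """
    m = len(dm.labels)
    if m < 3:
        raise ValueError("need >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    d = dm.d.astype(float).copy()
    active = list(range(m))

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        n_act = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(n_act):
            for aj in range(ai + 1, n_act):
                i, j = active[ai], active[aj]
                q = (n_act - 2) * d[i, j] - sums[i] - sums[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (n_act - 2))
        lj = d[i, j] - li
        new = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        # distances from the new node to every other active node
        d_new = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            d_new[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.vstack([d, d_new[None, :]])
        d_new_full = np.append(d_new, 0.0)
        d = np.hstack([d, d_new_full[:, None]])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j, k = active
    # three-taxon closed form for the final star
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    return TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj)),
                              (nodes[k], clamp(lk))])
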