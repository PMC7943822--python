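"""Eigengene-seeded correlation K-means: the module-refinement core.

The refinement loop takes the community structure found on the network
topology and re-clusters every gene on its expression profile:

1. the number of clusters K and the initial centers are the community
   count and module eigengenes from community detection;
2. each gene is assigned to the center minimizing the correlation
   distance D(g, C) = 1 - |cor(g, C)|;
3. each cluster's center is replaced by the first principal component
   (eigengene) of its members' standardized expression;
4. repeat until the labeling stops changing.

Because the final centers are exactly the eigengenes of the final
clusters, a converged labeling is a fixpoint of the assignment step:
every gene is most strongly correlated with its own module's eigengene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEFAULT_SEED,
    DataFormatError,
    ExpressionMatrix,
    ModulePartition,
)
from . import gcn, newman


@dataclass
class KpcaConfig:
    """Loop-control knobs for the refinement stage.

    ``min_module_size`` (genes, default 3) drops clusters that shrink
    below a meaningful eigengene; ``max_iter`` bounds the assign/update
    loop; termination is an exact labeling fixpoint.
    """

    max_iter: int = 100
    min_module_size: int = 3
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class KpcaTrace:
    """Per-iteration diagnostics of the refinement loop."""

    label_changes: list[int] = field(default_factory=list)
    cluster_counts: list[int] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    oscillation_detected: bool = False

    def to_dict(self) -> dict:
        return {
            "label_changes": self.label_changes,
            "cluster_counts": self.cluster_counts,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "oscillation_detected": self.oscillation_detected,
        }


def _standardize_rows(values: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = gene_ids[int(np.argmax(sd == 0))]
        raise DataFormatError(f"gene {bad!r} is constant across samples")
    return (values - values.mean(axis=1, keepdims=True)) / sd[:, None]


def compute_eigengene(expr_submatrix: ExpressionMatrix) -> np.ndarray:
    """First principal component of a module's standardized expression.

    Rows are standardized to mean 0, sd 1 across samples; the eigengene
    is the first right-singular vector of the standardized matrix,
    normalized to unit Euclidean norm.  Its sign is fixed so it
    correlates non-negatively with the column mean of the standardized
    rows (falling back to a positive leading non-zero entry when that
    mean is orthogonal to the eigengene).
    """
    if expr_submatrix.n_genes < 1:
        raise DataFormatError("eigengene needs at least one gene")
    z = _standardize_rows(expr_submatrix.values, expr_submatrix.gene_ids)
    if z.shape[0] == 1:
        me = z[0]
    else:
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
    me = me / np.linalg.norm(me)
    ref = z.mean(axis=0)
    orient = float(me @ ref)
    if orient < 0:
        me = -me
    elif orient == 0:
        nz = np.flatnonzero(me)
        if nz.size and me[nz[0]] < 0:
            me = -me
    return me


def correlation_distance(g: np.ndarray, center: np.ndarray) -> float:
    """Distance between a gene profile and a cluster center.

    D(g, C) = 1 - |cor(g, C)|, in [0, 1]: 0 for perfect (anti-)
    correlation, 1 for no linear relationship.
    """
    g = np.asarray(g, dtype=float)
    center = np.asarray(center, dtype=float)
    if g.shape != center.shape:
        raise DataFormatError("gene and center vectors must have equal length")
    for name, v in (("gene", g), ("center", center)):
        if v.std() == 0:
            raise DataFormatError(f"{name} vector is constant; correlation undefined")
    r = float(np.corrcoef(g, center)[0, 1])
    return 1.0 - abs(r)


def _distance_matrix(z_genes: np.ndarray, centers: list[np.ndarray]) -> np.ndarray:
    """(genes x centers) correlation distances from standardized genes."""
    m = z_genes.shape[1]
    c = np.stack(centers)
    c_sd = c.std(axis=1)
    if (c_sd == 0).any():
        raise DataFormatError("a cluster center is constant; correlation undefined")
    zc = (c - c.mean(axis=1, keepdims=True)) / c_sd[:, None]
    r = (z_genes @ zc.T) / m
    return 1.0 - np.abs(np.clip(r, -1.0, 1.0))


def assign_genes(expr: ExpressionMatrix, centers: list[np.ndarray]) -> np.ndarray:
    """Label each gene with its nearest center (ties to the lowest index)."""
    if not centers:
        raise DataFormatError("need at least one cluster center")
    z = _standardize_rows(expr.values, expr.gene_ids)
    d = _distance_matrix(z, centers)
    return d.argmin(axis=1)


def update_centers(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    min_module_size: int = 3,
) -> tuple[list[np.ndarray], dict[int, int]]:
    """Recompute each cluster's eigengene; drop degenerate clusters.

    Clusters that are empty or smaller than ``min_module_size`` are
    removed and the survivors renumbered contiguously; the returned map
    sends old labels to new ones.
    """
    labels = np.asarray(labels)
    survivors = [
        lab
        for lab in sorted(set(labels.tolist()))
        if int((labels == lab).sum()) >= min_module_size
    ]
    if not survivors:
        raise DataFormatError(
            f"every cluster fell below min_module_size={min_module_size}"
        )
    label_map = {old: new for new, old in enumerate(survivors)}
    centers = [
        compute_eigengene(expr.subset_genes(labels == old)) for old in survivors
    ]
    return centers, label_map


def run_gcna_kpca(
    expr: ExpressionMatrix,
    threshold: float = gcn.PCC_THRESHOLD,
    alpha: float = gcn.PCC_ALPHA,
    config: KpcaConfig | None = None,
) -> tuple[ModulePartition, KpcaTrace]:
    """Full module identification on a preprocessed expression matrix.

    Builds the co-expression network at ``threshold``/``alpha``, seeds K
    and the initial centers from leading-eigenvector community
    detection, then iterates correlation-distance assignment and
    eigengene center updates until the labeling reaches a fixpoint (or
    ``max_iter``; a labeling that repeats an earlier iteration stops the
    loop with the best labeling seen by module-membership error rate).
    """
    config = config or KpcaConfig()
    cor = gcn.pairwise_pearson(expr)
    network = gcn.build_gcn(cor, threshold=threshold, alpha=alpha)
    communities = newman.detect_communities(network, seed=config.seed)
    if communities.n_modules == 0:
        raise DataFormatError(
            "community detection found no modules (edgeless network); "
            "lower the correlation threshold"
        )

    # Seed centers: eigengenes of the Newman communities. Seed communities
    # below min_module_size still seed a center; size pruning applies from
    # the first update step onward.
    seed_groups = [
        [g for g, lab in communities.labels.items() if lab == k]
        for k in range(communities.n_modules)
    ]
    centers = [compute_eigengene(expr.subset_genes(grp)) for grp in seed_groups]

    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    prev = np.full(expr.n_genes, -1, dtype=int)
    for g, lab in communities.labels.items():
        prev[gene_index[g]] = lab

    trace = KpcaTrace()
    seen: dict[bytes, int] = {prev.tobytes(): 0}
    history: list[tuple[np.ndarray, list[np.ndarray]]] = []

    labels = prev
    for it in range(1, config.max_iter + 1):
        labels = assign_genes(expr, centers)
        changes = int((labels != prev).sum())
        trace.label_changes.append(changes)
        trace.cluster_counts.append(len(set(labels.tolist())))
        trace.n_iterations = it
        if changes == 0:
            trace.converged = True
            break
        key = labels.tobytes()
        if key in seen:
            trace.oscillation_detected = True
            history.append((labels, centers))
            labels, centers = _best_by_error_rate(expr, history)
            break
        seen[key] = it
        history.append((labels, centers))
        centers, label_map = update_centers(
            expr, labels, min_module_size=config.min_module_size
        )
        labels = np.array(
            [label_map.get(lab, -1) for lab in labels], dtype=int
        )
        # Genes of dropped clusters rejoin at the next assignment pass.
        prev = labels

    # Final centers must be the eigengenes of the final labeling.
    centers, label_map = update_centers(
        expr, labels, min_module_size=config.min_module_size
    )
    final = np.array([label_map.get(lab, -1) for lab in labels], dtype=int)
    if (final < 0).any():
        # A cluster died in the very last update: reassign its genes once.
        final = assign_genes(expr, centers)
        centers, label_map = update_centers(expr, final, min_module_size=2)
        final = np.array([label_map[lab] for lab in final], dtype=int)

    partition = ModulePartition(
        labels={g: int(final[i]) for g, i in gene_index.items()},
        n_modules=len(centers),
        eigengenes={k: c for k, c in enumerate(centers)},
        sample_ids=list(expr.sample_ids),
    )
    return partition, trace


def _best_by_error_rate(
    expr: ExpressionMatrix,
    history: list[tuple[np.ndarray, list[np.ndarray]]],
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pick the labeling with the lowest module-membership error rate."""
    from .evaluation import error_rate  # local import avoids a cycle

    best = None
    best_rate = np.inf
    for labels, centers in history:
        used = sorted(set(int(l) for l in labels if l >= 0))
        compact = {old: new for new, old in enumerate(used)}
        part = ModulePartition(
            labels={
                g: compact[int(l)]
                for g, l in zip(expr.gene_ids, labels)
                if l >= 0
            },
            n_modules=len(used),
        )
        rate = error_rate(part, expr).error_rate
        if rate < best_rate:
            best_rate = rate
            best = (labels, centers)
    assert best is not None
    return best
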