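"""Key-gene identification on the key module's PPI subnetwork.

The module with the highest biological significance (Sig_i) is the key
module; its genes are ranked by PageRank on the protein-protein
interaction subnetwork they induce, and the top 10 are reported as key
genes.  Undirected PPI edges are expanded into two directed edges for
the PageRank transition matrix; dangling (isolated) nodes redistribute
their mass uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataFormatError, ModulePartition, PPINetwork, logger
from .evaluation import EnrichmentReport

PAGERANK_DAMPING = 0.85
TOP_K = 10


@dataclass
class KeyGeneResult:
    """Key module id, per-gene PageRank scores, and the top-k genes."""

    key_module: int
    scores: dict[str, float]
    top_genes: list[str]


def select_key_module(enrichment: EnrichmentReport) -> int:
    """Module with the highest Sig_i; ties go to the lowest module id."""
    if not enrichment.sig_per_module:
        raise DataFormatError("enrichment report covers no modules")
    best = max(sorted(enrichment.sig_per_module), key=lambda k: enrichment.sig_per_module[k])
    # max() keeps the first of equal values, and the keys are pre-sorted,
    # so exact ties resolve to the lowest module id.
    return int(best)


def pagerank(
    network: PPINetwork,
    damping: float = PAGERANK_DAMPING,
    tol: float = 1e-10,
    max_iter: int = 1000,
    weighted: bool = False,
) -> dict[str, float]:
    """PageRank scores by power iteration with uniform teleport.

    The undirected graph is treated as bidirectional; transition
    probability from a node splits equally over its neighbors (or
    proportionally to edge ``score`` when ``weighted``).  Dangling nodes
    spread their mass uniformly over all nodes.  Iteration stops when
    the L1 change drops below ``tol``; failure to converge within
    ``max_iter`` raises with the residual.
    """
    nodes = sorted(network.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise DataFormatError("PageRank needs at least one node")
    pos = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v, d in network.graph.edges(data=True):
        w = float(d.get("score", 1.0)) if weighted else 1.0
        a[pos[u], pos[v]] = w
        a[pos[v], pos[u]] = w
    out = a.sum(axis=1)
    dangling = out == 0
    # Column-stochastic transition matrix M[j, i] = P(i -> j).
    m = np.zeros((n, n))
    nz = ~dangling
    m[:, nz] = (a[nz] / out[nz, None]).T

    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = (1.0 - damping) / n + damping * (m @ x + x[dangling].sum() / n)
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual < tol:
            x = x / x.sum()
            return {v: float(x[pos[v]]) for v in nodes}
    raise DataFormatError(
        f"PageRank failed to converge in {max_iter} iterations (L1 residual {residual:.3g})"
    )


def top_key_genes(
    partition: ModulePartition,
    key_module: int,
    ppi: PPINetwork,
    k: int = TOP_K,
    damping: float = PAGERANK_DAMPING,
    weighted: bool = False,
) -> KeyGeneResult:
    """Rank the key module's genes by PageRank on their induced PPI.

    Module genes absent from the PPI node set are excluded from the
    ranking (and logged).  When fewer than ``k`` genes are rankable, the
    full ranked list is returned with a warning.  Ties in score break
    lexicographically by gene id.
    """
    module_genes = set(partition.module_genes(key_module))
    present = module_genes & set(ppi.graph.nodes)
    absent = module_genes - present
    if absent:
        logger.info(
            "%d key-module gene(s) absent from the PPI and excluded: %s",
            len(absent), sorted(absent)[:10],
        )
    if not present:
        raise DataFormatError("no key-module gene appears in the PPI network")
    induced = PPINetwork(ppi.graph.subgraph(sorted(present)).copy())
    scores = pagerank(induced, damping=damping, weighted=weighted)
    ranked = sorted(scores, key=lambda g: (-scores[g], g))
    if len(ranked) < k:
        logger.warning(
            "key module has only %d rankable genes (< k=%d); returning all",
            len(ranked), k,
        )
    return KeyGeneResult(
        key_module=int(key_module),
        scores=scores,
        top_genes=ranked[:k],
    )
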