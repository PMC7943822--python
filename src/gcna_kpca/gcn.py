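"""Gene co-expression network construction.

Two genes are linked when the absolute Pearson correlation of their
expression profiles reaches a magnitude threshold (default |r| >= 0.65)
and the correlation is statistically significant (two-sided p < 0.05
from the t transform).  Adjacency is defined on |r|, so strong negative
co-expression also creates an edge; the sign is kept as edge metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .core import CoexpressionNetwork, DataFormatError, ExpressionMatrix

PCC_THRESHOLD = 0.65
PCC_ALPHA = 0.05


@dataclass
class CorrelationResult:
    """All-pairs Pearson correlations with two-sided p-values."""

    gene_ids: list[str]
    r: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.r.shape != (n, n) or self.p.shape != (n, n):
            raise DataFormatError("correlation matrices must be square over gene_ids")
        if np.abs(self.r - self.r.T).max(initial=0.0) > 1e-12:
            raise DataFormatError("correlation matrix is not symmetric")


def pairwise_pearson(expr: ExpressionMatrix) -> CorrelationResult:
    """All-pairs Pearson correlation across samples, with p-values.

    The two-sided p-value comes from the exact null transform
    ``t = r * sqrt(m-2) / sqrt(1-r^2)`` with ``m-2`` degrees of freedom
    (m samples); pairs with |r| = 1 get p = 0.

    Genes must have non-zero variance across samples — callers are
    expected to pre-filter constant genes.
    """
    m = expr.n_samples
    if m < 3:
        raise DataFormatError("correlation p-values need at least 3 samples")
    sd = expr.values.std(axis=1)
    if (sd == 0).any():
        bad = expr.gene_ids[int(np.argmax(sd == 0))]
        raise DataFormatError(f"gene {bad!r} has zero variance across samples")
    z = (expr.values - expr.values.mean(axis=1, keepdims=True)) / sd[:, None]
    r = (z @ z.T) / m
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(m - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 0.0)
    return CorrelationResult(list(expr.gene_ids), r, p)


def build_gcn(
    cor: CorrelationResult,
    threshold: float = PCC_THRESHOLD,
    alpha: float = PCC_ALPHA,
    bonferroni: bool = False,
) -> CoexpressionNetwork:
    """Threshold a correlation matrix into a co-expression network.

    Edge (i, j) exists iff ``|r_ij| >= threshold`` and ``p_ij < alpha``;
    the edge weight is |r_ij| and the correlation sign is stored on the
    edge.  All genes become nodes, so thresholding can only isolate a
    gene, never remove it.  ``bonferroni`` divides alpha by the number of
    tested pairs for users who want family-wise control; the default
    mirrors the per-pair rule.
    """
    n = len(cor.gene_ids)
    eff_alpha = alpha / (n * (n - 1) / 2) if (bonferroni and n > 1) else alpha
    g = nx.Graph()
    g.add_nodes_from(cor.gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    absr = np.abs(cor.r[iu, ju])
    keep = (absr >= threshold) & (cor.p[iu, ju] < eff_alpha)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(
            cor.gene_ids[i],
            cor.gene_ids[j],
            weight=float(abs(cor.r[i, j])),
            sign=int(np.sign(cor.r[i, j])) or 1,
            p=float(cor.p[i, j]),
        )
    return CoexpressionNetwork(g, threshold=threshold)
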