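"""Evaluation metrics for module and key-gene identification.

Four complementary yardsticks:

* **error rate** — fraction of genes whose expression correlates more
  strongly with another module's eigengene than with their own
  (module membership MM_g = |cor(g, ME_own)|);
* **biological significance** — per module, the sum of -log10 p over
  annotation terms significantly over-represented by Fisher's exact
  test, averaged over modules (Sig);
* **prognostic significance** — sum of -log10 logrank p-values of key
  genes under a median expression split (Sig_SA);
* **diagnostic AUC** — per-gene tumor-vs-normal ROC area via the
  rank-sum formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    AnnotationSets,
    DataFormatError,
    ExpressionMatrix,
    ModulePartition,
    SampleGroups,
    SurvivalTable,
    TUMOR,
    NORMAL,
)
from .cluster import compute_eigengene, _standardize_rows

#: Floor applied to p-values before taking -log10.
P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Error rate (module membership)
# ---------------------------------------------------------------------------

@dataclass
class ErrorRateReport:
    """Per-gene module membership and the aggregate error rate."""

    module_membership: dict[str, float]
    violations: dict[str, bool]
    error_rate: float


def error_rate(partition: ModulePartition, expr: ExpressionMatrix) -> ErrorRateReport:
    """Fraction of genes better correlated with a foreign eigengene.

    Gene g in module i is a violation iff some j != i satisfies
    |cor(g, ME_j)| > MM_g, with MM_g = |cor(g, ME_i)|; exact ties do not
    count against g.  Eigengenes are recomputed from ``expr`` when the
    partition does not carry them.  With a single module the error rate
    is 0 by vacuity (a warning is emitted).
    """
    genes = [g for g in partition.gene_ids if g in set(expr.gene_ids)]
    if len(genes) != len(partition.gene_ids):
        missing = sorted(set(partition.gene_ids) - set(expr.gene_ids))
        raise DataFormatError(f"partition gene {missing[0]!r} absent from expression")
    if partition.n_modules == 1:
        warnings.warn("single-module partition: error rate is 0 by vacuity")
        return ErrorRateReport(
            module_membership={g: 1.0 for g in genes},
            violations={g: False for g in genes},
            error_rate=0.0,
        )

    if set(partition.eigengenes) == set(range(partition.n_modules)):
        mes = [partition.eigengenes[k] for k in range(partition.n_modules)]
    else:
        mes = [
            compute_eigengene(expr.subset_genes(partition.module_genes(k)))
            for k in range(partition.n_modules)
        ]

    sub = expr.subset_genes(genes)
    z = _standardize_rows(sub.values, sub.gene_ids)
    c = np.stack(mes)
    zc = (c - c.mean(axis=1, keepdims=True)) / c.std(axis=1)[:, None]
    absr = np.abs(np.clip((z @ zc.T) / sub.n_samples, -1.0, 1.0))

    mm: dict[str, float] = {}
    viol: dict[str, bool] = {}
    for i, g in enumerate(genes):
        own = partition.labels[g]
        mm[g] = float(absr[i, own])
        others = np.delete(absr[i], own)
        viol[g] = bool(others.max(initial=0.0) > absr[i, own])
    rate = sum(viol.values()) / len(genes)
    return ErrorRateReport(module_membership=mm, violations=viol, error_rate=rate)


# ---------------------------------------------------------------------------
# Fisher enrichment and biological significance
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentReport:
    """Per-module enrichment results and the Sig summary."""

    per_module: dict[int, list[tuple[str, int, float]]]  # (term, overlap, p)
    sig_per_module: dict[int, float]
    sig: float


def fisher_enrichment(
    module_genes: frozenset[str] | set[str],
    sets: AnnotationSets,
    background: frozenset[str] | set[str],
) -> list[tuple[str, int, float]]:
    """One-sided over-representation p per term (hypergeometric tail).

    For a module of size n drawn from a background of size N, a term
    covering K background genes, and an observed overlap x, the p-value
    is P(X >= x) with X ~ Hypergeom(N, K, n).  Terms with no overlap get
    p = 1.  The module must be a subset of the background.
    """
    background = frozenset(background)
    module = frozenset(module_genes)
    if not background:
        raise DataFormatError("enrichment background is empty")
    if not module <= background:
        stray = sorted(module - background)[0]
        raise DataFormatError(f"module gene {stray!r} not in background")
    n_bg = len(background)
    n_mod = len(module)
    out: list[tuple[str, int, float]] = []
    for term, (_, genes) in sets.items():
        term_bg = genes & background
        overlap = len(module & term_bg)
        if overlap == 0 or not term_bg:
            out.append((term, overlap, 1.0))
            continue
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(term_bg), n_mod))
        out.append((term, overlap, min(p, 1.0)))
    return out


def biological_significance(
    partition: ModulePartition,
    sets: AnnotationSets,
    background: frozenset[str] | set[str] | None = None,
    term_alpha: float = 0.05,
) -> EnrichmentReport:
    """Sig_i per module and their mean Sig over all modules.

    Sig_i sums -log10(p) over the module's terms with p < ``term_alpha``
    (a module with no significant term contributes 0); Sig is the mean
    of Sig_i over the K modules.  The background defaults to the set of
    clustered genes.
    """
    if background is None:
        background = frozenset(partition.gene_ids)
    per_module: dict[int, list[tuple[str, int, float]]] = {}
    sig_i: dict[int, float] = {}
    for k in range(partition.n_modules):
        res = fisher_enrichment(set(partition.module_genes(k)), sets, background)
        per_module[k] = res
        sig_i[k] = float(
            sum(-np.log10(max(p, P_FLOOR)) for _, _, p in res if p < term_alpha)
        )
    m = partition.n_modules
    sig = float(sum(sig_i.values()) / m) if m else 0.0
    return EnrichmentReport(per_module=per_module, sig_per_module=sig_i, sig=sig)


# ---------------------------------------------------------------------------
# Survival: logrank and prognostic significance
# ---------------------------------------------------------------------------

@dataclass
class SurvivalReport:
    """Per-gene logrank p-values and the Sig_SA summary."""

    logrank_p: dict[str, float]
    sig_sa: float


def logrank_by_median(
    gene_values: np.ndarray,
    survival: SurvivalTable,
    percentile: float = 50.0,
) -> float:
    """Two-sided logrank p after splitting samples at an expression cut.

    Samples at or below the ``percentile`` cut (median by default) form
    the low-expression stratum, the rest the high stratum.  Degenerate
    splits (one empty stratum, or no observed events) return p = 1 with
    a warning.
    """
    from lifelines.statistics import logrank_test

    x = np.asarray(gene_values, dtype=float)
    if len(x) != len(survival.sample_ids):
        raise DataFormatError("expression vector and survival table length differ")
    cut = float(np.percentile(x, percentile))
    low = x <= cut
    high = ~low
    if not low.any() or not high.any():
        warnings.warn("all samples fall in one expression stratum; p = 1")
        return 1.0
    if survival.event.sum() == 0:
        warnings.warn("no observed events; logrank statistic is 0, p = 1")
        return 1.0
    res = logrank_test(
        survival.time[high],
        survival.time[low],
        event_observed_A=survival.event[high],
        event_observed_B=survival.event[low],
    )
    p = float(res.p_value)
    return 1.0 if not np.isfinite(p) else p


def prognostic_significance(pvalues: list[float] | np.ndarray) -> float:
    """Sig_SA = sum of -log10(p) over the key genes' logrank p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size < 1:
        raise DataFormatError("need at least one p-value")
    if ((pvalues < 0) | (pvalues > 1)).any():
        raise DataFormatError("p-values must lie in [0, 1]")
    return float(np.sum(-np.log10(np.maximum(pvalues, P_FLOOR))))


def survival_report(
    expr: ExpressionMatrix,
    genes: list[str],
    survival: SurvivalTable,
    percentile: float = 50.0,
) -> SurvivalReport:
    """Logrank p for each listed gene plus the aggregate Sig_SA."""
    surv = survival.align(expr.sample_ids)
    ps = {
        g: logrank_by_median(expr.gene_vector(g), surv, percentile=percentile)
        for g in genes
    }
    return SurvivalReport(logrank_p=ps, sig_sa=prognostic_significance(list(ps.values())))


# ---------------------------------------------------------------------------
# Diagnostic AUC
# ---------------------------------------------------------------------------

def gene_auc(gene_values: np.ndarray, groups: SampleGroups, sample_ids: list[str]) -> float:
    """Tumor-vs-normal ROC area by the rank-sum formulation.

    Equals the probability that a random tumor sample's expression
    exceeds a random normal sample's, counting exact ties as 1/2
    (midrank convention).
    """
    x = np.asarray(gene_values, dtype=float)
    t_mask = groups.mask(sample_ids, TUMOR)
    n_mask = groups.mask(sample_ids, NORMAL)
    n1, n0 = int(t_mask.sum()), int(n_mask.sum())
    if n1 == 0 or n0 == 0:
        raise DataFormatError("AUC needs at least one sample in each class")
    ranks = stats.rankdata(x)
    u = ranks[t_mask].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
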