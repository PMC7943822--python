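"""Expression preprocessing: the four-step differential-expression filter.

The pipeline reduces a full expression matrix to a differential gene set
before network construction:

1. drop genes whose maximum expression is below a floor in both groups;
2. flag outlier samples by average-linkage hierarchical clustering and
   optionally drop them;
3. keep genes with tumor/normal fold change >= ``up`` or <= ``down``;
4. keep genes whose two-sided Welch t-test between groups has p < alpha.

Step order matters: each step receives the survivors of the previous one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist

from .core import ExpressionMatrix, SampleGroups, DataFormatError, logger


@dataclass
class PreprocessReport:
    """Per-step bookkeeping of the preprocessing pipeline.

    ``removed_low``/``removed_fc``/``removed_ttest`` count genes removed
    at steps 1, 3 and 4; they sum to input minus output genes.
    ``fold_change`` and ``t_pvalue`` hold the statistics of retained genes.
    """

    n_genes_in: int = 0
    n_genes_out: int = 0
    removed_low: int = 0
    removed_fc: int = 0
    removed_ttest: int = 0
    removed_samples: list[str] = field(default_factory=list)
    fold_change: dict[str, float] = field(default_factory=dict)
    t_pvalue: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            "removed_low_expression": self.removed_low,
            "removed_fold_change": self.removed_fc,
            "removed_t_test": self.removed_ttest,
            "removed_samples": self.removed_samples,
            "fold_change": self.fold_change,
            "t_pvalue": self.t_pvalue,
        }


def filter_low_expression(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    min_max: float = 1.0,
    require_both: bool = False,
) -> ExpressionMatrix:
    """Remove genes unexpressed relative to a per-group maximum floor.

    By default a gene is kept when its maximum expression reaches
    ``min_max`` in *at least one* group (tumor or normal), so genes
    expressed only in one condition survive.  ``require_both=True``
    switches to the stricter rule that both group maxima must reach the
    floor.
    """
    t_mask, n_mask = groups.require_both_groups(expr.sample_ids)
    max_t = expr.values[:, t_mask].max(axis=1)
    max_n = expr.values[:, n_mask].max(axis=1)
    if require_both:
        keep = (max_t >= min_max) & (max_n >= min_max)
    else:
        keep = (max_t >= min_max) | (max_n >= min_max)
    if not keep.any():
        raise DataFormatError(
            f"no gene reaches max expression {min_max}; lower --min-max"
        )
    return expr.subset_genes(keep)


def detect_outlier_samples(expr: ExpressionMatrix, z_cut: float = 2.5) -> list[str]:
    """Flag samples that join the sample dendrogram at an extreme height.

    Samples are clustered by average linkage on Euclidean distance between
    expression profiles.  For each sample the height of the merge that
    first absorbs it into the tree is recorded; a sample is flagged when
    that height exceeds ``mean + z_cut * sd`` of all leaf merge heights.
    The list is advisory: callers decide whether to drop flagged samples.
    """
    n = expr.n_samples
    if n < 3:
        raise DataFormatError("outlier detection needs at least 3 samples")
    Z = average(pdist(expr.values.T, metric="euclidean"))
    # A leaf's merge height is the height of the step at which its
    # singleton cluster disappears from the agglomeration.
    heights = np.full(n, np.nan)
    for step, (a, b, h, _) in enumerate(Z):
        for cl in (int(a), int(b)):
            if cl < n:
                heights[cl] = h
    mu, sd = float(np.mean(heights)), float(np.std(heights))
    if not np.isfinite(z_cut):
        return []
    cut = mu + z_cut * sd
    flagged = [expr.sample_ids[i] for i in range(n) if heights[i] > cut]
    if flagged:
        logger.info("flagged %d outlier sample(s): %s", len(flagged), flagged)
    return flagged


def fold_change_filter(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    up: float = 2.0,
    down: float = 0.5,
    pseudocount: float = 1e-3,
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Keep genes with tumor/normal mean ratio >= ``up`` or <= ``down``.

    FC = (mean tumor + pseudocount) / (mean normal + pseudocount); the
    pseudocount guards against division by zero for silent genes.
    Returns the filtered matrix and the FC of every input gene.
    """
    t_mask, n_mask = groups.require_both_groups(expr.sample_ids)
    mean_t = expr.values[:, t_mask].mean(axis=1)
    mean_n = expr.values[:, n_mask].mean(axis=1)
    fc = (mean_t + pseudocount) / (mean_n + pseudocount)
    keep = (fc >= up) | (fc <= down)
    fcs = dict(zip(expr.gene_ids, map(float, fc)))
    return expr.subset_genes(keep), fcs


def t_test_filter(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    alpha: float = 0.05,
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Keep genes whose two-sided Welch t-test p-value is below ``alpha``.

    Welch (unequal-variance) form.  A gene with zero variance in both
    groups has no evidence of difference; its p is defined as 1 and the
    gene is removed.  Returns the filtered matrix and every gene's p.
    """
    t_mask, n_mask = groups.require_both_groups(expr.sample_ids)
    if t_mask.sum() < 2 or n_mask.sum() < 2:
        raise DataFormatError("Welch t-test needs >= 2 samples per group")
    xt = expr.values[:, t_mask]
    xn = expr.values[:, n_mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(xt, xn, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    keep = p < alpha
    pvals = dict(zip(expr.gene_ids, map(float, p)))
    return expr.subset_genes(keep), pvals


def run_preprocess(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    min_max: float = 1.0,
    require_both: bool = False,
    outlier_z: float = 2.5,
    drop_samples: list[str] | None = None,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    pseudocount: float = 1e-3,
    alpha: float = 0.05,
    auto_drop_outliers: bool = True,
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Run filters (1)-(4) in order and return the survivors plus a report.

    ``drop_samples`` removes named samples unconditionally (mirroring a
    curated removal list); flagged outliers are additionally dropped when
    ``auto_drop_outliers`` is set.
    """
    report = PreprocessReport(n_genes_in=expr.n_genes)

    step1 = filter_low_expression(expr, groups, min_max=min_max, require_both=require_both)
    report.removed_low = expr.n_genes - step1.n_genes

    to_drop = set(drop_samples or [])
    if auto_drop_outliers and np.isfinite(outlier_z):
        to_drop |= set(detect_outlier_samples(step1, z_cut=outlier_z))
    to_drop &= set(step1.sample_ids)
    report.removed_samples = sorted(to_drop)
    step2 = (
        step1.subset_samples([s for s in step1.sample_ids if s not in to_drop])
        if to_drop
        else step1
    )

    step3, fcs = fold_change_filter(
        step2, groups, up=fc_up, down=fc_down, pseudocount=pseudocount
    )
    report.removed_fc = step2.n_genes - step3.n_genes

    step4, pvals = t_test_filter(step3, groups, alpha=alpha)
    report.removed_ttest = step3.n_genes - step4.n_genes

    report.n_genes_out = step4.n_genes
    report.fold_change = {g: fcs[g] for g in step4.gene_ids}
    report.t_pvalue = {g: pvals[g] for g in step4.gene_ids}
    return step4, report
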