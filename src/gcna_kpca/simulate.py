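"""Synthetic data with the statistical structure every stage assumes.

The generator emulates a tumor/normal expression study with planted
gene modules:

* each module is driven by one latent factor per sample; a member gene
  is ``sqrt(rho) * factor + sqrt(1-rho) * noise`` on a log scale, so the
  true within-module correlation is ``rho`` and the factor itself is
  the module's true eigengene;
* module genes carry a differential-expression shift of ``d`` (log-
  scale sd units) between tumor and normal, with direction alternating
  up/down per module; background genes are independent noise;
* the log signal is exponentiated onto a non-negative FPKM-like scale
  (log-normal, median ~5) so magnitude-based preprocessing filters see
  realistic values;
* survival times are exponential with hazard tied to the first module's
  eigengene; censoring is independent exponential;
* annotation terms mirror planted modules (plus decoys), and the PPI
  plants one hub per module.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import (
    AnnotationSets,
    ExpressionMatrix,
    PPINetwork,
    SampleGroups,
    SurvivalTable,
    TUMOR,
    NORMAL,
)

#: Multiplier applied to the log-scale signal before exponentiation.
LOG_SCALE = 0.5
#: Log-scale baseline: exp(BASELINE) ~ 5 FPKM median expression.
LOG_BASELINE = float(np.log(5.0))


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults are the "small" preset: 5 modules x 20 genes plus 100
    unstructured background genes, 30 tumor + 30 normal samples,
    within-module latent correlation 0.8, a 2-sd log-scale differential
    shift on module genes (direction alternating per module), hazard
    ratio 2 per unit of module-0 eigengene, 30% censoring.
    """

    n_modules: int = 5
    genes_per_module: int = 20
    n_background_genes: int = 100
    n_tumor: int = 30
    n_normal: int = 30
    within_module_corr: float = 0.8
    de_effect_size: float = 2.0
    noise_sd: float = 1.0
    survival_hazard_ratio: float = 2.0
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.within_module_corr < 1.0):
            raise ValueError("within_module_corr must lie in (0, 1)")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        for name in ("n_modules", "genes_per_module", "n_background_genes",
                     "n_tumor", "n_normal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    module_labels: dict[str, int]          # planted module per module gene
    factors: np.ndarray                    # (n_modules, n_samples) latent factors
    de_genes: list[str]
    de_direction: dict[int, int]           # module -> +1 (up) / -1 (down)
    annotation_map: dict[str, int] = field(default_factory=dict)  # term -> module
    ppi_hubs: list[str] = field(default_factory=list)

    def module_gene_ids(self) -> list[str]:
        return list(self.module_labels)


def simulate_expression(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, SampleGroups, SyntheticTruth]:
    """Draw one expression matrix with planted modules and DE structure."""
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_tumor + spec.n_normal
    sample_ids = [f"T{i:03d}" for i in range(spec.n_tumor)] + [
        f"N{i:03d}" for i in range(spec.n_normal)
    ]
    group = SampleGroups(
        {s: (TUMOR if s.startswith("T") else NORMAL) for s in sample_ids}
    )
    is_tumor = np.array([s.startswith("T") for s in sample_ids], dtype=float)
    centered_group = is_tumor - 0.5  # +d/2 in tumor, -d/2 in normal

    rho = spec.within_module_corr
    factors = rng.standard_normal((spec.n_modules, n_samples))

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    labels: dict[str, int] = {}
    de_direction = {j: (1 if j % 2 == 0 else -1) for j in range(spec.n_modules)}
    for j in range(spec.n_modules):
        shift = spec.de_effect_size * de_direction[j] * centered_group
        for i in range(spec.genes_per_module):
            gid = f"M{j}G{i:03d}"
            eps = rng.standard_normal(n_samples)
            z = np.sqrt(rho) * factors[j] + np.sqrt(1 - rho) * spec.noise_sd * eps
            rows.append(z + shift)
            gene_ids.append(gid)
            labels[gid] = j
    for i in range(spec.n_background_genes):
        gid = f"BG{i:04d}"
        rows.append(spec.noise_sd * rng.standard_normal(n_samples))
        gene_ids.append(gid)

    z = np.vstack(rows) if rows else np.empty((0, n_samples))
    values = np.exp(LOG_SCALE * z + LOG_BASELINE)
    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = SyntheticTruth(
        module_labels=labels,
        factors=factors,
        de_genes=[g for g in gene_ids if g in labels],
        de_direction=de_direction,
    )
    return expr, group, truth


def simulate_annotations(
    truth: SyntheticTruth,
    terms_per_module: int = 1,
    noise_genes_per_term: int = 2,
    n_decoy_terms: int = 5,
    decoy_size: int = 15,
    seed: int = 0,
) -> AnnotationSets:
    """Annotation terms mirroring the planted modules, plus decoys.

    Each planted module yields ``terms_per_module`` terms holding its
    genes plus a few off-module genes; decoy terms are random draws from
    all genes and carry no module signal.
    """
    rng = np.random.default_rng(seed)
    all_genes = sorted(truth.module_labels)
    by_module: dict[int, list[str]] = {}
    for g, m in truth.module_labels.items():
        by_module.setdefault(m, []).append(g)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    annotation_map: dict[str, int] = {}
    for m in sorted(by_module):
        off_module = [g for g in all_genes if truth.module_labels[g] != m]
        for t in range(terms_per_module):
            term = f"GO:M{m}T{t}"
            genes = set(by_module[m])
            if noise_genes_per_term and off_module:
                extra = rng.choice(
                    off_module,
                    size=min(noise_genes_per_term, len(off_module)),
                    replace=False,
                )
                genes |= set(extra.tolist())
            sets[term] = (f"planted term for module {m}", frozenset(genes))
            annotation_map[term] = m
    for d in range(n_decoy_terms):
        if not all_genes:
            break
        pick = rng.choice(all_genes, size=min(decoy_size, len(all_genes)), replace=False)
        sets[f"GO:DECOY{d}"] = ("decoy term", frozenset(pick.tolist()))
    truth.annotation_map = annotation_map
    return AnnotationSets(sets)


def simulate_survival(
    truth: SyntheticTruth,
    expr: ExpressionMatrix,
    spec: SimulationSpec,
    base_rate: float = 0.1,
) -> SurvivalTable:
    """Exponential survival tied to the first module's eigengene.

    Per-sample hazard is ``base_rate * HR ** e_s`` where ``e_s`` is the
    module-0 eigengene score standardized to unit variance, so HR is the
    hazard ratio per standard deviation of module activity.  Censoring
    is independent exponential with rate chosen so the expected censored
    fraction approximates ``censoring_rate``; a rate of 0 leaves every
    observation an event.
    """
    from .cluster import compute_eigengene

    rng = np.random.default_rng(spec.seed + 1)
    n = expr.n_samples
    module0 = [g for g, m in truth.module_labels.items() if m == 0]
    if module0:
        me = compute_eigengene(expr.subset_genes(module0))
        score = me * np.sqrt(n)  # unit-norm -> approximately unit-variance
    else:
        score = np.zeros(n)
    hazard = base_rate * spec.survival_hazard_ratio ** score
    times = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        cens_rate = base_rate * spec.censoring_rate / (1.0 - spec.censoring_rate)
        cens = rng.exponential(1.0 / cens_rate, size=n)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    else:
        event = np.ones(n, dtype=int)
        obs = times
    return SurvivalTable(list(expr.sample_ids), obs, event)


def simulate_ppi(
    truth: SyntheticTruth,
    hub_degree: int = 8,
    background_edge_p: float = 0.05,
    seed: int = 0,
) -> PPINetwork:
    """PPI with one planted hub per module plus sparse random edges.

    The hub (the module's first gene) is wired to ``hub_degree`` random
    members of its module; background edges are Erdos-Renyi over all
    module genes at ``background_edge_p``.
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    by_module: dict[int, list[str]] = {}
    for gene, m in truth.module_labels.items():
        by_module.setdefault(m, []).append(gene)
    hubs: list[str] = []
    for m in sorted(by_module):
        members = by_module[m]
        g.add_nodes_from(members)
        hub = members[0]
        hubs.append(hub)
        others = members[1:]
        if others:
            chosen = rng.choice(
                others, size=min(hub_degree, len(others)), replace=False
            )
            for other in chosen.tolist():
                g.add_edge(hub, other)
    all_genes = sorted(truth.module_labels)
    if background_edge_p > 0:
        for i, u in enumerate(all_genes):
            draws = rng.random(len(all_genes) - i - 1)
            for off, v in enumerate(all_genes[i + 1:]):
                if draws[off] < background_edge_p and not g.has_edge(u, v):
                    g.add_edge(u, v)
    truth.ppi_hubs = hubs
    return PPINetwork(g)
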