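"""Shared fixtures and independent oracles for the test suite.

The oracles here (exhaustive modularity search, hypergeometric
summation, pairwise AUC counting, dense PageRank solve) deliberately
avoid the code paths they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from gcna_kpca import ExpressionMatrix, SampleGroups


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_expr(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    sample_ids = sample_ids or [f"s{j}" for j in range(m)]
    return ExpressionMatrix(gene_ids, sample_ids, values)


def make_groups(sample_ids, n_tumor) -> SampleGroups:
    return SampleGroups(
        {s: ("tumor" if i < n_tumor else "normal") for i, s in enumerate(sample_ids)}
    )


# ---------------------------------------------------------------------------
# Modularity oracles
# ---------------------------------------------------------------------------

def modularity_by_formula(graph: nx.Graph, labels: dict) -> float:
    """Direct (brute-force) evaluation of the Newman-Girvan formula."""
    nodes = list(graph.nodes)
    two_m = 2.0 * graph.number_of_edges()
    deg = dict(graph.degree)
    q = 0.0
    for i in nodes:
        for j in nodes:
            if labels[i] == labels[j]:
                a = 1.0 if graph.has_edge(i, j) else 0.0
                q += a - deg[i] * deg[j] / two_m
    return q / two_m


def _set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = [0] * n

    def rec(i: int, maxlab: int):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab))

    yield from rec(1, 0)


def exhaustive_best_q(graph: nx.Graph) -> tuple[float, dict]:
    """Maximum modularity over every partition, by exhaustive search."""
    nodes = list(graph.nodes)
    n = len(nodes)
    edges = [(nodes.index(u), nodes.index(v)) for u, v in graph.edges]
    deg = np.array([graph.degree[v] for v in nodes], dtype=float)
    two_m = deg.sum()
    best_q, best_labels = -np.inf, None
    for part in _set_partitions(n):
        internal: dict[int, float] = {}
        degsum: dict[int, float] = {}
        for i, lab in enumerate(part):
            degsum[lab] = degsum.get(lab, 0.0) + deg[i]
        for u, v in edges:
            if part[u] == part[v]:
                internal[part[u]] = internal.get(part[u], 0.0) + 1.0
        q = sum(
            2.0 * internal.get(c, 0.0) / two_m - (degsum[c] / two_m) ** 2
            for c in degsum
        )
        if q > best_q:
            best_q, best_labels = q, part
    return best_q, dict(zip(nodes, best_labels))


def random_connected_graph(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    """Seeded G(n, p) conditioned on connectivity (rejection sampling)."""
    while True:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < p:
                g.add_edge(i, j)
        if g.number_of_edges() and nx.is_connected(g):
            return g


def two_clique_bridge(k: int = 4) -> nx.Graph:
    """Two K_k cliques joined by a single bridge edge."""
    g = nx.Graph()
    for off in (0, k):
        for i, j in itertools.combinations(range(off, off + k), 2):
            g.add_edge(i, j)
    g.add_edge(0, k)
    return g


# ---------------------------------------------------------------------------
# Metric oracles
# ---------------------------------------------------------------------------

def hypergeom_tail_by_sum(overlap, n_bg, n_term, n_mod) -> float:
    """P(X >= overlap) by explicit summation of the hypergeometric PMF."""
    from math import comb

    total = comb(n_bg, n_mod)
    acc = 0
    for x in range(overlap, min(n_term, n_mod) + 1):
        acc += comb(n_term, x) * comb(n_bg - n_term, n_mod - x)
    return acc / total


def auc_by_pair_counting(values, tumor_mask) -> float:
    """AUC as the fraction of (tumor, normal) pairs won (ties count 1/2)."""
    values = np.asarray(values, dtype=float)
    t = values[tumor_mask]
    n = values[~np.asarray(tumor_mask)]
    wins = 0.0
    for a in t:
        for b in n:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(t) * len(n))


def pagerank_by_linear_solve(graph: nx.Graph, damping: float = 0.85) -> dict:
    """Stationary PageRank from the dense linear system (I - dM)x = (1-d)/n."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v in graph.edges:
        a[pos[u], pos[v]] = 1.0
        a[pos[v], pos[u]] = 1.0
    out = a.sum(axis=1)
    m = np.zeros((n, n))
    nz = out > 0
    m[:, nz] = (a[nz] / out[nz, None]).T
    m[:, ~nz] = 1.0 / n  # dangling nodes teleport uniformly
    x = np.linalg.solve(np.eye(n) - damping * m, np.full(n, (1 - damping) / n))
    x = x / x.sum()
    return {v: float(x[pos[v]]) for v in nodes}


def logrank_by_hand(time, event, group) -> float:
    """Two-group logrank chi-square p-value from the O-E/V formula."""
    from scipy import stats

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)  # 1 = high stratum
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 1.0
    chi2 = o_minus_e**2 / var
    return float(stats.chi2.sf(chi2, df=1))
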