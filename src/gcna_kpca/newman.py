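"""Newman modularity maximization by the leading-eigenvector method.

Modularity Q compares the fraction of edges falling within communities
to the expectation under a degree-preserving random rewiring:

    Q = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) * delta(c_i, c_j)

The leading-eigenvector method recursively bisects the graph: each
candidate community is split by the sign pattern of the dominant
eigenvector of its generalized modularity matrix, refined by a
Kernighan-Lin-style single-node sweep, and the split is accepted only
when it increases Q.  The recursion bottoms out at indivisible
communities (no bisection with positive modularity gain).

The co-expression network is treated as unweighted by default (an edge
either exists or not); ``weighted=True`` uses |r| edge weights and node
strengths in place of adjacency and degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .core import CoexpressionNetwork, DataFormatError, DEFAULT_SEED

#: Subgraphs at or above this size use a seeded iterative eigensolver.
DENSE_EIGEN_LIMIT = 2000

#: Minimum modularity gain for accepting a split (guards numerical noise).
DELTA_Q_TOL = 1e-12


def _as_graph(network: CoexpressionNetwork | nx.Graph) -> nx.Graph:
    return network.graph if isinstance(network, CoexpressionNetwork) else network


def modularity(
    network: CoexpressionNetwork | nx.Graph,
    labels: dict[str, int],
    weighted: bool = False,
) -> float:
    """Newman-Girvan modularity of a labeling, by direct formula.

    Only labeled nodes participate; every labeled node's incident edges
    must stay among labeled nodes.  Raises on an edgeless graph, for
    which Q is undefined.
    """
    g = _as_graph(network)
    if g.number_of_edges() == 0:
        raise DataFormatError("modularity is undefined on an edgeless graph")
    nodes = [n for n in g.nodes if n in labels]
    sub = g.subgraph(nodes)
    wkey = "weight" if weighted else None
    two_m = 2.0 * sub.size(weight=wkey)
    if two_m == 0:
        raise DataFormatError("modularity is undefined on an edgeless subgraph")
    internal = {c: 0.0 for c in set(labels[n] for n in nodes)}
    degsum = dict.fromkeys(internal, 0.0)
    deg = dict(sub.degree(weight=wkey))
    for n in nodes:
        degsum[labels[n]] += deg[n]
    for u, v, d in sub.edges(data=True):
        if labels[u] == labels[v]:
            internal[labels[u]] += d.get("weight", 1.0) if weighted else 1.0
    return float(
        sum(2.0 * internal[c] / two_m - (degsum[c] / two_m) ** 2 for c in internal)
    )


def leading_eigenvector_bisect(
    adjacency: np.ndarray,
    degrees: np.ndarray,
    two_m: float,
    indices: np.ndarray | None = None,
    seed: int = DEFAULT_SEED,
) -> tuple[np.ndarray, float]:
    """Propose a bisection of a (sub)graph by the leading eigenvector.

    Parameters
    ----------
    adjacency : (n, n) array
        Adjacency of the *full* graph the community lives in.
    degrees : (n,) array
        Degrees (or strengths) in the full graph.
    two_m : float
        Twice the edge count (or total weight) of the full graph.
    indices : array of int, optional
        Node indices of the community to split; all nodes by default.
    seed : int
        Seed for the iterative eigensolver start vector on large
        subgraphs.

    Returns
    -------
    signs : (len(indices),) array of +-1
        Proposed side for each community member.
    delta_q : float
        Modularity gain of the refined split; ``<= 0`` means the
        community is indivisible.
    """
    if indices is None:
        indices = np.arange(adjacency.shape[0])
    n = len(indices)
    if n < 2:
        raise DataFormatError("cannot bisect a community of fewer than 2 nodes")

    a = adjacency[np.ix_(indices, indices)]
    k = degrees[indices]
    b = a - np.outer(k, k) / two_m
    # Generalized modularity matrix: subtract each row's sum on the
    # diagonal so that splitting a community is assessed in the context
    # of the full graph.
    bg = b - np.diag(b.sum(axis=1))

    if n < DENSE_EIGEN_LIMIT:
        evals, evecs = scipy.linalg.eigh(bg)
        lead = evecs[:, -1]
        lead_val = evals[-1]
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n)
        lead_val, lead = scipy.sparse.linalg.eigsh(bg, k=1, which="LA", v0=v0)
        lead_val = float(lead_val[0])
        lead = lead[:, 0]

    if lead_val <= DELTA_Q_TOL:
        return np.ones(n, dtype=int), 0.0

    s = np.where(lead >= 0.0, 1, -1).astype(int)  # exact zeros join the +1 side
    s = _kl_refine(bg, s)
    if len(set(s)) < 2:
        return np.ones(n, dtype=int), 0.0
    delta_q = float(s @ bg @ s) / (2.0 * two_m)
    return s, delta_q


def _kl_refine(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin-style sweep refinement of a sign split.

    Each pass moves every node exactly once, always taking the flip with
    the largest (possibly negative) gain, and keeps the best
    intermediate state of the pass; passes repeat while the objective
    s^T Bg s improves.
    """
    s = s.copy()
    n = len(s)
    diag = np.diag(bg).copy()
    for _ in range(n):  # passes; each strictly improves or we stop
        trial = s.copy()
        moved = np.zeros(n, dtype=bool)
        best_state = s.copy()
        best_total = 0.0
        total = 0.0
        for _ in range(n):
            bs = bg @ trial
            gains = -4.0 * trial * bs + 4.0 * diag  # effect of one flip
            gains[moved] = -np.inf
            pick = int(np.argmax(gains))
            total += gains[pick]
            trial[pick] = -trial[pick]
            moved[pick] = True
            if total > best_total + DELTA_Q_TOL:
                best_total = total
                best_state = trial.copy()
        if best_total <= DELTA_Q_TOL:
            break
        s = best_state
    return s


@dataclass
class CommunityResult:
    """Outcome of recursive leading-eigenvector community detection."""

    labels: dict[str, int]
    n_modules: int
    q: float
    isolated: list[str] = field(default_factory=list)


def detect_communities(
    network: CoexpressionNetwork | nx.Graph,
    weighted: bool = False,
    seed: int = DEFAULT_SEED,
) -> CommunityResult:
    """Recursively bisect every connected component until indivisible.

    Isolated (degree-0) nodes are set aside and reported separately —
    downstream clustering assigns them to modules by expression distance.
    K aggregates final communities across components; the reported Q is
    recomputed from the final labeling by the direct formula.
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise DataFormatError("cannot detect communities in an empty network")
    node_order = list(g.nodes)
    isolated = [n for n, d in g.degree if d == 0]
    core = [n for n in node_order if n not in set(isolated)]
    if not core:
        return CommunityResult(labels={}, n_modules=0, q=0.0, isolated=isolated)

    sub = g.subgraph(core)
    pos = {n: i for i, n in enumerate(core)}
    wkey = "weight" if weighted else None
    adjacency = nx.to_numpy_array(sub, nodelist=core, weight=wkey if weighted else None)
    if not weighted:
        adjacency = (adjacency != 0).astype(float)
    degrees = adjacency.sum(axis=1)
    two_m = float(degrees.sum())

    final_groups: list[np.ndarray] = []
    # Each connected component starts as one candidate community.
    components = sorted(
        (sorted(comp, key=pos.get) for comp in nx.connected_components(sub)),
        key=lambda c: pos[c[0]],
    )
    stack = [np.array([pos[n] for n in comp], dtype=int) for comp in components]
    while stack:
        idx = stack.pop()
        if len(idx) < 2:
            final_groups.append(idx)
            continue
        s, dq = leading_eigenvector_bisect(adjacency, degrees, two_m, idx, seed=seed)
        if dq > DELTA_Q_TOL and len(set(s)) == 2:
            stack.append(idx[s > 0])
            stack.append(idx[s < 0])
        else:
            final_groups.append(idx)

    lab_arr = np.empty(len(core), dtype=int)
    for c, idx in enumerate(final_groups):
        lab_arr[idx] = c
    lab_arr = _vertex_move_refine(adjacency, degrees, two_m, lab_arr)

    # renumber communities by first appearance in node order
    order: dict[int, int] = {}
    for lab in lab_arr:
        order.setdefault(int(lab), len(order))
    labels = {core[i]: order[int(lab_arr[i])] for i in range(len(core))}
    q = modularity(sub, labels, weighted=weighted)
    return CommunityResult(
        labels=labels, n_modules=len(set(labels.values())), q=q, isolated=isolated
    )


def _vertex_move_refine(
    adjacency: np.ndarray,
    degrees: np.ndarray,
    two_m: float,
    labels: np.ndarray,
) -> np.ndarray:
    """Final fine-tuning: greedy single-node moves between communities.

    Repeatedly relocates the node whose move to another existing
    community yields the largest modularity gain, while any positive
    gain remains.  Complements recursive bisection, which cannot revise
    an early cut once made.
    """
    labels = labels.copy()
    n = len(labels)
    m = two_m / 2.0
    comms = sorted(set(labels.tolist()))
    degsum = {c: float(degrees[labels == c].sum()) for c in comms}
    for _ in range(10 * n):
        best_gain, best_move = DELTA_Q_TOL, None
        for v in range(n):
            c = int(labels[v])
            # edges from v into each community
            k_vc = {d: float(adjacency[v, labels == d].sum()) for d in comms}
            for d in comms:
                if d == c:
                    continue
                gain = (k_vc[d] - k_vc[c]) / m - degrees[v] * (
                    degsum[d] - degsum[c] + degrees[v]
                ) / (2.0 * m * m)
                if gain > best_gain:
                    best_gain, best_move = gain, (v, c, d)
        if best_move is None:
            break
        v, c, d = best_move
        labels[v] = d
        degsum[c] -= degrees[v]
        degsum[d] += degrees[v]
        if not (labels == c).any():
            comms.remove(c)
            del degsum[c]
    return labels
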