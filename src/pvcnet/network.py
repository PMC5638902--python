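"""Group-level correlation brain networks and their graph metrics.

Pipeline (applied in this exact order, each stage tagged on the matrix):

1. ``correlation_network`` — Pearson correlation of region rows across
   subjects, negatives clipped to 0 (stage ``clipped``).
2. ``standardize_columns`` — column z-scores (stage ``zscored``).
3. ``normalize_and_threshold`` — divide by the global maximum, re-symmetrize
   by averaging with the transpose (z-scoring breaks symmetry), zero the
   diagonal, and keep the floor(p * m(m-1)/2) largest off-diagonal weights
   (stage ``thresholded``). ``threshold_absolute`` is the fixed-cutoff
   variant used for cross-group density comparisons.

Metrics: binary degree/density, global efficiency and betweenness centrality
on the binarized graph, weighted-undirected clustering (geometric-mean
triangle form on max-normalized weights), and modularity
``Q = sum_i [p_i/P - (d_i/2P)^2]`` with a seeded greedy maximizer (exact
enumeration for graphs with at most 8 nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .quantify import IntensityMatrix

STAGES = ("pearson", "clipped", "zscored", "normalized", "thresholded")


@dataclass
class ConnectivityMatrix:
    """Region x region weights plus the pipeline stage that produced them."""

    weights: np.ndarray
    stage: str
    node_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("connectivity weights must be a square matrix")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.node_labels is None:
            self.node_labels = np.arange(1, len(self.weights) + 1)
        self.node_labels = np.asarray(self.node_labels)
        if len(self.node_labels) != len(self.weights):
            raise ValueError("node_labels length must match the matrix size")

    @property
    def n_nodes(self) -> int:
        return len(self.weights)


@dataclass
class Partition:
    """Node -> module assignment for modularity evaluation."""

    assignment: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be a 1-D node -> module vector")

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.assignment))


@dataclass
class NetworkMetricsReport:
    """Density D, global efficiency, weighted clustering, max modularity, plus
    per-node degree and betweenness, for one (group, condition) network."""

    density: float
    global_efficiency: float
    clustering: float
    max_modularity: float
    degree: np.ndarray
    betweenness: np.ndarray
    group: str = ""
    condition: str = ""


# ---------------------------------------------------------------------------
# Construction pipeline
# ---------------------------------------------------------------------------


def correlation_network(intensity: IntensityMatrix) -> ConnectivityMatrix:
    """Pearson correlation of region rows across subjects, negatives clipped."""
    if intensity.n_subjects < 3:
        raise ValueError("correlation network requires at least 3 subjects")
    values = intensity.values
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = intensity.region_labels[sd == 0]
        raise ValueError(f"zero-variance region rows: labels {bad.tolist()}")
    C = np.corrcoef(values)
    C = np.clip(C, 0.0, None)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    return ConnectivityMatrix(C, stage="clipped", node_labels=intensity.region_labels)


def standardize_columns(weights: ConnectivityMatrix) -> ConnectivityMatrix:
    """Column z-scores (sample SD): every column gets mean 0 and SD 1."""
    W = weights.weights
    sd = W.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant columns at indices {bad.tolist()}")
    Z = (W - W.mean(axis=0)) / sd
    return ConnectivityMatrix(Z, stage="zscored", node_labels=weights.node_labels)


def proportional_cutoff(weights: np.ndarray, p: float) -> float:
    """The weight of the K-th largest off-diagonal entry retained at proportion p."""
    m = len(weights)
    sym = (weights + weights.T) / 2.0
    iu = np.triu_indices(m, k=1)
    vals = np.sort(sym[iu])[::-1]
    keep = int(np.floor(p * m * (m - 1) / 2))
    if keep == 0:
        return np.inf
    return float(vals[keep - 1])


def normalize_and_threshold(
    weights: ConnectivityMatrix, p: float = 0.1, global_max: float | None = None
) -> ConnectivityMatrix:
    """Global max-normalization followed by the proportional threshold.

    ``global_max`` overrides the matrix's own maximum as the normalization
    constant — for inter-group analysis the maximum connection value *of all
    group networks* is normalized to 1, so every network of a comparison
    should be divided by the same shared maximum.

    Keeps the floor(p * m(m-1)/2) largest off-diagonal weights with a stable
    index-order tie-break; the result is symmetric and non-negative with a
    zero diagonal.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    W = weights.weights
    mx = float(W.max()) if global_max is None else float(global_max)
    if mx <= 0:
        raise ValueError("all-zero (or non-positive) matrix cannot be normalized")
    C = W / mx
    C = (C + C.T) / 2.0  # z-scoring breaks symmetry; average with the transpose
    np.fill_diagonal(C, 0.0)
    m = len(C)
    iu, ju = np.triu_indices(m, k=1)
    vals = C[iu, ju]
    keep = int(np.floor(p * m * (m - 1) / 2))
    out = np.zeros_like(C)
    if keep > 0:
        order = np.argsort(-vals, kind="stable")  # stable: ties by index order
        sel = order[:keep]
        out[iu[sel], ju[sel]] = np.clip(vals[sel], 0.0, None)
        out = out + out.T
    return ConnectivityMatrix(out, stage="thresholded", node_labels=weights.node_labels)


def pooled_proportional_cutoff(
    networks: list[ConnectivityMatrix], p: float
) -> tuple[float, float]:
    """One absolute cutoff for an inter-group comparison.

    The shared normalization constant is the maximum connection value over all
    networks; the cutoff is the proportion-p threshold of the pooled
    (normalized, symmetrized) off-diagonal weights. Returns (cutoff, shared_max).
    """
    gmax = max(float(n.weights.max()) for n in networks)
    if gmax <= 0:
        raise ValueError("all networks are non-positive; cannot normalize")
    pooled = []
    for n in networks:
        C = (n.weights + n.weights.T) / 2.0 / gmax
        pooled.append(C[np.triu_indices(len(C), k=1)])
    vals = np.sort(np.concatenate(pooled))[::-1]
    keep = int(np.floor(p * len(vals)))
    if keep == 0:
        return np.inf, gmax
    return float(vals[keep - 1]), gmax


def threshold_absolute(
    weights: ConnectivityMatrix, cutoff: float, global_max: float | None = None
) -> ConnectivityMatrix:
    """Fixed-cutoff variant: keep off-diagonal weights >= cutoff.

    Used for cross-group comparisons at a fixed normalized weight (the cutoff
    is typically anchored as ``proportional_cutoff`` of a reference group).
    ``global_max`` shares one normalization constant across the compared
    networks, as in the proportional pipeline.
    """
    W = weights.weights
    mx = float(W.max()) if global_max is None else float(global_max)
    if mx <= 0:
        raise ValueError("all-zero (or non-positive) matrix cannot be normalized")
    C = W / mx
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 0.0)
    out = np.where(C >= cutoff, np.clip(C, 0.0, None), 0.0)
    np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(out, stage="thresholded", node_labels=weights.node_labels)


# ---------------------------------------------------------------------------
# Graph metrics
# ---------------------------------------------------------------------------


def _require_thresholded(weights: ConnectivityMatrix) -> np.ndarray:
    if weights.stage != "thresholded":
        raise ValueError(
            f"graph metrics expect a thresholded matrix, got stage {weights.stage!r}"
        )
    return weights.weights


def _binary_graph(W: np.ndarray) -> nx.Graph:
    return nx.from_numpy_array((W != 0).astype(int))


def degree_and_density(weights: ConnectivityMatrix) -> tuple[np.ndarray, float]:
    """Binary node degrees (row sums) and density d = 2K / (N^2 - N)."""
    W = _require_thresholded(weights)
    B = (W != 0).astype(int)
    degree = B.sum(axis=1)
    n = len(B)
    if n < 2:
        return degree, 0.0
    K = B[np.triu_indices(n, k=1)].sum()
    return degree, float(2.0 * K / (n * n - n))


def global_efficiency(weights: ConnectivityMatrix) -> float:
    """Mean inverse shortest path length over node pairs (binarized graph)."""
    W = _require_thresholded(weights)
    if len(W) < 2:
        return 0.0
    return float(nx.global_efficiency(_binary_graph(W)))


def clustering_coefficient(weights: ConnectivityMatrix, variant: str = "weighted") -> float:
    """Network-average clustering coefficient.

    ``weighted`` (default) is the geometric-mean-of-triangle-weights form on
    max-normalized weights (C_wu); ``binary`` counts triangles on the
    binarized graph. Degree-<2 nodes contribute 0.
    """
    W = _require_thresholded(weights)
    if len(W) < 3 or not (W != 0).any():
        return 0.0
    if variant == "binary":
        G = _binary_graph(W)
        cc = nx.clustering(G)
    elif variant == "weighted":
        G = nx.from_numpy_array(W)
        cc = nx.clustering(G, weight="weight")
    else:
        raise ValueError(f"unknown clustering variant {variant!r}")
    return float(np.mean(list(cc.values())))


def betweenness_centrality(weights: ConnectivityMatrix) -> np.ndarray:
    """Binarized-graph betweenness, normalized to [0, 1] by (N-1)(N-2)/2 pairs."""
    W = _require_thresholded(weights)
    G = _binary_graph(W)
    bc = nx.betweenness_centrality(G, normalized=True)
    return np.array([bc[i] for i in range(len(W))])


def betweenness_ranking(weights: ConnectivityMatrix) -> list[tuple[int, float]]:
    """(node label, betweenness) sorted descending — the hub table analogue."""
    bc = betweenness_centrality(weights)
    order = np.argsort(-bc, kind="stable")
    labels = weights.node_labels
    return [(int(labels[i]), float(bc[i])) for i in order]


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------


def modularity(weights: ConnectivityMatrix, partition: Partition) -> float:
    """Q = sum over modules of [p_i/P - (d_i/2P)^2] on the binarized graph."""
    W = _require_thresholded(weights)
    n = len(W)
    if len(partition.assignment) != n:
        raise ValueError("partition must cover every node exactly once")
    B = (W != 0).astype(int)
    np.fill_diagonal(B, 0)
    P = B[np.triu_indices(n, k=1)].sum()
    if P < 1:
        raise ValueError("modularity of an edgeless graph is undefined")
    deg = B.sum(axis=1)
    Q = 0.0
    for mod in np.unique(partition.assignment):
        members = partition.assignment == mod
        p_i = B[np.ix_(members, members)].sum() / 2
        d_i = deg[members].sum()
        Q += p_i / P - (d_i / (2.0 * P)) ** 2
    return float(Q)


def _partitions_rgs(n: int):
    """All set partitions of range(n) as restricted-growth assignment vectors."""
    a = np.zeros(n, dtype=int)
    b = np.zeros(n, dtype=int)  # b[k] = max(a[:k+1])
    while True:
        yield a.copy()
        # next restricted growth string
        for k in range(n - 1, 0, -1):
            if a[k] <= b[k - 1]:
                a[k] += 1
                b[k] = max(b[k - 1], a[k])
                a[k + 1 :] = 0
                b[k + 1 :] = b[k]
                break
        else:
            return


def _greedy_partition(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy agglomeration followed by node-move refinement (binary graph).

    Merging modules a, b changes Q by e_ab/P - d_a d_b / (2 P^2); moving a
    node v from A to B changes it by (e_vB - e_v,A\\{v})/P
    - d_v (D_B - D_A + d_v) / (2 P^2). Both are maintained incrementally.
    """
    n = len(B)
    P = float(B[np.triu_indices(n, k=1)].sum())
    deg = B.sum(axis=1).astype(float)

    # --- agglomeration on the module graph ---
    E = B.astype(float).copy()  # inter-module edge counts; diagonal unused
    D = deg.copy()  # module total degree
    alive = np.ones(n, dtype=bool)
    assign = np.arange(n)
    while alive.sum() > 1:
        idx = np.flatnonzero(alive)
        gains = E[np.ix_(idx, idx)] / P - np.outer(D[idx], D[idx]) / (2.0 * P * P)
        np.fill_diagonal(gains, -np.inf)
        a_, b_ = np.unravel_index(np.argmax(gains), gains.shape)
        if gains[a_, b_] <= 1e-12:
            break
        a_, b_ = int(idx[a_]), int(idx[b_])
        assign[assign == b_] = a_
        E[a_, :] += E[b_, :]
        E[:, a_] += E[:, b_]
        D[a_] += D[b_]
        alive[b_] = False

    # --- node-move refinement, order shuffled reproducibly ---
    D_mod = np.zeros(n)
    for mod in np.unique(assign):
        D_mod[mod] = deg[assign == mod].sum()
    improved = True
    while improved:
        improved = False
        for node in rng.permutation(n):
            cur = assign[node]
            e_to = np.bincount(assign, weights=B[node], minlength=n)
            base = e_to[cur]  # includes nothing for self (diagonal is 0)
            d_v = deg[node]
            gains = (e_to - base) / P - d_v * (D_mod - D_mod[cur] + d_v) / (
                2.0 * P * P
            )
            gains[cur] = 0.0
            # only occupied modules are candidates
            occupied = np.bincount(assign, minlength=n) > 0
            gains[~occupied] = -np.inf
            best = int(np.argmax(gains))
            if gains[best] > 1e-12:
                assign[node] = best
                D_mod[cur] -= d_v
                D_mod[best] += d_v
                improved = True
    return assign


def maximize_modularity(
    weights: ConnectivityMatrix, seed: int = 0
) -> tuple[Partition, float]:
    """Maximize Q over node partitions.

    Exact exhaustive enumeration for graphs with <= 8 nodes (Bell(8) = 4140
    partitions); greedy agglomeration plus seeded node-move refinement above.
    Deterministic under ``seed``; the returned value equals
    ``modularity(weights, partition)`` for the returned partition.
    """
    W = _require_thresholded(weights)
    n = len(W)
    B = (W != 0).astype(int)
    np.fill_diagonal(B, 0)
    P = B[np.triu_indices(n, k=1)].sum()
    if P < 1:
        raise ValueError("modularity maximization requires at least one edge")
    if n <= 8:
        best_q, best_assign = -np.inf, None
        for assign in _partitions_rgs(n):
            q = modularity(weights, Partition(assign))
            if q > best_q:
                best_q, best_assign = q, assign
        part = Partition(best_assign)
        return part, float(best_q)
    rng = np.random.default_rng(seed)
    best_part, best_q = None, -np.inf
    for _ in range(3):  # a few restarts guard against greedy local optima
        part = Partition(_greedy_partition(B, rng))
        q = modularity(weights, part)
        if q > best_q:
            best_part, best_q = part, q
    return best_part, float(best_q)


def metrics_report(
    weights: ConnectivityMatrix,
    group: str = "",
    condition: str = "",
    seed: int = 0,
) -> NetworkMetricsReport:
    """All Table-3-style metrics for one thresholded network."""
    degree, density = degree_and_density(weights)
    _, m_max = maximize_modularity(weights, seed=seed)
    return NetworkMetricsReport(
        density=density,
        global_efficiency=global_efficiency(weights),
        clustering=clustering_coefficient(weights),
        max_modularity=m_max,
        degree=degree,
        betweenness=betweenness_centrality(weights),
        group=group,
        condition=condition,
    )
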