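"""Weighted small-world metrics for hemispheric networks.

Edge lengths are the reciprocal of edge weights (a stronger connection
is a shorter path), so all path-based quantities — characteristic path
length L_w, global efficiency E_global, nodal efficiency E_nodal — are
computed on ``L_ij = 1/w_ij`` shortest paths.  Clustering C_w is the
Onnela geometric-mean triangle intensity, which lies in [0, 1] when
weights are normalized to a maximum of 1.  Small-worldness is assessed
against degree-preserving rewired null networks:

    gamma = C_w / <C_w^rand>,  lambda = L_w / <L_w^rand>,
    sigma = gamma / lambda,

with the null averages taken over matched random networks obtained by
double-edge swaps that preserve the binary degree sequence (weights
travel with their edges) and, where possible, connectedness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .build import HemiNetwork, validate_connectome


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest path lengths on reciprocal-weight edges."""

    lengths: np.ndarray  # L_ij, np.inf where unreachable

    @property
    def n_nodes(self) -> int:
        return self.lengths.shape[0]

    @property
    def reachable(self) -> np.ndarray:
        r = np.isfinite(self.lengths)
        np.fill_diagonal(r.copy(), True)
        return r

    @property
    def n_unreachable_pairs(self) -> int:
        """Unreachable ordered pairs i != j."""
        off = ~np.eye(self.n_nodes, dtype=bool)
        return int(np.sum(~np.isfinite(self.lengths) & off))


@dataclass
class GlobalMetrics:
    c_w: float
    l_w: float
    e_global: float
    e_local: float
    n_unreachable_pairs: int = 0
    c_w_rand: float | None = None
    l_w_rand: float | None = None
    gamma: float | None = None
    lam: float | None = None
    sigma: float | None = None


def _weights(hn: HemiNetwork | np.ndarray) -> np.ndarray:
    return hn.weights if isinstance(hn, HemiNetwork) else np.asarray(hn, dtype=float)


def normalize_weights_joint(
    left: HemiNetwork, right: HemiNetwork
) -> tuple[HemiNetwork, HemiNetwork]:
    """Divide both hemispheric networks by their single joint maximum weight.

    Joint (rather than per-network) normalization bounds the Onnela
    clustering coefficient in [0, 1] while preserving the left/right
    weight ratio — per-network normalization would cancel exactly the
    global asymmetry effects under study.
    """
    w_max = max(left.weights.max(), right.weights.max())
    if w_max == 0:
        raise ValueError("cannot normalize: both networks are empty")
    from dataclasses import replace

    return (
        replace(left, weights=left.weights / w_max, normalized=True),
        replace(right, weights=right.weights / w_max, normalized=True),
    )


def shortest_paths(hn: HemiNetwork | np.ndarray) -> DistanceMatrix:
    """Dijkstra all-pairs shortest paths on edge lengths ``1/w_ij``."""
    w = _weights(hn)
    validate_connectome(w)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    return DistanceMatrix(lengths=dist)


def clustering_coefficient_w(hn: HemiNetwork | np.ndarray) -> float:
    """Onnela weighted clustering coefficient, averaged over all N nodes.

    Per node: ``(1/(k_i(k_i-1))) * sum_{j,k} (w_ij w_jk w_ki)^(1/3)``
    over ordered neighbor pairs; nodes of degree < 2 contribute 0.
    Weights must be normalized (max 1) for the [0, 1] bound to hold.
    """
    w = _weights(hn)
    cw = np.cbrt(w)
    triangles = np.diag(cw @ cw @ cw)  # 2x the per-node triangle intensity sum
    k = np.count_nonzero(w, axis=1)
    denom = k * (k - 1)
    per_node = np.divide(triangles, denom, out=np.zeros_like(triangles), where=denom > 0)
    return float(per_node.mean())


def characteristic_path_length_w(dm: DistanceMatrix) -> float:
    """Mean shortest path length over reachable ordered pairs i != j."""
    n = dm.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dm.lengths) & off
    if not finite.any():
        raise ValueError("empty network: no reachable pair")
    return float(dm.lengths[finite].mean())


def global_efficiency(dm: DistanceMatrix) -> float:
    """Mean of 1/L_ij over all ordered pairs (1/inf = 0 for unreachable)."""
    n = dm.n_nodes
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dm.lengths) & (dm.lengths > 0), 1.0 / dm.lengths, 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def nodal_efficiency(dm: DistanceMatrix) -> np.ndarray:
    """Per-node efficiency: ``E_nodal(i) = (1/(N-1)) sum_{j!=i} 1/L_ij``."""
    n = dm.n_nodes
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dm.lengths) & (dm.lengths > 0), 1.0 / dm.lengths, 0.0)
    return inv.sum(axis=1, where=off) / (n - 1)


def local_efficiency(hn: HemiNetwork | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbor subgraph.

    The subgraph induced by node i's neighbors keeps its original edge
    weights; nodes with fewer than two neighbors contribute 0.
    """
    w = _weights(hn)
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), 0.0)
        dist = shortest_path(lengths, method="D", directed=False)
        total += global_efficiency(DistanceMatrix(lengths=dist))
    return total / n


def node_degrees(hn: HemiNetwork | np.ndarray) -> np.ndarray:
    return np.count_nonzero(_weights(hn), axis=1)


def is_connected(w: np.ndarray) -> bool:
    n_comp, _ = connected_components(w, directed=False)
    return n_comp == 1


def _swap_kernel(
    out: np.ndarray,
    ea: np.ndarray,
    eb: np.ndarray,
    picks: np.ndarray,
    flips: np.ndarray,
    n_swaps: int,
) -> int:
    """Apply weighted double-edge swaps; proposals come pre-drawn.

    Each proposal names two edge slots and an orientation flip; it is
    rejected if it would create a self-loop or a multi-edge.  Weights
    travel with their first endpoint.  Returns the number of swaps done.
    """
    done = 0
    for k in range(picks.shape[0]):
        e1, e2 = picks[k, 0], picks[k, 1]
        if e1 == e2:
            continue
        a, b = ea[e1], eb[e1]
        c, d = ea[e2], eb[e2]
        if flips[k]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if out[a, d] > 0 or out[c, b] > 0:
            continue
        w1, w2 = out[a, b], out[c, d]
        out[a, b] = 0.0
        out[b, a] = 0.0
        out[c, d] = 0.0
        out[d, c] = 0.0
        out[a, d] = w1
        out[d, a] = w1
        out[c, b] = w2
        out[b, c] = w2
        ea[e1], eb[e1] = min(a, d), max(a, d)
        ea[e2], eb[e2] = min(c, b), max(c, b)
        done += 1
        if done >= n_swaps:
            break
    return done


try:  # the kernel is pure index arithmetic; JIT it when numba is available
    from numba import njit

    _swap_kernel = njit(cache=False)(_swap_kernel)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def _double_edge_swaps(
    w: np.ndarray, n_swaps: int, rng: np.random.Generator, max_tries: int
) -> np.ndarray:
    """Perform up to ``n_swaps`` weighted double-edge swaps on a copy of ``w``."""
    out = w.copy()
    iu, ju = np.nonzero(np.triu(out, k=1))
    ea = iu.astype(np.int64)
    eb = ju.astype(np.int64)
    n_edges = len(ea)
    picks = rng.integers(0, n_edges, size=(max_tries, 2))
    flips = rng.random(max_tries) < 0.5
    _swap_kernel(out, ea, eb, picks, flips, n_swaps)
    return out


def rewire_preserving_degree(
    hn: HemiNetwork | np.ndarray,
    swaps_per_edge: int = 10,
    seed: int = 0,
    max_attempts: int = 10,
) -> np.ndarray:
    """Degree-preserving randomization by weighted double-edge swaps.

    Each swap exchanges the endpoints of two randomly chosen edges,
    rejected if it would create a self-loop or multi-edge; weights
    travel with their edges, so the binary degree sequence and the
    weight multiset are preserved exactly.  If the input was connected
    and an attempt disconnects it, the full rewiring is retried (up to
    ``max_attempts``) and the attempt with the fewest components is
    returned as a last resort.  Graphs with no admissible swap (e.g. a
    complete graph) are returned unchanged.
    """
    w = _weights(hn)
    n = w.shape[0]
    n_edges = int(np.count_nonzero(np.triu(w, k=1)))
    if n_edges == n * (n - 1) // 2 or n_edges < 2:
        return w.copy()  # no admissible swap exists
    n_swaps = swaps_per_edge * n_edges
    max_tries = 20 * n_swaps
    was_connected = is_connected(w)
    seeds = np.random.SeedSequence(seed).spawn(max_attempts)
    best, best_ncomp = None, np.inf
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seeds[attempt])
        candidate = _double_edge_swaps(w, n_swaps, rng, max_tries)
        if not was_connected:
            return candidate
        n_comp, _ = connected_components(candidate, directed=False)
        if n_comp == 1:
            return candidate
        if n_comp < best_ncomp:
            best, best_ncomp = candidate, n_comp
    return best  # disconnected despite retries; caller may flag it


def compute_global_metrics(hn: HemiNetwork | np.ndarray) -> GlobalMetrics:
    """C_w, L_w, E_global, E_local (no null-model quantities)."""
    dm = shortest_paths(hn)
    return GlobalMetrics(
        c_w=clustering_coefficient_w(hn),
        l_w=characteristic_path_length_w(dm),
        e_global=global_efficiency(dm),
        e_local=local_efficiency(hn),
        n_unreachable_pairs=dm.n_unreachable_pairs,
    )


def small_worldness(
    hn: HemiNetwork | np.ndarray,
    n_null: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> GlobalMetrics:
    """Small-world parameters against degree-preserving rewired nulls.

    ``n_null`` matched random networks are generated (default 100);
    gamma = C_w / mean(C_w^rand), lambda = L_w / mean(L_w^rand),
    sigma = gamma / lambda.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    gm = compute_global_metrics(hn)
    w = _weights(hn)
    null_seeds = np.random.SeedSequence(seed).generate_state(n_null)
    c_rand = np.empty(n_null)
    l_rand = np.empty(n_null)
    for i in range(n_null):
        null = rewire_preserving_degree(w, swaps_per_edge=swaps_per_edge, seed=int(null_seeds[i]))
        c_rand[i] = clustering_coefficient_w(null)
        l_rand[i] = characteristic_path_length_w(shortest_paths(null))
    gm.c_w_rand = float(c_rand.mean())
    gm.l_w_rand = float(l_rand.mean())
    if gm.c_w_rand == 0 or gm.l_w_rand == 0:
        raise ValueError("degenerate null: zero mean clustering or path length")
    gm.gamma = gm.c_w / gm.c_w_rand
    gm.lam = gm.l_w / gm.l_w_rand
    gm.sigma = gm.gamma / gm.lam
    return gm


def integrate_over_sparsity(values, levels) -> float:
    """Area under the metric-sparsity curve divided by the grid span.

    The trapezoidal integral over the (sorted) sparsity levels,
    normalized by ``s_max - s_min``; a single level returns its value.
    """
    values = np.asarray(values, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if values.shape != levels.shape:
        raise ValueError("values and levels must have equal length")
    if values.size == 0:
        raise ValueError("no sparsity levels")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite metric values")
    if values.size == 1:
        return float(values[0])
    order = np.argsort(levels)
    levels, values = levels[order], values[order]
    span = levels[-1] - levels[0]
    return float(np.trapezoid(values, levels) / span)
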