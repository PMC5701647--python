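"""Paired network-based statistic (NBS) for lateralized connections.

For every homotopic edge, a paired t statistic compares left- and
right-hemisphere weights across subjects.  Edges exceeding a
component-forming threshold are assembled into connected components
(candidate lateralized subnetworks), and each component's size (edge
count) is referred to a permutation null distribution of the *maximal*
component size obtained by randomly swapping the left/right labels
within each subject — which controls the family-wise error over all
components of that analysis.  The two effect directions (left > right
and right > left) are analyzed as separate one-tailed component
searches, each referred to its own tail's permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Replaces an infinite t (nonzero mean difference with zero variance).
T_SENTINEL = 1e12


@dataclass
class Component:
    edges: list[tuple[int, int]]
    tail: str  # "left>right" or "right>left"
    p_corrected: float | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> list[int]:
        return sorted({k for e in self.edges for k in e})


@dataclass
class NBSResult:
    t_map: np.ndarray
    t_threshold: float
    components: list[Component]
    null_max_sizes: np.ndarray  # (n_perm, 2): per-tail max component sizes
    n_perm: int
    seed: int
    exhaustive: bool = False
    zero_variance_edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def significant(self) -> list[Component]:
        return [c for c in self.components if c.p_corrected is not None and c.p_corrected < 0.05]


def _stack_to_edges(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_subjects, N, N) -> (n_subjects, n_edges) over the upper triangle."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("stack must have shape (n_subjects, N, N)")
    n = stack.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    return stack[:, iu, ju], iu, ju


def _edge_tstats(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paired t per edge from difference rows ``d`` (n_subjects x n_edges).

    Returns (t, zero_variance mask).  Zero-variance edges get t = 0 when
    the mean difference is 0, otherwise a signed large sentinel.
    """
    n = d.shape[0]
    mean = d.mean(axis=0)
    var = d.var(axis=0, ddof=1)
    zero_var = var == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t = np.where(zero_var, np.where(mean == 0, 0.0, np.sign(mean) * T_SENTINEL), t)
    return t, zero_var


def paired_edge_tstats(left_stack: np.ndarray, right_stack: np.ndarray) -> np.ndarray:
    """Edge-wise paired t map (left minus right), as a symmetric N x N matrix."""
    dl, iu, ju = _stack_to_edges(left_stack)
    dr, _, _ = _stack_to_edges(right_stack)
    if dl.shape != dr.shape:
        raise ValueError("left and right stacks have different shapes")
    if dl.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a paired t-test")
    t, _ = _edge_tstats(dl - dr)
    n = left_stack.shape[1]
    t_map = np.zeros((n, n))
    t_map[iu, ju] = t
    t_map += t_map.T
    return t_map


def _components_from_edges(
    edge_nodes: np.ndarray,
) -> list[list[int]]:
    """Group edge indices into connected components (union-find)."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edge_nodes:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for k, (a, _b) in enumerate(edge_nodes):
        groups.setdefault(find(a), []).append(k)
    return list(groups.values())


def _max_component_size(edge_nodes: np.ndarray) -> int:
    if len(edge_nodes) == 0:
        return 0
    return max(len(g) for g in _components_from_edges(edge_nodes))


def suprathreshold_components(
    t_map: np.ndarray, t_threshold: float, tail: str = "left>right"
) -> list[Component]:
    """Connected components of edges beyond the threshold, largest first.

    ``left>right`` keeps edges with ``t > t_threshold`` (t is computed on
    left-minus-right differences); ``right>left`` keeps ``t < -t_threshold``.
    """
    if t_threshold <= 0:
        raise ValueError("t_threshold must be positive")
    if tail not in ("left>right", "right>left"):
        raise ValueError(f"unknown tail: {tail!r}")
    n = t_map.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    t = t_map[iu, ju]
    mask = t > t_threshold if tail == "left>right" else t < -t_threshold
    edge_nodes = np.column_stack([iu[mask], ju[mask]])
    comps = []
    for group in _components_from_edges(edge_nodes):
        edges = [(int(edge_nodes[k, 0]), int(edge_nodes[k, 1])) for k in group]
        comps.append(Component(edges=sorted(edges), tail=tail))
    comps.sort(key=lambda c: -c.n_edges)
    return comps


def _null_max_sizes(
    d: np.ndarray,
    valid: np.ndarray,
    iu: np.ndarray,
    ju: np.ndarray,
    t_threshold: float,
    signs: np.ndarray,
) -> np.ndarray:
    """Per-tail max suprathreshold component size for each sign pattern.

    Returns an ``(n_perm, 2)`` array: column 0 is the left>right tail,
    column 1 the right>left tail.  Sign-flipping leaves each subject's
    squared differences unchanged, so the permuted t statistics need
    only the flipped means.
    """
    n = d.shape[0]
    sum_sq = (d**2).sum(axis=0)
    means = signs @ d / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.clip((sum_sq - n * means**2) / (n - 1), 0.0, None)
        t = means / np.sqrt(var / n)
    t = np.where(var == 0, np.where(means == 0, 0.0, np.sign(means) * T_SENTINEL), t)
    t[:, ~valid] = 0.0
    out = np.empty((signs.shape[0], 2), dtype=int)
    for p in range(signs.shape[0]):
        row = t[p]
        for col, mask in enumerate((row > t_threshold, row < -t_threshold)):
            size = 0
            if mask.any():
                size = _max_component_size(np.column_stack([iu[mask], ju[mask]]))
            out[p, col] = size
    return out


def nbs_paired(
    left_stack: np.ndarray,
    right_stack: np.ndarray,
    t_threshold: float = 3.0,
    n_perm: int = 5000,
    seed: int = 0,
    exhaustive: bool = False,
) -> NBSResult:
    """Paired NBS with a within-subject hemisphere-swap permutation null.

    Each permutation independently swaps the left/right networks of each
    subject with probability 1/2 (a sign flip of the paired
    differences), recomputes the edge-wise t map, and records the
    maximal suprathreshold component size of each tail.  The corrected p
    of an observed component of size ``K`` is
    ``(1 + #{perm: max >= K}) / (1 + n_perm)`` against its own tail's
    null.  With
    ``exhaustive=True`` all 2^n sign patterns are enumerated (n <= 20)
    and the p value is the exact proportion ``#{max >= K} / 2^n``
    (the identity relabeling is part of the enumeration, so no
    smoothing is applied).

    Edges whose paired differences have zero variance across subjects
    are excluded from component formation (their t is undefined).
    """
    if t_threshold <= 0:
        raise ValueError("t_threshold must be positive")
    dl, iu, ju = _stack_to_edges(left_stack)
    dr, _, _ = _stack_to_edges(right_stack)
    if dl.shape != dr.shape:
        raise ValueError("left and right stacks have different shapes")
    n_subjects = dl.shape[0]
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    d = dl - dr
    t, zero_var = _edge_tstats(d)
    valid = ~zero_var
    n = left_stack.shape[1]
    t_map = np.zeros((n, n))
    t_map[iu, ju] = t
    t_map += t_map.T

    t_masked = np.where(valid, t, 0.0)
    masked_map = np.zeros((n, n))
    masked_map[iu, ju] = t_masked
    masked_map += masked_map.T
    components = suprathreshold_components(
        masked_map, t_threshold, "left>right"
    ) + suprathreshold_components(masked_map, t_threshold, "right>left")
    components.sort(key=lambda c: -c.n_edges)

    if exhaustive:
        if n_subjects > 20:
            raise ValueError("exhaustive enumeration limited to 20 subjects")
        n_total = 2**n_subjects
        bits = (np.arange(n_total)[:, None] >> np.arange(n_subjects)) & 1
        signs = 1.0 - 2.0 * bits
        null_max = _null_max_sizes(d, valid, iu, ju, t_threshold, signs)
        for comp in components:
            col = 0 if comp.tail == "left>right" else 1
            comp.p_corrected = float(np.sum(null_max[:, col] >= comp.n_edges) / n_total)
        n_perm_out = n_total
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        signs = 1.0 - 2.0 * rng.integers(0, 2, size=(n_perm, n_subjects))
        null_max = _null_max_sizes(d, valid, iu, ju, t_threshold, signs)
        for comp in components:
            col = 0 if comp.tail == "left>right" else 1
            comp.p_corrected = float(
                (1 + np.sum(null_max[:, col] >= comp.n_edges)) / (1 + n_perm)
            )
        n_perm_out = n_perm

    return NBSResult(
        t_map=t_map,
        t_threshold=float(t_threshold),
        components=components,
        null_max_sizes=null_max,
        n_perm=n_perm_out,
        seed=seed,
        exhaustive=exhaustive,
        zero_variance_edges=[(int(i), int(j)) for i, j in zip(iu[zero_var], ju[zero_var])],
    )
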