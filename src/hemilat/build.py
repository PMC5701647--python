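"""Connectome construction and hemispheric decomposition.

Functional networks: Pearson correlation between ROI time series,
Fisher r-to-z transformed, negative connections removed.  Structural
networks: streamline density, i.e. streamline count divided by the
summed volumes of the two connected regions.  Whole-brain 90x90
matrices are then split into 45x45 intrahemispheric networks ordered by
homotopic pair, and (for the functional arm) thresholded to a grid of
fixed sparsity values, retaining the supra-threshold weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .regions import N_PAIRS, hemisphere_indices, validate_node_table

#: |r| is clipped here before atanh so perfect correlations stay finite.
R_CLIP = 0.999999


@dataclass(frozen=True)
class HemiNetwork:
    """One 45x45 intrahemispheric weighted network.

    Rows/columns are ordered by homotopic pair index, so index ``k`` in
    the left network refers to the same region as index ``k`` in the
    right network of the same subject.
    """

    weights: np.ndarray
    hemisphere: str  # "L" or "R"
    subject_id: str = ""
    modality: str = ""  # "structural" or "functional"
    sparsity: float | None = None  # None = unthresholded
    normalized: bool = False
    unreachable_sparsity: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        validate_connectome(w)
        object.__setattr__(self, "weights", w)
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))


def validate_connectome(w: np.ndarray, atol: float = 1e-8) -> None:
    """Assert the symmetric / nonnegative / zero-diagonal / finite contract."""
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"connectome must be square, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("connectome contains non-finite entries")
    if not np.allclose(w, w.T, atol=atol):
        i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
        raise ValueError(f"connectome is asymmetric at entry ({i}, {j})")
    if np.any(np.diag(w) != 0):
        raise ValueError("connectome diagonal must be zero")
    if np.any(w < 0):
        i, j = np.unravel_index(np.argmin(w), w.shape)
        raise ValueError(
            f"negative weight at ({i}, {j}); only positive connections are retained"
        )


def functional_connectivity(timeseries: np.ndarray) -> np.ndarray:
    """Positive Fisher-z functional connectivity from ROI time series.

    Pairwise Pearson correlations are clipped to ``|r| <= 0.999999``,
    Fisher transformed (``z = atanh r``), and negative values are set to
    zero; the diagonal is zero.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D (time x regions) array")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contain non-finite values")
    variances = ts.var(axis=0)
    dead = np.flatnonzero(variances == 0)
    if dead.size:
        raise ValueError(f"region column {dead[0]} has zero variance")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    z[z < 0] = 0.0
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return z


def structural_density(streamline_counts: np.ndarray, roi_volumes: np.ndarray) -> np.ndarray:
    """Streamline-density connectome: ``w_ij = counts_ij / (vol_i + vol_j)``."""
    counts = np.asarray(streamline_counts, dtype=float)
    volumes = np.asarray(roi_volumes, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("streamline counts must be a square matrix")
    if counts.shape[0] != volumes.shape[0]:
        raise ValueError("volume vector length must match the count matrix")
    if not np.array_equal(counts, counts.T):
        raise ValueError("streamline count matrix must be symmetric")
    if np.any(counts < 0):
        raise ValueError("streamline counts must be nonnegative")
    if np.any(volumes <= 0):
        raise ValueError(f"ROI volume {int(np.argmin(volumes))} is nonpositive")
    denom = volumes[:, None] + volumes[None, :]
    w = counts / denom
    np.fill_diagonal(w, 0.0)
    return w


def split_hemispheres(
    connectome: np.ndarray, node_table: pd.DataFrame, subject_id: str = "", modality: str = ""
) -> tuple[HemiNetwork, HemiNetwork]:
    """Discard interhemispheric connections; return (left, right) 45x45 networks.

    Both outputs are ordered by homotopic pair index, so the networks
    are directly comparable entry by entry.
    """
    validate_node_table(node_table)
    w = np.asarray(connectome, dtype=float)
    if w.shape != (len(node_table), len(node_table)):
        raise ValueError(
            f"connectome shape {w.shape} does not match node table ({len(node_table)} rows)"
        )
    validate_connectome(w)
    left_idx, right_idx = hemisphere_indices(node_table)
    left = HemiNetwork(
        w[np.ix_(left_idx, left_idx)], "L", subject_id=subject_id, modality=modality
    )
    right = HemiNetwork(
        w[np.ix_(right_idx, right_idx)], "R", subject_id=subject_id, modality=modality
    )
    return left, right


def _edge_count(s: float, n: int) -> int:
    """Number of edges at sparsity ``s``: round-half-away-from-zero of s*n(n-1)/2."""
    total = n * (n - 1) // 2
    return int(np.floor(s * total + 0.5))


def threshold_sparsity(hn: HemiNetwork, s: float) -> HemiNetwork:
    """Keep the K strongest edges (K = round(s * N(N-1)/2)) at their weights.

    Ties at the cutoff are broken deterministically: descending weight,
    then ascending (i, j) lexicographic.  If the network has fewer than
    K nonzero edges, all of them are kept and the output is flagged
    ``unreachable_sparsity``.
    """
    if not (0 < s <= 1):
        raise ValueError(f"sparsity must lie in (0, 1], got {s}")
    w = hn.weights
    n = hn.n_nodes
    k_target = _edge_count(s, n)
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    nonzero = vals > 0
    order = np.lexsort((ju, iu, -vals))  # weight desc, then (i, j) asc
    order = order[nonzero[order]]
    unreachable = len(order) < k_target
    keep = order[:k_target]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = vals[keep]
    out += out.T
    return replace(
        hn, weights=out, sparsity=float(s), unreachable_sparsity=bool(unreachable)
    )


def sparsity_grid(s_min: float = 0.10, s_max: float = 0.35, step: float = 0.01) -> np.ndarray:
    """Inclusive grid of sparsity levels; the defaults give 26 levels."""
    if not s_min < s_max:
        raise ValueError("require s_min < s_max")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(np.floor((s_max - s_min) / step + 1e-9))
    levels = s_min + step * np.arange(n_steps + 1)
    if levels.size == 0:
        raise ValueError("empty sparsity grid")
    return levels


def sparsity_series(
    hn: HemiNetwork, s_min: float = 0.10, s_max: float = 0.35, step: float = 0.01
) -> list[HemiNetwork]:
    """Threshold ``hn`` at every level of the sparsity grid (nested edge sets)."""
    return [threshold_sparsity(hn, float(s)) for s in sparsity_grid(s_min, s_max, step)]


def iter_hemispheres(pair: tuple[HemiNetwork, HemiNetwork]) -> Iterator[HemiNetwork]:
    yield from pair
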