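"""Layer assignment, d-spacing and undulation analysis of LDH slabs.

Metal atoms are grouped into mineral layers by DBSCAN density clustering
(points at most ``eps`` = 5 Angstrom apart belong to the same layer), layers
are ordered by mean z, and two descriptors are derived:

* the d-spacing between adjacent layers, globally and as a local map produced
  by a 5 x 5 Angstrom window slid across the xy-plane in 1 Angstrom steps;
* layer undulation, the pooled standard deviation of metal z-coordinates
  after translating every layer's centre to the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .io import Frame, Role, Trajectory

__all__ = [
    "LayerAssignment",
    "DSpacingProfile",
    "UndulationStats",
    "assign_layers",
    "d_spacing",
    "undulation",
]

_METAL_ROLES = (Role.LDH_METAL_MG.value, Role.LDH_METAL_AL.value)


@dataclass
class LayerAssignment:
    """Metal atoms grouped into layers ordered by mean z.

    ``labels[i]`` is the layer index of the i-th metal atom (order of
    ``metal_rows``), −1 marks DBSCAN noise points; ``mean_z`` is sorted
    ascending.
    """

    metal_rows: np.ndarray  # indices into the frame's atom table
    labels: np.ndarray
    mean_z: np.ndarray
    n_noise: int = 0
    warning: str | None = None

    @property
    def n_layers(self) -> int:
        return len(self.mean_z)


@dataclass
class DSpacingProfile:
    """Adjacent-layer separations: global statistics and local maps.

    ``local_maps[p]`` is the (nwx, nwy) grid of local d-spacings for adjacent
    pair p (lower layer p, upper layer p+1), NaN where a window saw no atoms in
    one of the two layers; ``pair_mean``/``pair_std`` are over a pair's valid
    windows; ``mean``/``std`` pool every valid window of every pair.
    """

    pair_mean: np.ndarray
    pair_std: np.ndarray
    local_maps: list[np.ndarray]
    window: float
    step: float
    mean: float
    std: float


@dataclass
class UndulationStats:
    """z standard deviation of centred metal layers (Angstrom)."""

    per_layer_std: np.ndarray
    pooled_std: float


def _metal_coords(frame: Frame) -> tuple[np.ndarray, np.ndarray]:
    mask = frame.atoms["role"].isin(_METAL_ROLES).to_numpy()
    rows = np.flatnonzero(mask)
    return rows, frame.coords[rows]


def assign_layers(
    frame: Frame, eps: float = 5.0, min_samples: int = 4, expected: int | None = None
) -> LayerAssignment:
    """Cluster metal atoms into layers with DBSCAN (3-D distance, radius eps).

    Clusters are relabelled in order of increasing mean z.  Noise points are
    reported, never silently dropped.  When ``expected`` is given and the
    cluster count differs, a warning is attached (and emitted).
    """
    rows, coords = _metal_coords(frame)
    if len(rows) == 0:
        raise ValueError("frame contains no LDH metal atoms")
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)
    cluster_ids = [c for c in np.unique(raw) if c != -1]
    mean_z = np.array([coords[raw == c, 2].mean() for c in cluster_ids])
    order = np.argsort(mean_z)
    if len(mean_z) > 1 and np.any(np.diff(np.sort(mean_z)) == 0.0):
        raise ValueError("degenerate layers with identical mean z")
    relabel = {cluster_ids[o]: rank for rank, o in enumerate(order)}
    labels = np.array([relabel.get(c, -1) for c in raw])
    n_noise = int(np.sum(raw == -1))
    warning = None
    if expected is not None and len(cluster_ids) != expected:
        warning = f"found {len(cluster_ids)} layers, expected {expected}"
        warnings.warn(warning, stacklevel=2)
    return LayerAssignment(rows, labels, np.sort(mean_z), n_noise, warning)


def _window_starts(length: float, window: float, step: float, periodic: bool) -> np.ndarray:
    if periodic:
        return np.arange(0.0, length, step)
    n = int(np.floor((length - window) / step)) + 1
    if n < 1:
        raise ValueError("box smaller than the sliding window")
    return np.arange(n) * step


def d_spacing(
    assignment: LayerAssignment,
    frame: Frame,
    window: float = 5.0,
    step: float = 1.0,
    periodic: bool = True,
) -> DSpacingProfile:
    """d-spacing between adjacent layers, global and as a local xy map.

    For every adjacent layer pair, a ``window`` x ``window`` Angstrom window
    slides across the xy-plane in ``step`` Angstrom increments (wrapping around
    the periodic box by default); the local d-spacing of a window is the
    difference between the mean z of the upper and lower layer's atoms inside
    it.  Windows where either layer contributes no atom are marked NaN and
    excluded from the statistics.
    """
    if assignment.n_layers < 2:
        raise ValueError("d-spacing requires at least two layers")
    coords = frame.coords[assignment.metal_rows]
    box = np.asarray(frame.box, dtype=float)
    xs = _window_starts(box[0], window, step, periodic)
    ys = _window_starts(box[1], window, step, periodic)

    def in_window(pts: np.ndarray, x0: float, y0: float) -> np.ndarray:
        if periodic:
            dx = np.mod(pts[:, 0] - x0, box[0])
            dy = np.mod(pts[:, 1] - y0, box[1])
        else:
            dx = pts[:, 0] - x0
            dy = pts[:, 1] - y0
        return (dx >= 0) & (dx <= window) & (dy >= 0) & (dy <= window)

    layer_pts = [coords[assignment.labels == k] for k in range(assignment.n_layers)]
    local_maps: list[np.ndarray] = []
    pair_mean, pair_std = [], []
    for k in range(assignment.n_layers - 1):
        lo, hi = layer_pts[k], layer_pts[k + 1]
        grid = np.full((len(xs), len(ys)), np.nan)
        for i, x0 in enumerate(xs):
            for j, y0 in enumerate(ys):
                ml = in_window(lo, x0, y0)
                mh = in_window(hi, x0, y0)
                if ml.any() and mh.any():
                    grid[i, j] = hi[mh, 2].mean() - lo[ml, 2].mean()
        valid = grid[~np.isnan(grid)]
        if valid.size == 0:
            raise ValueError(f"no valid windows for layer pair ({k}, {k + 1})")
        local_maps.append(grid)
        pair_mean.append(valid.mean())
        pair_std.append(valid.std())
    pooled = np.concatenate([g[~np.isnan(g)].ravel() for g in local_maps])
    return DSpacingProfile(
        np.array(pair_mean),
        np.array(pair_std),
        local_maps,
        window,
        step,
        float(pooled.mean()),
        float(pooled.std()),
    )


def undulation(assignment: LayerAssignment, trajectory: Trajectory | Frame) -> UndulationStats:
    """Pooled z-spread of metal layers after centring each layer at the origin.

    For every frame and layer, metal z-coordinates are shifted by the layer's
    mean; the standard deviation of the accumulated residuals measures the
    undulation amplitude (a sinusoid of amplitude A gives A/sqrt(2)).
    The layer assignment from a reference frame is reused across frames
    (atom ordering is constant within a trajectory).
    """
    frames = [trajectory] if isinstance(trajectory, Frame) else list(trajectory)
    per_layer: list[list[np.ndarray]] = [[] for _ in range(assignment.n_layers)]
    for fr in frames:
        z = fr.coords[assignment.metal_rows, 2]
        for k in range(assignment.n_layers):
            zk = z[assignment.labels == k]
            if zk.size:
                per_layer[k].append(zk - zk.mean())
    stds = np.array([np.concatenate(ch).std() if ch else np.nan for ch in per_layer])
    pooled = np.concatenate([np.concatenate(ch) for ch in per_layer if ch])
    return UndulationStats(stds, float(pooled.std()))
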