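"""Iso-distance gradient layering between two boundary masks.

Within a lobule ROI, each voxel is placed on a continuous [0, 1] ratio
``d_origin / (d_origin + d_destination)`` of geodesic distances to the two
boundaries, then binned into K equal-width steps (default K = 7).  Distances
are geodesic within ``roi | sources`` over the 26-connected lattice with
Euclidean inter-centre edge weights, which prevents shortcuts across fissure
gaps in folded geometry; an ambient Euclidean mode is available.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric

from .errors import ConnectivityError

__all__ = [
    "GradientStepMap",
    "IntrinsicCoords",
    "geodesic_distance",
    "euclidean_distance",
    "compute_steps",
    "brute_force_steps",
    "intrinsic_coordinates",
]

#: ties within this distance of a bin edge resolve to the lower step
EDGE_TOL = 1e-9


@dataclass
class GradientStepMap:
    steps: np.ndarray                 # int16; 0 outside ROI / unreachable
    ratio: np.ndarray                 # float; NaN where steps == 0
    n_steps: int
    direction: str = ""
    lobule: int = 0
    hemisphere: str = ""
    n_unreachable: int = 0

    def step_mask(self, s: int) -> np.ndarray:
        return self.steps == s

    def counts(self) -> np.ndarray:
        """Voxel count per step 1..K."""
        return np.bincount(self.steps.ravel(), minlength=self.n_steps + 1)[1:]


@dataclass
class IntrinsicCoords:
    """Continuous intrinsic coordinates of a lobule ROI plus the step maps
    they were derived from.  Ratios are NaN outside their reachable ROI."""

    depth: np.ndarray
    mediolateral: np.ndarray
    posterior_anterior: np.ndarray
    step_maps: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return ~(np.isnan(self.depth) | np.isnan(self.mediolateral) | np.isnan(self.posterior_anterior))


def geodesic_distance(roi: np.ndarray, sources: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Shortest 26-connected path length (mm) from every ROI voxel to the
    source set, propagating inside ``roi | sources`` only.

    Unreachable voxels (and voxels outside the domain) carry ``inf``.
    """
    roi = roi.astype(bool)
    src = sources.astype(bool)
    if not src.any():
        raise ValueError("sources mask is empty")
    domain = roi | src
    costs = np.where(domain, 1.0, np.inf)
    mcp = MCP_Geometric(costs, sampling=tuple(float(v) for v in voxel_size_mm))
    dist, _ = mcp.find_costs(np.argwhere(src))
    dist = np.asarray(dist, dtype=np.float64)
    dist[~domain] = np.inf
    return dist


def euclidean_distance(sources: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Ambient Euclidean distance (mm) to the source set, ignoring the ROI."""
    src = sources.astype(bool)
    if not src.any():
        raise ValueError("sources mask is empty")
    return ndimage.distance_transform_edt(~src, sampling=voxel_size_mm)


def dijkstra_distance(roi: np.ndarray, sources: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Reference distance engine: explicit priority-queue relaxation over the
    26-connected voxel graph.  Independent of :func:`geodesic_distance`;
    intended for tests and small instances only."""
    roi = roi.astype(bool)
    src = sources.astype(bool)
    if not src.any():
        raise ValueError("sources mask is empty")
    domain = roi | src
    shape = domain.shape
    vs = tuple(float(v) for v in voxel_size_mm)
    offsets = [
        (d, math.sqrt((d[0] * vs[0]) ** 2 + (d[1] * vs[1]) ** 2 + (d[2] * vs[2]) ** 2))
        for d in itertools.product((-1, 0, 1), repeat=3)
        if d != (0, 0, 0)
    ]
    dist = np.full(shape, np.inf)
    heap = []
    for v in map(tuple, np.argwhere(src)):
        dist[v] = 0.0
        heap.append((0.0, v))
    heapq.heapify(heap)
    while heap:
        d, (i, j, k) = heapq.heappop(heap)
        if d > dist[i, j, k]:
            continue
        for (di, dj, dk), w in offsets:
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2] and domain[ni, nj, nk]:
                nd = d + w
                if nd < dist[ni, nj, nk]:
                    dist[ni, nj, nk] = nd
                    heapq.heappush(heap, (nd, (ni, nj, nk)))
    dist[~domain] = np.inf
    return dist


def _bin_steps(ratio: np.ndarray, reachable: np.ndarray, n_steps: int, tol: float) -> np.ndarray:
    steps = np.zeros(ratio.shape, dtype=np.int16)
    r = ratio[reachable]
    s = np.ceil(n_steps * (r - tol)).astype(np.int16)
    steps[reachable] = np.clip(s, 1, n_steps)
    return steps


def _steps_from_distances(roi, d_origin, d_dest, n_steps, tol, max_unreachable_frac,
                          raise_on_disconnect=True, **meta):
    roi = roi.astype(bool)
    reachable = roi & np.isfinite(d_origin) & np.isfinite(d_dest)
    n_unreachable = int(np.count_nonzero(roi) - np.count_nonzero(reachable))
    if roi.any() and raise_on_disconnect and n_unreachable > max_unreachable_frac * np.count_nonzero(roi):
        raise ConnectivityError(
            f"{n_unreachable}/{int(np.count_nonzero(roi))} ROI voxels unreachable from a boundary"
        )
    ratio = np.full(roi.shape, np.nan)
    with np.errstate(invalid="ignore"):
        total = d_origin + d_dest
        ok = reachable & (total > 0)
        ratio[ok] = d_origin[ok] / total[ok]
    steps = _bin_steps(ratio, ok, n_steps, tol)
    return GradientStepMap(steps=steps, ratio=ratio, n_steps=n_steps,
                           n_unreachable=n_unreachable, **meta)


def compute_steps(
    roi: np.ndarray,
    origin_boundary: np.ndarray,
    destination_boundary: np.ndarray,
    n_steps: int = 7,
    voxel_size_mm=(1.0, 1.0, 1.0),
    metric: str = "geodesic",
    tol: float = EDGE_TOL,
    max_unreachable_frac: float = 0.2,
    **meta,
) -> GradientStepMap:
    """Assign each reachable ROI voxel an iso-distance step in 1..K.

    Step ``s`` covers ratios in ``((s-1)/K, s/K]`` with ratio 0 mapped to
    step 1; ties within ``tol`` of an edge resolve to the lower step.
    Raises :class:`ConnectivityError` when more than ``max_unreachable_frac``
    of the ROI cannot reach both boundaries.
    """
    roi = roi.astype(bool)
    org = origin_boundary.astype(bool)
    dst = destination_boundary.astype(bool)
    if not org.any() or not dst.any():
        raise ValueError("both boundary masks must be non-empty")
    if (roi & (org | dst)).any():
        raise ValueError("roi must be disjoint from both boundary masks")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if metric == "geodesic":
        d_o = geodesic_distance(roi, org, voxel_size_mm)
        d_d = geodesic_distance(roi, dst, voxel_size_mm)
    elif metric == "euclidean":
        d_o = euclidean_distance(org, voxel_size_mm)
        d_d = euclidean_distance(dst, voxel_size_mm)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return _steps_from_distances(roi, d_o, d_d, n_steps, tol, max_unreachable_frac, **meta)


def brute_force_steps(
    roi: np.ndarray,
    origin_boundary: np.ndarray,
    destination_boundary: np.ndarray,
    n_steps: int = 7,
    voxel_size_mm=(1.0, 1.0, 1.0),
    tol: float = EDGE_TOL,
    max_unreachable_frac: float = 0.2,
    **meta,
) -> GradientStepMap:
    """Same contract as :func:`compute_steps`, with distances obtained by the
    exhaustive priority-queue search.  Test oracle; O(V log V) per boundary
    in pure Python, so keep instances small."""
    roi = roi.astype(bool)
    org = origin_boundary.astype(bool)
    dst = destination_boundary.astype(bool)
    if not org.any() or not dst.any():
        raise ValueError("both boundary masks must be non-empty")
    if (roi & (org | dst)).any():
        raise ValueError("roi must be disjoint from both boundary masks")
    d_o = dijkstra_distance(roi, org, voxel_size_mm)
    d_d = dijkstra_distance(roi, dst, voxel_size_mm)
    return _steps_from_distances(roi, d_o, d_d, n_steps, tol, max_unreachable_frac, **meta)


def intrinsic_coordinates(boundaries, roi: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0),
                          n_steps: int = 7) -> IntrinsicCoords:
    """The three continuous ratio fields of a lobule ROI.

    Per direction the ROI passed to the layering is the lobule minus the
    origin and destination masks (the spec of :func:`compute_steps` requires
    disjointness); ratios are NaN there and outside the lobule.
    """
    roi = roi.astype(bool)
    fields = {}
    step_maps = {}
    for direction, (org, dst) in boundaries.pairs().items():
        sub_roi = roi & ~(org | dst)
        sm = compute_steps(sub_roi, org, dst, n_steps=n_steps, voxel_size_mm=voxel_size_mm,
                           max_unreachable_frac=1.0, direction=direction,
                           lobule=boundaries.lobule, hemisphere=boundaries.hemisphere)
        fields[direction] = sm.ratio
        step_maps[direction] = sm
    return IntrinsicCoords(
        depth=fields["fissure_depth"],
        mediolateral=fields["mediolateral"],
        posterior_anterior=fields["posterior_anterior"],
        step_maps=step_maps,
    )
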