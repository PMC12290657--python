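"""Synthetic folded-sheet anatomy and block-design BOLD generator.

The phantom consists of two mirror-image hemispheres: a sinusoidally folded
grey-matter band wrapped around a white-matter core whose probability decays
from 1.0 at the core to 0 at the outer surface.  Consecutive angular sectors
of the band are assigned lobule labels so that every target lobule has an
anterior and a posterior neighbour.  BOLD runs are baseline 100 plus planted
condition-specific Gaussian blobs placed by intrinsic coordinates, modulated
by an HRF-convolved boxcar, plus (optionally AR(1)) Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .errors import DesignError, ReferenceError_, SizingError

__all__ = [
    "Block",
    "TaskDesign",
    "EffectSpec",
    "NoiseSpec",
    "PhantomAnatomy",
    "BoldRun",
    "generate_anatomy",
    "build_task_design",
    "generate_bold",
]

#: label offset added to right-hemisphere lobules
HEMISPHERE_OFFSET = 100

CONDITIONS = ("MCFT", "SUFF")


@dataclass(frozen=True)
class Block:
    onset_s: float
    duration_s: float
    condition: str


@dataclass
class TaskDesign:
    """Ordered non-overlapping ON blocks for a single run."""

    blocks: list[Block]
    tr_s: float
    n_volumes: int
    run_id: int = 0

    def __post_init__(self):
        if self.tr_s <= 0 or self.n_volumes <= 0:
            raise DesignError("tr_s and n_volumes must be positive")
        prev_end = -np.inf
        for b in sorted(self.blocks, key=lambda b: b.onset_s):
            if b.onset_s < prev_end:
                raise DesignError("blocks overlap")
            prev_end = b.onset_s + b.duration_s
        self.blocks = sorted(self.blocks, key=lambda b: b.onset_s)
        run_len = self.n_volumes * self.tr_s
        for b in self.blocks:
            if b.onset_s + b.duration_s > run_len + 1e-9:
                raise DesignError("block extends past end of run")

    @property
    def run_length_s(self) -> float:
        return self.n_volumes * self.tr_s

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for b in self.blocks:
            if b.condition not in seen:
                seen.append(b.condition)
        return seen


@dataclass(frozen=True)
class EffectSpec:
    """A planted activation: condition, target lobule, intrinsic-coordinate
    centre (depth, mediolateral, posterior-anterior ratios in [0,1]),
    spatial Gaussian SD in mm and amplitude in percent signal change."""

    condition: str
    lobule: int
    centre_intrinsic: tuple[float, float, float]
    spatial_sd_mm: float = 3.0
    amplitude_pct: float = 1.5

    def __post_init__(self):
        if not all(0.0 <= c <= 1.0 for c in self.centre_intrinsic):
            raise ValueError("centre_intrinsic ratios must lie in [0, 1]")
        if self.amplitude_pct < 0:
            raise ValueError("amplitude_pct must be >= 0")
        if self.spatial_sd_mm <= 0:
            raise ValueError("spatial_sd_mm must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    sigma_pct: float = 1.0
    ar1_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_pct <= 0:
            raise ValueError("sigma_pct must be > 0")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must be in [0, 1)")


@dataclass
class PhantomAnatomy:
    lobule_labels: np.ndarray          # int16, left 1..L, right 101..100+L
    wm_probability: np.ndarray         # float32 in [0, 1]
    cerebellum_mask: np.ndarray        # bool
    gm_mask: np.ndarray                # bool
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lobules: int = 3
    hemisphere_offset: int = HEMISPHERE_OFFSET

    @property
    def shape(self):
        return self.lobule_labels.shape

    @property
    def midline_x(self) -> float:
        """The mirror plane, in voxel coordinates along axis 0."""
        return (self.shape[0] - 1) / 2.0

    def label_code(self, lobule: int, hemisphere: str) -> int:
        if not (1 <= lobule <= self.n_lobules):
            raise ReferenceError_(f"lobule {lobule} not in 1..{self.n_lobules}")
        if hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        return lobule + (self.hemisphere_offset if hemisphere == "right" else 0)

    def lobule_mask(self, lobule: int, hemisphere: str) -> np.ndarray:
        return self.lobule_labels == self.label_code(lobule, hemisphere)


@dataclass
class BoldRun:
    data: np.ndarray                   # float32, (x, y, z, t)
    design: TaskDesign
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def tr_s(self) -> float:
        return self.design.tr_s

    @property
    def run_id(self) -> int:
        return self.design.run_id


# ---------------------------------------------------------------------------
# anatomy

def generate_anatomy(
    grid_shape=(48, 48, 48),
    n_lobules: int = 3,
    fold_count: int = 4,
    seed: int = 0,
    band_thickness_vox: float = 4.0,
    fold_amplitude_vox: float | None = None,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> PhantomAnatomy:
    """Build the two-hemisphere folded-sheet phantom.

    Each hemisphere is half of a quasi-spherical blob centred on the
    mid-sagittal plane: a white-matter core of folded radius
    ``R(theta) = R0 + A sin(fold_count * theta + phase)`` with a grey-matter
    band of constant thickness on top.  ``theta`` is the polar angle in the
    (posterior-anterior, inferior-superior) plane, so folds run along the fan
    of lobule sectors and both hemispheres meet across the midline over the
    full band cross-section.  The right hemisphere is the exact mirror image
    of the left.

    Deterministic for fixed arguments and seed (the seed sets fold phase).
    """
    nx, ny, nz = grid_shape
    if min(grid_shape) < 24:
        raise SizingError("grid_shape must be at least 24 voxels per axis")
    if n_lobules < 3:
        raise ValueError("n_lobules must be >= 3")
    if fold_count < 1:
        raise ValueError("fold_count must be >= 1")
    t = float(band_thickness_vox)
    if t < 3.0:
        raise SizingError("band thickness must be at least 3 voxels")

    r_reach = 0.75 * min((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    if fold_amplitude_vox is None:
        amp = float(np.clip(0.2 * (r_reach - t), 1.0, 2.0))
    else:
        amp = float(fold_amplitude_vox)
    r_core0 = r_reach - amp - t
    wm_margin = 0.5  # keeps the p > 0.99 core strictly below the GM band
    if r_core0 - amp - wm_margin < 0.25:
        raise SizingError("grid too small for the requested band thickness/folds")

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * math.pi)

    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    cz = (nz - 1) / 2.0

    x = np.arange(nx, dtype=np.float64)[:, None, None]
    y = np.arange(ny, dtype=np.float64)[None, :, None]
    z = np.arange(nz, dtype=np.float64)[None, None, :]
    dx, dy, dz = x - cx, y - cy, z - cz
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    theta = np.arctan2(np.broadcast_to(dz, r.shape), np.broadcast_to(dy, r.shape))
    left_half = np.broadcast_to(x < cx, r.shape)

    r_core = r_core0 + amp * np.sin(fold_count * theta + phase)
    blob = r <= r_core + t
    cereb_l = blob & left_half
    gm_l = (r > r_core) & cereb_l
    # WM probability: 1 deep in the core, linear decay to 0 at the outer
    # surface; the margin keeps p at the GM inner edge below 0.99
    wm_l = np.clip((r_core + t - r) / (t + wm_margin), 0.0, 1.0)
    wm_l = np.where(cereb_l, wm_l, 0.0)

    # angular fan of lobule sectors spanning [-pi/2, pi/2), label 1 = most
    # posterior-inferior sector, increasing towards anterior-superior
    width = math.pi / n_lobules
    sector = np.floor((theta + math.pi / 2.0) / width).astype(np.int32)
    in_fan = (sector >= 0) & (sector < n_lobules)
    labels_l = np.where(gm_l & in_fan, sector + 1, 0).astype(np.int16)

    # exact mirror about the plane x = (nx - 1) / 2
    labels_r = np.flip(labels_l, axis=0)
    labels = labels_l + np.where(labels_r > 0, labels_r + HEMISPHERE_OFFSET, 0).astype(np.int16)
    gm = gm_l | np.flip(gm_l, axis=0)
    cereb = cereb_l | np.flip(cereb_l, axis=0)
    wm = np.maximum(wm_l, np.flip(wm_l, axis=0)).astype(np.float32)

    if not (wm > 0.99).any():
        raise SizingError("WM core came out empty; enlarge grid or shrink band")

    return PhantomAnatomy(
        lobule_labels=labels,
        wm_probability=wm,
        cerebellum_mask=cereb,
        gm_mask=gm,
        voxel_size_mm=tuple(float(v) for v in voxel_size_mm),
        n_lobules=n_lobules,
    )


# ---------------------------------------------------------------------------
# task design

def build_task_design(
    run_length_s: float,
    tr_s: float,
    on_s: float,
    off_s: float,
    order=CONDITIONS,
    run_id: int = 0,
) -> TaskDesign:
    """Tile ``[0, run_length_s]`` with ON(on_s) + OFF(off_s) cycles.

    Conditions are drawn cyclically from ``order`` so both tasks alternate
    within the run; pass a single-element order for one-task runs.
    """
    if min(run_length_s, tr_s, on_s, off_s) <= 0:
        raise DesignError("all durations must be positive")
    if run_length_s < on_s + off_s:
        raise DesignError("run shorter than one ON+OFF cycle")
    n_volumes = int(math.floor(run_length_s / tr_s))
    blocks = []
    k = 0
    onset = 0.0
    while onset + on_s <= run_length_s + 1e-9:
        blocks.append(Block(onset, on_s, order[k % len(order)]))
        k += 1
        onset = k * (on_s + off_s)
    return TaskDesign(blocks=blocks, tr_s=tr_s, n_volumes=n_volumes, run_id=run_id)


# ---------------------------------------------------------------------------
# BOLD generation

BASELINE = 100.0


def _blob(anatomy: PhantomAnatomy, centre_vox, sd_mm: float) -> np.ndarray:
    vs = np.asarray(anatomy.voxel_size_mm)
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in anatomy.shape], indexing="ij")
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, centre_vox, vs))
    return np.exp(-d2 / (2.0 * sd_mm ** 2))


def _effect_centre_voxel(coords, centre_intrinsic) -> tuple[int, int, int]:
    """Voxel of the ROI whose intrinsic coordinates are nearest the target."""
    valid = coords.valid
    cost = np.zeros(np.count_nonzero(valid), dtype=np.float64)
    for field_, target in zip((coords.depth, coords.mediolateral, coords.posterior_anterior), centre_intrinsic):
        cost += (field_[valid] - target) ** 2
    idx = np.argmin(cost)
    vox = tuple(int(a[idx]) for a in np.nonzero(valid))
    return vox


def generate_bold(
    anatomy: PhantomAnatomy,
    designs: list[TaskDesign],
    effects: list[EffectSpec],
    noise: NoiseSpec,
    coords: dict | None = None,
    simulate_mask: np.ndarray | None = None,
    mirror_effects: bool = True,
) -> list[BoldRun]:
    """Simulate one BOLD run per design.

    ``coords`` maps ``(lobule, hemisphere)`` to an ``IntrinsicCoords`` (from
    :func:`cbgrad.gradients.intrinsic_coordinates`); when omitted it is
    computed here via the segmentation and gradients modules.  Effects are
    planted in both hemispheres when ``mirror_effects`` (the tasks are
    bimanual).  Time series outside ``simulate_mask`` (default: the
    cerebellum mask) stay at baseline; pass ``np.ones(shape, bool)`` to
    simulate the whole grid.
    """
    if not designs:
        raise DesignError("designs must be non-empty")
    hemis = ("left", "right") if mirror_effects else ("left",)
    for e in effects:
        if e.lobule < 1 or e.lobule > anatomy.n_lobules:
            raise ReferenceError_(f"effect lobule {e.lobule} absent from anatomy")
        if e.condition not in CONDITIONS:
            raise ReferenceError_(f"unknown condition {e.condition!r}")

    if coords is None and effects:
        coords = compute_intrinsic_coords(anatomy, sorted({e.lobule for e in effects}))

    if simulate_mask is None:
        simulate_mask = anatomy.cerebellum_mask
    mask = simulate_mask.astype(bool)
    n_masked = int(np.count_nonzero(mask))

    # spatial weight per effect x hemisphere, restricted to the mask
    blobs = []  # (condition, weights over masked voxels)
    for e in effects:
        for hemi in hemis:
            centre = _effect_centre_voxel(coords[(e.lobule, hemi)], e.centre_intrinsic)
            w = _blob(anatomy, centre, e.spatial_sd_mm)[mask]
            blobs.append((e.condition, e.amplitude_pct / 100.0 * w))

    from .glm import condition_regressor  # deferred to avoid an import cycle

    rng = np.random.default_rng(noise.seed)
    sigma = noise.sigma_pct / 100.0 * BASELINE
    runs = []
    for design in designs:
        T = design.n_volumes
        series = np.full((n_masked, T), BASELINE, dtype=np.float64)
        for cond, w in blobs:
            reg = condition_regressor(design, cond)  # unit peak
            series += BASELINE * np.outer(w, reg)
        eps = rng.standard_normal((n_masked, T))
        if noise.ar1_rho > 0.0:
            # stationary AR(1) with marginal SD sigma
            eps = sp_signal.lfilter([1.0], [1.0, -noise.ar1_rho], eps, axis=1)
            eps *= math.sqrt(1.0 - noise.ar1_rho ** 2)
        series += sigma * eps
        data = np.full(anatomy.shape + (T,), BASELINE, dtype=np.float32)
        data[mask] = series.astype(np.float32)
        runs.append(BoldRun(data=data, design=design, voxel_size_mm=anatomy.voxel_size_mm))
    return runs


def compute_intrinsic_coords(anatomy: PhantomAnatomy, lobules, n_steps: int = 7) -> dict:
    """Boundary sets + intrinsic ratio fields for the given lobules, both
    hemispheres.  Returns ``{(lobule, hemisphere): IntrinsicCoords}``."""
    from .gradients import intrinsic_coordinates
    from .segmentation import build_boundary_set

    out = {}
    for lob in lobules:
        for hemi in ("left", "right"):
            bs = build_boundary_set(anatomy, lob, hemi)
            roi = anatomy.lobule_mask(lob, hemi)
            out[(lob, hemi)] = intrinsic_coordinates(bs, roi, voxel_size_mm=anatomy.voxel_size_mm, n_steps=n_steps)
    return out
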