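"""First-level block-design GLM, contrast z-maps and run combination.

Per run: ordinary least squares of each voxel time series on HRF-convolved
condition boxcars (plus Legendre drift terms and an intercept); t statistics
for named contrasts are mapped to standard-normal deviates through a
tail-stable probability round-trip, and runs are combined with
inverse-variance (fixed-effects) weighting.  Activation masks use a strict
``z > threshold`` cut (default 3.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .errors import DesignError, ShapeError

__all__ = [
    "DesignMatrix",
    "GlmFit",
    "ContrastMap",
    "hrf_double_gamma",
    "condition_regressor",
    "build_design_matrix",
    "fit_glm",
    "contrast_zmap",
    "fixed_effects_combine",
    "threshold_map",
    "CONTRAST_NAMES",
]

CONTRAST_NAMES = ("MCFT>rest", "SUFF>rest", "MCFT>SUFF")

#: z assigned to degenerate noiseless voxels; ~largest finite normal deviate
Z_MAX = 38.0


@dataclass
class DesignMatrix:
    matrix: np.ndarray                # (n_volumes, p)
    column_names: list[str]
    tr_s: float

    def __post_init__(self):
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise DesignError("design matrix is rank deficient")
        if "intercept" not in self.column_names:
            raise DesignError("intercept column missing")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def contrast_vector(self, name: str) -> np.ndarray:
        """Contrast row vector for 'A>rest' or 'A>B' against column names."""
        c = np.zeros(self.matrix.shape[1])
        lhs, rhs = name.split(">")
        c[self.column_names.index(lhs)] = 1.0
        if rhs not in ("rest", "baseline"):
            c[self.column_names.index(rhs)] -= 1.0
        return c


@dataclass
class GlmFit:
    beta: np.ndarray                  # (p, n_voxels)
    sigma2: np.ndarray                # (n_voxels,)
    dof: int
    xtx_inv: np.ndarray               # (p, p)
    mask: np.ndarray                  # bool volume locating the voxel axis
    design: DesignMatrix


@dataclass
class ContrastMap:
    name: str
    cope: np.ndarray                  # 3D
    varcope: np.ndarray               # 3D
    z: np.ndarray                     # 3D
    dof: float
    mask: np.ndarray                  # bool 3D


def hrf_double_gamma(t_s, peak_s: float = 6.0, undershoot_s: float = 16.0, ratio: float = 1.0 / 6.0):
    """Canonical difference-of-gamma-densities haemodynamic response.

    Gamma shapes are chosen (unit scale) so the positive lobe peaks at
    ``peak_s`` and the undershoot at ``undershoot_s``; the undershoot is
    scaled by ``ratio``.  Zero at t = 0 and for t < 0.
    """
    t = np.asarray(t_s, dtype=float)
    h = stats.gamma.pdf(t, a=peak_s + 1.0) - ratio * stats.gamma.pdf(t, a=undershoot_s + 1.0)
    return np.where(t > 0, h, 0.0)


def _sampled_regressor(design, condition: str, hrf_params=None, dt: float = 0.1) -> np.ndarray:
    """Boxcar of one condition convolved with the HRF, sampled at volume
    acquisition times, normalised to unit peak."""
    hrf_params = hrf_params or {}
    run_len = design.n_volumes * design.tr_s
    n_fine = int(np.ceil((run_len + 33.0) / dt))
    tt = np.arange(n_fine) * dt
    box = np.zeros(n_fine)
    for b in design.blocks:
        if b.condition == condition:
            box[(tt >= b.onset_s) & (tt < b.onset_s + b.duration_s)] = 1.0
    kernel = hrf_double_gamma(np.arange(0.0, 33.0, dt), **hrf_params)
    conv = np.convolve(box, kernel)[:n_fine] * dt
    vol_idx = np.round(np.arange(design.n_volumes) * design.tr_s / dt).astype(int)
    reg = conv[vol_idx]
    peak = np.abs(reg).max()
    return reg / peak if peak > 0 else reg


def condition_regressor(design, condition: str, hrf_params=None) -> np.ndarray:
    """Public unit-peak regressor used by both the GLM and the phantom."""
    return _sampled_regressor(design, condition, hrf_params)


def build_design_matrix(design, hrf_params=None, drift_order: int = 0) -> DesignMatrix:
    """One HRF-convolved unit-peak column per condition, Legendre drift
    columns 1..``drift_order``, intercept last."""
    cols = []
    names = []
    for cond in design.conditions():
        cols.append(_sampled_regressor(design, cond, hrf_params))
        names.append(cond)
    if drift_order > 0:
        x = np.linspace(-1.0, 1.0, design.n_volumes)
        for d in range(1, drift_order + 1):
            cols.append(np.polynomial.legendre.Legendre.basis(d)(x))
            names.append(f"drift{d}")
    cols.append(np.ones(design.n_volumes))
    names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), column_names=names, tr_s=design.tr_s)


def fit_glm(bold, X: DesignMatrix, mask: np.ndarray | None = None) -> GlmFit:
    """Voxelwise OLS.  ``bold`` is a 4D array or a :class:`~cbgrad.phantom.BoldRun`."""
    data = np.asarray(bold) if isinstance(bold, np.ndarray) else np.asarray(bold.data)
    if data.ndim != 4:
        raise ShapeError("bold data must be 4D (x, y, z, t)")
    if data.shape[-1] != X.n_volumes:
        raise ShapeError(f"bold has {data.shape[-1]} volumes, design has {X.n_volumes}")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    mask = mask.astype(bool)
    Y = data[mask].T.astype(np.float64)          # (T, V)
    M = X.matrix
    p = M.shape[1]
    dof = X.n_volumes - p
    if dof <= 0:
        raise DesignError("non-positive residual degrees of freedom")
    xtx_inv = np.linalg.inv(M.T @ M)
    beta = xtx_inv @ (M.T @ Y)
    resid = Y - M @ beta
    sigma2 = np.einsum("tv,tv->v", resid, resid) / dof
    return GlmFit(beta=beta, sigma2=sigma2, dof=dof, xtx_inv=xtx_inv, mask=mask, design=X)


def _t_to_z(t: np.ndarray, dof: float) -> np.ndarray:
    """Map t deviates to standard-normal deviates via tail log-probabilities,
    finite out to |z| ~ 38."""
    t = np.asarray(t, dtype=np.float64)
    logp = stats.t.logsf(np.abs(t), dof)
    with np.errstate(invalid="ignore"):
        z = -special.ndtri_exp(logp)             # positive tail deviate
    # logsf underflows to -inf for |z| beyond ~38; cap there
    z = np.where(np.isfinite(z), np.minimum(z, Z_MAX), Z_MAX)
    return np.sign(t) * z


def contrast_zmap(fit: GlmFit, c: np.ndarray, name: str) -> ContrastMap:
    """z-statistic map for contrast vector ``c`` (or a named contrast)."""
    if isinstance(c, str):
        name, c = c, fit.design.contrast_vector(c)
    c = np.asarray(c, dtype=np.float64)
    cope_v = c @ fit.beta
    cvc = float(c @ fit.xtx_inv @ c)
    varcope_v = fit.sigma2 * cvc
    z_v = np.zeros_like(cope_v)
    good = varcope_v > 0
    z_v[good] = _t_to_z(cope_v[good] / np.sqrt(varcope_v[good]), fit.dof)
    n_degenerate = int(np.count_nonzero(~good & (cope_v != 0)))
    if n_degenerate:
        warnings.warn(f"{n_degenerate} voxels with zero residual variance; z set to +/-{Z_MAX}")
        z_v[~good] = np.sign(cope_v[~good]) * Z_MAX

    shape = fit.mask.shape
    cope = np.zeros(shape)
    varcope = np.zeros(shape)
    z = np.zeros(shape)
    cope[fit.mask] = cope_v
    varcope[fit.mask] = varcope_v
    z[fit.mask] = z_v
    return ContrastMap(name=name, cope=cope, varcope=varcope, z=z, dof=fit.dof, mask=fit.mask.copy())


def fixed_effects_combine(maps: list[ContrastMap]) -> ContrastMap:
    """Inverse-variance-weighted combination of per-run contrast maps; the
    combined statistic is treated as a normal deviate."""
    if not maps:
        raise ValueError("no maps to combine")
    first = maps[0]
    for m in maps[1:]:
        if m.cope.shape != first.cope.shape:
            raise ShapeError("contrast maps have mismatched grids")
        if m.name != first.name:
            raise ValueError("contrast maps have mismatched names")
    if len(maps) == 1:
        return first
    mask = np.logical_and.reduce([m.mask for m in maps])
    good = mask & np.logical_and.reduce([m.varcope > 0 for m in maps])
    wsum = np.zeros(first.cope.shape)
    wcope = np.zeros(first.cope.shape)
    for m in maps:
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(good, 1.0 / m.varcope, 0.0)
        wsum += w
        wcope += w * m.cope
    cope = np.where(good, wcope / np.where(wsum > 0, wsum, 1.0), 0.0)
    varcope = np.where(good, 1.0 / np.where(wsum > 0, wsum, 1.0), 0.0)
    z = np.where(good, cope / np.sqrt(np.where(varcope > 0, varcope, 1.0)), 0.0)
    return ContrastMap(name=first.name, cope=cope, varcope=varcope, z=z,
                       dof=float(sum(m.dof for m in maps)), mask=mask)


def threshold_map(cmap: ContrastMap, z_thresh: float = 3.1) -> np.ndarray:
    """Strict ``z > z_thresh`` activation mask within the map's mask."""
    return (cmap.z > z_thresh) & cmap.mask
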