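"""Quadrant-ROI centre-of-gravity analysis of activation maps.

Four quadrants (hemisphere x superior/inferior lobule sets) are built from
the label map; per condition the z-weighted centroid of supra-zero voxels is
computed in mm, and per-axis paired t-tests quantify the condition shift.
Sign convention: the first axis runs left -> right, so a positive delta-x is
a rightward shift; medial/lateral interpretation flips between hemispheres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .stepstats import PairedTestResult, paired_t

__all__ = ["CogResult", "CogShift", "QUADRANTS", "quadrant_rois", "centre_of_gravity", "cog_shift_analysis"]

QUADRANTS = ("RU", "RL", "LU", "LL")


class EmptyClusterError(DegenerateInputError):
    """No voxel with z > 0 inside the quadrant mask."""


@dataclass
class CogResult:
    quadrant: str
    condition: str
    cog_mm: tuple[float, float, float]
    total_weight: float


@dataclass
class CogShift:
    quadrant: str
    delta_mm: tuple[float, float, float]       # mean over subjects, A - B
    sd_mm: tuple[float, float, float]
    tests: tuple[PairedTestResult, PairedTestResult, PairedTestResult]
    n_subjects: int


def quadrant_rois(labels: np.ndarray, superior_lobules, inferior_lobules,
                  hemisphere_offset: int = 100) -> dict[str, np.ndarray]:
    """Four disjoint masks keyed RU/RL/LU/LL (right/left x upper/lower).

    ``superior_lobules``/``inferior_lobules`` are left-hemisphere label
    values; right-hemisphere codes are obtained by adding the offset.
    """
    sup = set(int(v) for v in superior_lobules)
    inf_ = set(int(v) for v in inferior_lobules)
    if not sup or not inf_:
        raise ValueError("superior and inferior lobule sets must be non-empty")
    if sup & inf_:
        raise ValueError("superior and inferior lobule sets overlap")
    out = {
        "LU": np.isin(labels, sorted(sup)),
        "LL": np.isin(labels, sorted(inf_)),
        "RU": np.isin(labels, sorted(v + hemisphere_offset for v in sup)),
        "RL": np.isin(labels, sorted(v + hemisphere_offset for v in inf_)),
    }
    return out


def centre_of_gravity(zmap, mask: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0),
                      origin_mm=(0.0, 0.0, 0.0), weighted: bool = True,
                      quadrant: str = "", condition: str = "") -> CogResult:
    """z-weighted centroid (mm) of voxels with z > 0 inside ``mask``.

    With ``weighted=False`` every supra-zero voxel counts equally.
    Raises :class:`EmptyClusterError` when no voxel has z > 0.
    """
    m = mask.astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    zdata = zmap.z if hasattr(zmap, "z") else np.asarray(zmap)
    sel = m & (zdata > 0)
    if not sel.any():
        raise EmptyClusterError("no voxel with z > 0 in mask")
    w = zdata[sel] if weighted else np.ones(np.count_nonzero(sel))
    idx = np.nonzero(sel)
    total = float(w.sum())
    cog = tuple(
        float(origin_mm[a] + voxel_size_mm[a] * np.sum(w * idx[a]) / total)
        for a in range(3)
    )
    return CogResult(quadrant=quadrant, condition=condition, cog_mm=cog, total_weight=total)


def cog_shift_analysis(per_subject_cogs: pd.DataFrame, condition_a: str = "MCFT",
                       condition_b: str = "SUFF") -> dict[str, CogShift]:
    """Per-quadrant shift ``cog(A) - cog(B)`` across subjects with per-axis
    paired t-tests.

    Expects a table with columns subject, quadrant, condition, x_mm, y_mm,
    z_mm; subjects missing either condition in a quadrant are excluded.
    """
    required = {"subject", "quadrant", "condition", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(per_subject_cogs.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    out = {}
    for quadrant, grp in per_subject_cogs.groupby("quadrant"):
        wide = grp.pivot_table(index="subject", columns="condition",
                               values=["x_mm", "y_mm", "z_mm"]).dropna()
        if wide.empty or condition_a not in grp["condition"].values:
            continue
        tests = []
        deltas = []
        sds = []
        for axis in ("x_mm", "y_mm", "z_mm"):
            a = wide[(axis, condition_a)].to_numpy()
            b = wide[(axis, condition_b)].to_numpy()
            r = paired_t(a, b)
            tests.append(r)
            deltas.append(r.mean_diff)
            sds.append(r.sd_diff)
        out[quadrant] = CogShift(
            quadrant=quadrant,
            delta_mm=tuple(deltas),
            sd_mm=tuple(sds),
            tests=tuple(tests),
            n_subjects=len(wide),
        )
    return out
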