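"""Boundary-mask construction per lobule.

Six masks seed the three gradient directions: deep (WM fissure core),
superficial (outer surface), anterior/posterior (neighbouring lobules),
medial (contralateral hemisphere) and lateral (remaining outline).  Hard
label maps are disjoint, so "overlap" between neighbouring structures is
taken after one-voxel dilation with the 26-neighbour structuring element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AdjacencyError, BoundaryError

__all__ = [
    "BoundarySet",
    "deep_fissure_boundary",
    "superficial_boundary",
    "ap_boundaries",
    "medial_boundary",
    "lobule_outline",
    "lateral_boundary",
    "build_boundary_set",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _dilate1(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=_STRUCT26)


@dataclass
class BoundarySet:
    """The six boundary masks for one lobule in one hemisphere.

    Masks are made pairwise disjoint by the fixed precedence
    deep > superficial > medial > anterior > posterior > lateral.
    """

    lobule: int
    hemisphere: str
    deep: np.ndarray
    superficial: np.ndarray
    anterior: np.ndarray
    posterior: np.ndarray
    medial: np.ndarray
    lateral: np.ndarray

    def pairs(self):
        """Origin/destination boundary pairs per gradient direction, ordered
        so ratio 0 sits at step 1 of the published convention:
        deep->superficial, lateral->medial, posterior->anterior."""
        return {
            "fissure_depth": (self.deep, self.superficial),
            "mediolateral": (self.lateral, self.medial),
            "posterior_anterior": (self.posterior, self.anterior),
        }


def deep_fissure_boundary(wm_probability: np.ndarray, threshold: float = 0.99) -> np.ndarray:
    """Voxels with WM probability strictly above ``threshold``."""
    p = np.asarray(wm_probability)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("wm_probability values must lie in [0, 1]")
    mask = p > threshold
    if not mask.any():
        raise BoundaryError(f"no voxel exceeds WM probability {threshold}")
    return mask


def superficial_boundary(lobule_mask: np.ndarray, cerebellum_mask: np.ndarray) -> np.ndarray:
    """One-voxel dilation of the lobule minus the cerebellum mask: the shell
    of exterior voxels where the lobule reaches the outer surface."""
    lob = lobule_mask.astype(bool)
    cer = cerebellum_mask.astype(bool)
    if (lob & ~cer).any():
        raise ValueError("lobule_mask must be contained in cerebellum_mask")
    mask = _dilate1(lob) & ~cer
    if not mask.any():
        raise BoundaryError("lobule is fully interior: no superficial boundary")
    return mask


def ap_boundaries(lobule_mask, anterior_neighbour_mask, posterior_neighbour_mask):
    """Anterior/posterior borders: overlap of the dilated lobule with each
    dilated neighbour (strict intersection of disjoint labels is empty)."""
    lob_d = _dilate1(lobule_mask.astype(bool))
    out = []
    for name, nb in (("anterior", anterior_neighbour_mask), ("posterior", posterior_neighbour_mask)):
        nb = nb.astype(bool)
        if not nb.any():
            raise AdjacencyError(f"{name} neighbour mask is empty")
        b = lob_d & _dilate1(nb)
        if not b.any():
            raise AdjacencyError(f"lobule does not touch its {name} neighbour")
        out.append(b)
    return tuple(out)


def medial_boundary(lobule_left_mask: np.ndarray, lobule_right_mask: np.ndarray) -> np.ndarray:
    """Midline border: dilated-overlap of the left and right homologues."""
    left = lobule_left_mask.astype(bool)
    right = lobule_right_mask.astype(bool)
    if not left.any() or not right.any():
        raise AdjacencyError("hemisphere lobule mask is empty")
    mask = _dilate1(left) & _dilate1(right)
    if not mask.any():
        raise AdjacencyError("left and right lobules do not meet at the midline")
    return mask


def lobule_outline(lobule_mask: np.ndarray) -> np.ndarray:
    """Voxels of the lobule having at least one 26-neighbour outside it."""
    lob = lobule_mask.astype(bool)
    interior = ndimage.binary_erosion(lob, structure=_STRUCT26, border_value=0)
    return lob & ~interior


def lateral_boundary(
    outline: np.ndarray,
    posterior: np.ndarray,
    anterior: np.ndarray,
    medial: np.ndarray,
    deep: np.ndarray,
    superficial: np.ndarray,
    lateral_axis: int = 0,
    lateral_sign: int | None = None,
) -> np.ndarray:
    """Outline minus the other five boundaries, restricted to the largest
    connected component on the lateral side of the lobule centroid.

    ``lateral_sign`` is -1 when lateral means decreasing coordinate along
    ``lateral_axis`` (left hemisphere under the left->right axis convention),
    +1 for the right hemisphere, or ``None`` to skip the side restriction.
    """
    rest = outline.astype(bool)
    for m in (posterior, anterior, medial, deep, superficial):
        rest &= ~m.astype(bool)
    if not rest.any():
        raise BoundaryError("outline fully covered by other boundaries")
    if lateral_sign is not None:
        centroid = np.mean(np.nonzero(outline), axis=1)[lateral_axis]
        coord = np.indices(rest.shape)[lateral_axis]
        side = coord > centroid if lateral_sign > 0 else coord < centroid
        if (rest & side).any():
            rest &= side
    labeled, n = ndimage.label(rest, structure=_STRUCT26)
    if n > 1:
        counts = np.bincount(labeled.ravel())[1:]
        rest = labeled == (int(np.argmax(counts)) + 1)
    if not rest.any():
        raise BoundaryError("lateral boundary empty")
    return rest


def build_boundary_set(anatomy, lobule: int, hemisphere: str, wm_threshold: float = 0.99) -> BoundarySet:
    """Assemble the full :class:`BoundarySet` for one phantom lobule.

    Target lobules must have both neighbours present (labels ``lobule +/- 1``
    in the same hemisphere).  The precedence
    deep > superficial > medial > anterior > posterior > lateral is applied
    so the returned masks are pairwise disjoint.
    """
    lob = anatomy.lobule_mask(lobule, hemisphere)
    if not lob.any():
        raise BoundaryError(f"lobule {lobule} ({hemisphere}) is empty")
    other = "right" if hemisphere == "left" else "left"

    deep = deep_fissure_boundary(anatomy.wm_probability, wm_threshold)
    superficial = superficial_boundary(lob, anatomy.cerebellum_mask)
    anterior, posterior = ap_boundaries(
        lob,
        anatomy.lobule_mask(lobule + 1, hemisphere) if lobule < anatomy.n_lobules else _raise_missing(lobule, "anterior"),
        anatomy.lobule_mask(lobule - 1, hemisphere) if lobule > 1 else _raise_missing(lobule, "posterior"),
    )
    medial = medial_boundary(anatomy.lobule_mask(lobule, "left"), anatomy.lobule_mask(lobule, "right"))
    outline = lobule_outline(lob)
    lateral_sign = -1 if hemisphere == "left" else 1
    lateral = lateral_boundary(outline, posterior, anterior, medial, deep, superficial,
                               lateral_axis=0, lateral_sign=lateral_sign)

    superficial = superficial & ~deep
    medial = medial & ~(deep | superficial)
    anterior = anterior & ~(deep | superficial | medial)
    posterior = posterior & ~(deep | superficial | medial | anterior)
    lateral = lateral & ~(deep | superficial | medial | anterior | posterior)
    for name, m in (("superficial", superficial), ("medial", medial), ("anterior", anterior),
                    ("posterior", posterior), ("lateral", lateral)):
        if not m.any():
            raise BoundaryError(f"{name} boundary empty after precedence resolution")

    return BoundarySet(
        lobule=lobule,
        hemisphere=hemisphere,
        deep=deep,
        superficial=superficial,
        anterior=anterior,
        posterior=posterior,
        medial=medial,
        lateral=lateral,
    )


def _raise_missing(lobule: int, which: str):
    raise AdjacencyError(f"lobule {lobule} has no {which} neighbour label")
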