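"""NIfTI volume I/O and task-design table round-trips.

All volumes are stored with a diagonal affine built from the voxel size, with
the axis convention: axis 0 = left -> right, axis 1 = posterior -> anterior,
axis 2 = inferior -> superior.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib
import pandas as pd

from .errors import ShapeError

__all__ = ["read_volume", "write_volume", "read_design_tsv", "write_design_tsv"]


def write_volume(data: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0), tr_s: float | None = None) -> None:
    """Write a 3D or 4D array as NIfTI with a diagonal affine.

    For 4D data the repetition time (seconds) is stored in the 4th zoom.
    Boolean arrays are written as uint8.
    """
    if data.ndim not in (3, 4):
        raise ShapeError(f"expected 3D or 4D data, got ndim={data.ndim}")
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(data, affine)
    zooms = list(voxel_size_mm)
    if data.ndim == 4:
        zooms.append(tr_s if tr_s is not None else 1.0)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_volume(path):
    """Read a NIfTI file; returns ``(data, voxel_size_mm, tr_s)``.

    ``tr_s`` is ``None`` for 3D images.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    tr_s = float(zooms[3]) if data.ndim == 4 else None
    return data, voxel_size, tr_s


def write_design_tsv(design, path) -> None:
    """Write block onsets as a 3-column onset/duration/condition TSV (seconds)."""
    df = pd.DataFrame(
        [(b.onset_s, b.duration_s, b.condition) for b in design.blocks],
        columns=["onset", "duration", "condition"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_design_tsv(path, tr_s: float, n_volumes: int, run_id: int = 0):
    from .phantom import Block, TaskDesign

    df = pd.read_csv(path, sep="\t")
    blocks = [Block(float(r.onset), float(r.duration), str(r.condition)) for r in df.itertuples()]
    return TaskDesign(blocks=blocks, tr_s=tr_s, n_volumes=n_volumes, run_id=run_id)
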