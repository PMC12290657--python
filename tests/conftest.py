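import numpy as np
import pytest

from cbgrad.phantom import generate_anatomy, build_task_design, compute_intrinsic_coords


@pytest.fixture(scope="session")
def anatomy48():
    """Desk-scale phantom shared across the session (read-only)."""
    return generate_anatomy((48, 48, 48), n_lobules=3, fold_count=4, seed=7,
                            band_thickness_vox=8.0, fold_amplitude_vox=2.0)


@pytest.fixture(scope="session")
def anatomy24():
    return generate_anatomy((24, 24, 24), n_lobules=3, fold_count=3, seed=3,
                            band_thickness_vox=4.0)


@pytest.fixture(scope="session")
def coords48(anatomy48):
    return compute_intrinsic_coords(anatomy48, [2], n_steps=7)


@pytest.fixture(scope="session")
def design90():
    """Default run: 300 s, TR 3.3 s, 20 s ON / 10 s OFF, alternating tasks."""
    return build_task_design(300.0, 3.3, 20.0, 10.0, ("MCFT", "SUFF"))


def make_slab(thickness=21, section=(8, 8), axis=0):
    """Slab ROI between two parallel boundary planes along ``axis``.

    Returns (roi, origin, dest) in a grid with one boundary plane on each
    side of the slab.
    """
    n = thickness + 2
    shape = [section[0], section[1]]
    shape.insert(axis, n)
    grid = np.zeros(tuple(shape), dtype=bool)

    def plane(i):
        m = np.zeros_like(grid)
        sl = [slice(None)] * 3
        sl[axis] = i
        m[tuple(sl)] = True
        return m

    roi = np.zeros_like(grid)
    sl = [slice(None)] * 3
    sl[axis] = slice(1, thickness + 1)
    roi[tuple(sl)] = True
    return roi, plane(0), plane(n - 1)
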