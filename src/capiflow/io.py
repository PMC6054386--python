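"""Array writers: NPZ always, NIfTI when nibabel is available.

The NIfTI affine places voxels on the phantom's physical grid (cell size
``L/n`` mm in-plane, slab thickness out of plane), so maps overlay
correctly in standard viewers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .phantom import PhantomSpec

__all__ = ["save_field_npz", "load_field_npz", "save_field_nifti",
           "streamline_to_csv"]


def save_field_npz(path: str | Path, **fields: np.ndarray) -> None:
    """Write named 2D/3D arrays to a compressed NPZ."""
    np.savez_compressed(path, **fields)


def load_field_npz(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        return {k: z[k] for k in z.files}


def _affine(spec: PhantomSpec) -> np.ndarray:
    return np.diag([spec.hy, spec.hx, spec.thickness, 1.0])


def save_field_nifti(path: str | Path, arr: np.ndarray,
                     spec: PhantomSpec) -> None:
    """Write a 2D field or 2D+t movie as NIfTI (requires nibabel).

    A 2D array is stored as (nx, ny, 1); a (nt, nx, ny) movie as
    (nx, ny, 1, nt).
    """
    import nibabel as nib

    arr = np.asarray(arr)
    if arr.ndim == 2:
        data = arr[:, :, None]
    elif arr.ndim == 3:
        data = arr.transpose(1, 2, 0)[:, :, None, :]
    else:
        raise ValueError("expected a 2D field or (nt, nx, ny) movie")
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                             _affine(spec)), str(path))


def streamline_to_csv(sl, path: str | Path) -> None:
    """Dump a streamline polyline as per-segment CSV for plotting."""
    import pandas as pd

    p = sl.points
    pd.DataFrame({
        "x0": p[:-1, 0], "y0": p[:-1, 1], "x1": p[1:, 0], "y1": p[1:, 1],
        "seg_len_mm": sl.seg_len, "seg_speed_mm_s": sl.seg_speed,
    }).to_csv(path, index=False)
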