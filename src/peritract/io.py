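"""File I/O: NIfTI volumes, FSL bval/bvec text, TRK/TCK streamlines."""

from __future__ import annotations

import numpy as np
import nibabel as nib

from peritract.curvegeom import Streamline
from peritract.diffusion import AcquisitionScheme

__all__ = [
    "load_volume",
    "save_volume",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "load_streamlines",
    "save_streamlines",
]


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def read_bvals_bvecs(bval_path, bvec_path) -> AcquisitionScheme:
    """FSL dialect: whitespace-separated rows; bvecs as 3 rows or 3 columns."""
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def write_bvals_bvecs(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(str(bvec_path), scheme.bvecs.T, fmt="%.6f")


def save_streamlines(path, streamlines, affine: np.ndarray | None = None,
                     shape=None) -> None:
    """Write streamlines (world mm) to .trk or .tck.

    For TRK, ``affine`` and ``shape`` describe the reference image grid
    (defaults to identity / a generous bounding box).
    """
    path = str(path)
    pts = [np.asarray(s.points, dtype=np.float32) for s in streamlines]
    tractogram = nib.streamlines.Tractogram(pts, affine_to_rasmm=np.eye(4))
    if path.endswith(".trk"):
        if affine is None:
            affine = np.eye(4)
        if shape is None:
            hi = np.max([p.max(axis=0) for p in pts], axis=0) if pts else np.ones(3)
            inv = np.linalg.inv(affine)
            shape = tuple(int(np.ceil(v)) + 1
                          for v in (hi @ inv[:3, :3].T + inv[:3, 3]))
        header = {
            nib.streamlines.trk.Field.VOXEL_TO_RASMM: np.asarray(affine, np.float32),
            nib.streamlines.trk.Field.VOXEL_SIZES:
                np.linalg.norm(np.asarray(affine)[:3, :3], axis=0).astype(np.float32),
            nib.streamlines.trk.Field.DIMENSIONS: np.asarray(shape, np.int16),
        }
        nib.streamlines.save(tractogram, path, header=header)
    else:
        nib.streamlines.save(tractogram, path)


def load_streamlines(path) -> list[Streamline]:
    """Read .trk/.tck into world-mm Streamlines (point order preserved)."""
    tract = nib.streamlines.load(str(path))
    return [Streamline(np.asarray(s, dtype=float)) for s in tract.streamlines]
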