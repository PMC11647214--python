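"""Containers and I/O for multi-shell diffusion-weighted datasets.

A :class:`DiffusionDataset` bundles the 4-D signal grid with its gradient
table (FSL-style b-values and unit gradient directions), the voxel-to-world
affine and a brain mask.  NIfTI volumes are read and written with nibabel;
gradient tables use the FSL text convention (``bvals``: one row of b-values,
``bvecs``: three rows of direction components).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "DiffusionDataset",
    "load_diffusion_dataset",
    "save_diffusion_dataset",
    "read_gradient_table",
    "write_gradient_table",
    "save_nifti",
    "load_nifti",
]

#: tolerance on the unit norm of b>0 gradient directions
_UNIT_TOL = 1e-3


@dataclass
class DiffusionDataset:
    """4-D diffusion signal with gradient table and voxel geometry.

    Parameters
    ----------
    signal : ndarray, shape (X, Y, Z, N)
        Non-negative signal intensities, one volume per gradient.
    bvals : ndarray, shape (N,)
        b-value per volume in s/mm^2.
    bvecs : ndarray, shape (N, 3)
        Gradient direction per volume; unit norm for b > 0 volumes,
        arbitrary (conventionally zero) for b = 0 volumes.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (mm) transform.
    brain_mask : ndarray of bool, shape (X, Y, Z), optional
        Voxels to analyse; defaults to the full grid.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray
    brain_mask: np.ndarray | None = None
    subject_id: str = "subject"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape[0] == 3 and self.bvecs.shape[1] != 3:
            self.bvecs = self.bvecs.T
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be a 4-D (x, y, z, volume) array")
        n = self.signal.shape[3]
        if len(self.bvals) != n or self.bvecs.shape != (n, 3):
            raise ValueError(
                f"gradient table length mismatch: {n} volumes, "
                f"{len(self.bvals)} bvals, {self.bvecs.shape[0]} bvecs"
            )
        if not np.any(self.bvals == 0):
            raise ValueError("at least one b=0 volume is required")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("b>0 gradient directions must have unit norm")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.signal.shape[:3], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask).astype(bool)
            if self.brain_mask.shape != self.signal.shape[:3]:
                raise ValueError("brain_mask shape does not match signal grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel spacing in mm, from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique nonzero b-values."""
        return np.unique(self.bvals[self.bvals > 0])

    def b0_mean(self) -> np.ndarray:
        """Mean of the b=0 volumes, shape (X, Y, Z)."""
        return self.signal[..., self.bvals == 0].mean(axis=3)


def make_affine(voxel_size_mm) -> np.ndarray:
    """Diagonal voxel->world affine for (an)isotropic spacing."""
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vs
    return aff


def read_gradient_table(bvals_path, bvecs_path):
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def write_gradient_table(bvals, bvecs, bvals_path, bvecs_path) -> None:
    np.savetxt(bvals_path, np.asarray(bvals)[None, :], fmt="%.1f")
    np.savetxt(bvecs_path, np.asarray(bvecs).T, fmt="%.6f")


def load_nifti(path):
    img = nib.load(os.fspath(path))
    return np.asarray(img.get_fdata()), img.affine


def save_nifti(data, affine, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data).astype(np.float32), affine), os.fspath(path))


def load_diffusion_dataset(dwi_path, bvals_path, bvecs_path, mask_path=None,
                           subject_id="subject") -> DiffusionDataset:
    signal, affine = load_nifti(dwi_path)
    bvals, bvecs = read_gradient_table(bvals_path, bvecs_path)
    mask = None
    if mask_path is not None:
        mask = load_nifti(mask_path)[0] > 0.5
    return DiffusionDataset(signal, bvals, bvecs, affine, mask, subject_id=subject_id)


def save_diffusion_dataset(data: DiffusionDataset, out_dir, stem="dwi") -> None:
    os.makedirs(out_dir, exist_ok=True)
    save_nifti(data.signal, data.affine, os.path.join(out_dir, f"{stem}.nii.gz"))
    write_gradient_table(data.bvals, data.bvecs,
                         os.path.join(out_dir, f"{stem}.bvals"),
                         os.path.join(out_dir, f"{stem}.bvecs"))
    save_nifti(data.brain_mask.astype(np.uint8), data.affine,
               os.path.join(out_dir, f"{stem}_mask.nii.gz"))
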