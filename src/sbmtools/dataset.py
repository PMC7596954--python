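"""Masked, vectorized gray-matter density datasets and NIfTI round-tripping.

A :class:`GMDataset` is the in-memory container every analysis stage
consumes: an ``N x V`` matrix of per-participant gray-matter densities
restricted to the ``V`` voxels of a shared boolean brain mask, together
with the geometry (mask volume, affine, voxel size) needed to map rows
back into 3D volumes.  Voxels are ordered row-major (C order) over the
mask, indices 0-based; world coordinates follow the NIfTI affine.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np


class ShapeMismatchError(ValueError):
    """A volume does not share shape/affine with the mask."""


def _deterministic_gz_bytes(raw: bytes) -> bytes:
    # mtime=0 keeps repeated writes byte-identical
    return gzip.compress(raw, compresslevel=1, mtime=0)


def save_nifti(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a volume as .nii or .nii.gz (deterministic gzip, float64)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine)
    if path.name.endswith(".nii.gz"):
        path.write_bytes(_deterministic_gz_bytes(img.to_bytes()))
    else:
        img.to_filename(str(path))
    return path


@dataclass
class GMDataset:
    """Participant-by-voxel gray-matter density matrix plus geometry.

    Attributes
    ----------
    data : (N, V) float64 array
        Masked, vectorized densities; row ``i`` is subject ``subject_ids[i]``.
    mask : (X, Y, Z) bool array
        Analysis mask; ``V == mask.sum()``.
    affine : (4, 4) array
        NIfTI voxel-to-world transform shared by all volumes.
    subject_ids : list of str
        Ordered identifiers aligning rows with the phenotype table.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (subjects x voxels)")
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but mask has "
                f"{int(self.mask.sum())} true voxels"
            )
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i + 1:04d}" for i in range(self.data.shape[0])]
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length does not match data rows")
        if np.isnan(self.data).any():
            raise ValueError("NaN voxels inside mask")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def unmask(self, row: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a V-vector back into a 3D volume (zeros outside mask)."""
        row = np.asarray(row, dtype=np.float64)
        if row.shape != (self.n_voxels,):
            raise ValueError("row length does not match mask voxel count")
        vol = np.full(self.mask.shape, fill, dtype=np.float64)
        vol[self.mask] = row
        return vol

    def mask_volume(self, volume: np.ndarray) -> np.ndarray:
        """Extract the masked voxels of a 3D volume in analysis order."""
        if volume.shape != self.mask.shape:
            raise ShapeMismatchError("volume shape does not match mask")
        return np.asarray(volume, dtype=np.float64)[self.mask]

    def copy_with(self, data: np.ndarray) -> "GMDataset":
        return GMDataset(
            data=np.asarray(data, dtype=np.float64),
            mask=self.mask,
            affine=self.affine,
            subject_ids=list(self.subject_ids),
        )

    # ------------------------------------------------------------------ I/O

    def write(self, outdir: str | Path, gzipped: bool = True) -> list[Path]:
        """Write one NIfTI per subject plus ``mask.nii[.gz]`` into *outdir*."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = ".nii.gz" if gzipped else ".nii"
        paths = []
        for i, sid in enumerate(self.subject_ids):
            paths.append(save_nifti(self.unmask(self.data[i]), self.affine,
                                    outdir / f"{sid}_gmdensity{ext}"))
        save_nifti(self.mask.astype(np.float32), self.affine, outdir / f"mask{ext}")
        return paths


def load_dataset(
    paths: Sequence[str | Path],
    mask_path: str | Path,
    subject_ids: Sequence[str] | None = None,
) -> GMDataset:
    """Load NIfTI volumes, check geometry against the mask, and vectorize.

    Every volume must share shape and affine with the mask; a mismatch is
    reported naming the offending file.  NaN values inside the mask and
    empty masks are rejected.
    """
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.get_fdata()) > 0.5
    if mask.sum() == 0:
        raise ValueError(f"mask {mask_path} has no true voxels")
    affine = mask_img.affine
    rows = []
    for p in paths:
        img = nib.load(str(p))
        if img.shape != mask.shape:
            raise ShapeMismatchError(
                f"{p}: shape {img.shape} does not match mask shape {mask.shape}"
            )
        if not np.allclose(img.affine, affine, atol=1e-4):
            raise ShapeMismatchError(f"{p}: affine does not match mask affine")
        vol = np.asarray(img.get_fdata(), dtype=np.float64)
        row = vol[mask]
        if np.isnan(row).any():
            raise ValueError(f"{p}: NaN voxels inside mask")
        rows.append(row)
    ids = list(subject_ids) if subject_ids is not None else [
        Path(p).name.split(".")[0].replace("_gmdensity", "") for p in paths
    ]
    return GMDataset(data=np.vstack(rows), mask=mask, affine=affine, subject_ids=ids)
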