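"""Reading and writing of MRI slices and binary masks.

Slices are 2D non-negative intensity grids on a 12-bit scale. Intensities
are never rescaled at read time: the absolute scale matters downstream
(the background-removal threshold of 5 and the texture quantization both
assume raw scanner-style units).

Coordinate convention (shared by all modules): 0-based ``(row, col)``,
``row`` = y, ``col`` = x.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "read_slice",
    "write_slice",
    "write_mask",
    "read_mask",
    "select_median_tumor_slice",
    "validate_slice",
    "validate_mask",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def validate_slice(pixels: np.ndarray) -> np.ndarray:
    """Check the SliceImage invariants and return a float64 copy."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"slice must be 2D, got shape {arr.shape}")
    if arr.shape[0] < 32 or arr.shape[1] < 32:
        raise ValueError(f"slice must be at least 32x32, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("slice contains non-finite values")
    if arr.min() < 0:
        raise ValueError("slice contains negative intensities")
    return arr


def validate_mask(values: np.ndarray, like: np.ndarray | None = None) -> np.ndarray:
    """Check BinaryMask invariants; returns a bool array."""
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {arr.shape}")
    if like is not None and arr.shape != np.asarray(like).shape:
        raise ValueError(f"mask shape {arr.shape} does not match image {np.asarray(like).shape}")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask values must be strictly binary (0/1)")
    return arr.astype(bool)


def _is_nifti(path: str) -> bool:
    return any(str(path).endswith(s) for s in _NIFTI_SUFFIXES)


def read_slice(path: str, slice_index: int | None = None) -> np.ndarray:
    """Read a 2D slice from a PNG/TIFF image or a NIfTI volume.

    For a 3D NIfTI volume ``slice_index`` selects along the last axis
    (0-based). Intensities are returned as stored, without rescaling.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(path).dataobj)
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError("slice_index required for a 3D volume")
            if not (0 <= slice_index < data.shape[2]):
                raise IndexError(
                    f"slice_index {slice_index} out of range for {data.shape[2]} slices"
                )
            data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise ValueError(f"unsupported NIfTI dimensionality: {data.ndim}")
    else:
        data = np.asarray(iio.imread(path))
        if data.ndim == 3:  # greyscale stored with a channel axis
            data = data[..., 0]
        if data.ndim != 2:
            raise ValueError(f"image at {path} is not 2D")
    return validate_slice(data)


def write_slice(pixels: np.ndarray, path: str) -> None:
    """Write an integer-valued slice as 16-bit PNG/TIFF (lossless)."""
    arr = validate_slice(pixels)
    rounded = np.rint(arr)
    if np.any(np.abs(arr - rounded) > 1e-9) or rounded.max() > np.iinfo(np.uint16).max:
        raise ValueError("only integer-valued slices within uint16 range can be written")
    iio.imwrite(path, rounded.astype(np.uint16))


def write_mask(mask: np.ndarray, path: str) -> None:
    """Write a binary mask losslessly; pixels are stored as {0, 1}."""
    arr = validate_mask(mask)
    iio.imwrite(path, arr.astype(np.uint8))


def read_mask(path: str, slice_index: int | None = None) -> np.ndarray:
    """Read a mask; any nonzero value maps to 1."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(path).dataobj)
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError("slice_index required for a 3D volume")
            data = data[:, :, slice_index]
    else:
        data = np.asarray(iio.imread(path))
        if data.ndim == 3:
            data = data[..., 0]
    return data != 0


def select_median_tumor_slice(volume: np.ndarray, gt_volume: np.ndarray) -> int:
    """Index of the slice holding the median tumor voxel along the slice axis.

    Sorting tumor voxels by slice index, this is the slice at which the
    cumulative count first reaches half the total (ties to the lower index).
    The returned slice always contains at least one tumor voxel.
    """
    vol = np.asarray(volume)
    gt = np.asarray(gt_volume)
    if vol.shape != gt.shape:
        raise ValueError("volume and ground truth must share dimensions")
    if vol.ndim != 3:
        raise ValueError("expected 3D volumes")
    per_slice = (gt != 0).sum(axis=(0, 1))
    total = int(per_slice.sum())
    if total == 0:
        raise ValueError("ground truth volume contains no tumor voxels")
    cum = np.cumsum(per_slice)
    return int(np.argmax(cum >= total / 2.0))
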