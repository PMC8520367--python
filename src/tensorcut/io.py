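"""Readers and writers for the package's on-disk formats.

Conventions (documented once, used everywhere):

* Voxel indexing is 0-based, row-major.
* Tensor fields are NIfTI volumes with a trailing dimension of 6 components in
  lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz).
* Seed masks are label images with values in {0, 1, 2}: 0 unknown, 1 target,
  2 background. 2D masks may be PNG or NIfTI; 3D only NIfTI.
* Output masks use 0/1. NIfTI affines are carried through untouched.
* Run audits are flat JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .energy import SeedSets
from .errors import FormatError
from .tensors import LOWER_TRIANGULAR_ORDER, ScalarImage, TensorField

__all__ = [
    "read_scalar_image",
    "write_scalar_image",
    "read_tensor_nifti",
    "write_tensor_nifti",
    "read_seed_mask",
    "read_label_array",
    "write_mask",
    "write_seed_mask",
    "write_audit",
    "read_audit",
]

log = logging.getLogger("tensorcut")

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path) -> bool:
    name = str(path).lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_scalar_image(path):
    """Read a scalar image (NIfTI, PNG grayscale, or .npy).

    Returns ``(ScalarImage, affine)``; affine is None for non-NIfTI inputs.
    """
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        return ScalarImage(np.squeeze(data)), img.affine
    if path.suffix.lower() == ".npy":
        return ScalarImage(np.load(path)), None
    data = np.asarray(iio.imread(path), dtype=float)
    if data.ndim == 3:  # collapse RGB(A) to grayscale by channel mean
        data = data[..., :3].mean(axis=-1)
    return ScalarImage(data), None


def write_scalar_image(path, img: ScalarImage, affine=None):
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(img.values, np.eye(4) if affine is None else affine), str(path))
    elif path.suffix.lower() == ".npy":
        np.save(path, img.values)
    else:
        v = img.values
        lo, hi = float(v.min()), float(v.max())
        scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 255).astype(np.uint8))


def read_tensor_nifti(path, spd_tol=None):
    """Read a 6-component tensor NIfTI into a :class:`TensorField`.

    The trailing dimension must hold 6 lower-triangular components. Voxels
    failing SPD validation are masked out, with a logged count.
    Returns ``(TensorField, affine)``.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim < 2 or data.shape[-1] != 6:
        raise FormatError(
            f"expected a trailing dimension of 6 tensor components in order "
            f"{LOWER_TRIANGULAR_ORDER}, got shape {data.shape}"
        )
    field = TensorField(data)
    kwargs = {} if spd_tol is None else {"tol": spd_tol}
    valid = field.spd_valid_mask(**kwargs)
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("masked out %d non-SPD voxel(s) while reading %s", n_bad, path)
        field = TensorField(data, mask=valid)
    return field, img.affine


def write_tensor_nifti(path, field: TensorField, affine=None):
    """Write a tensor field with the trailing-6-component convention."""
    nib.save(
        nib.Nifti1Image(field.lower, np.eye(4) if affine is None else affine), str(path)
    )


def read_label_array(path) -> np.ndarray:
    """Read an integer label image (PNG, NIfTI or .npy) without interpretation."""
    path = Path(path)
    if _is_nifti(path):
        data = np.squeeze(np.asarray(nib.load(str(path)).dataobj))
    elif path.suffix.lower() == ".npy":
        data = np.load(path)
    else:
        data = np.asarray(iio.imread(path))
        if data.ndim == 3:
            data = data[..., 0]
    out = np.asarray(data)
    if not np.allclose(out, np.round(out)):
        raise FormatError(f"label image {path} holds non-integer values")
    return np.round(out).astype(int)


def read_seed_mask(path) -> SeedSets:
    """Decode a 0/1/2 label image into :class:`SeedSets` (1 target, 2 background)."""
    labels = read_label_array(path)
    bad = set(np.unique(labels)) - {0, 1, 2}
    if bad:
        raise FormatError(
            f"seed mask {path} holds out-of-range labels {sorted(bad)}; "
            "expected 0 (unknown), 1 (target), 2 (background)"
        )
    target = frozenset(map(tuple, np.argwhere(labels == 1)))
    background = frozenset(map(tuple, np.argwhere(labels == 2)))
    return SeedSets(target, background)


def write_seed_mask(path, seeds: SeedSets, shape, affine=None):
    """Inverse of :func:`read_seed_mask`."""
    labels = np.zeros(shape, dtype=np.uint8)
    for i in seeds.target:
        labels[i] = 1
    for i in seeds.background:
        labels[i] = 2
    _write_labels(path, labels, affine)


def write_mask(path, mask, affine=None):
    """Write a binary mask (0 background / 1 target) as PNG or NIfTI."""
    _write_labels(path, np.asarray(mask, dtype=np.uint8), affine)


def _write_labels(path, labels: np.ndarray, affine):
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(labels.astype(np.uint8), np.eye(4) if affine is None else affine), str(path))
    elif path.suffix.lower() == ".npy":
        np.save(path, labels)
    else:
        iio.imwrite(path, labels.astype(np.uint8))


def write_audit(path, audit: dict):
    with open(path, "w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_audit(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
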