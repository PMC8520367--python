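"""Synthetic phantoms with known ground truth, plus segmentation scoring.

The phantom emulates the imaging picture of delayed post-hypoxic white-matter
injury: two mirror-symmetric oval lesions flanking the midline of an axial
slice ("bilateral symmetric periventricular" geometry). It makes no claim of
radiological realism — it is a controlled test bed with exact ground truth.

Scalar phantom: piecewise-constant intensities (background level, lesion
level) plus additive Gaussian noise.

Tensor phantom: isotropic background tensors, anisotropic lesion tensors with
the principal axis along x. Noise is applied in log-tensor space — a Gaussian
perturbation of the matrix-log components followed by the matrix exponential —
so every generated tensor is SPD by construction at any noise level; the
clip-based alternative (noise on raw components, then eigenvalue clipping) was
rejected because it silently distorts the noise model near the SPD boundary.

Defaults: 64x64 slice, lesion semi-axes 8 (columns) x 5 (rows) voxels,
background diag(1,1,1)*1e-3 mm^2/s, lesion diag(1.8,0.6,0.6)*1e-3 mm^2/s,
noise SD 0.05 in log-tensor units — a nontrivial but solvable task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import SeedSets
from .errors import InvalidInputError, SpecificationError
from .tensors import ScalarImage, TensorField, matrix_to_lower, spd_expm

__all__ = [
    "PhantomSpec",
    "make_scalar_phantom",
    "make_tensor_phantom",
    "dice",
    "default_phantom_seeds",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of a bilateral-lesion phantom.

    ``lesion_center`` is the (row, col) center of the left lesion; the right
    lesion is its exact mirror about the midline column. ``lesion_axes`` are
    semi-axes (rows, cols). Tensor eigenvalues are in mm^2/s; ``noise`` is the
    Gaussian SD (intensity units for the scalar phantom, log-tensor units for
    the tensor phantom). ``seed`` drives the reproducible RNG.
    """

    shape: tuple = (64, 64)
    lesion_center: tuple = (32, 20)
    lesion_axes: tuple = (5.0, 8.0)
    background_eigs: tuple = (1e-3, 1e-3, 1e-3)
    lesion_eigs: tuple = (1.8e-3, 0.6e-3, 0.6e-3)
    background_level: float = 0.0
    lesion_level: float = 1.0
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 2:
            raise SpecificationError("phantoms are 2D axial slices")
        if any(e <= 0 for e in self.background_eigs + self.lesion_eigs):
            raise SpecificationError("tensor eigenvalues must be strictly positive")
        if self.noise < 0:
            raise SpecificationError("noise SD must be nonnegative")
        h, w = self.shape
        cr, cc = self.lesion_center
        ar, ac = self.lesion_axes
        if ar <= 0 or ac <= 0:
            raise SpecificationError("lesion semi-axes must be positive")
        for c in (cc, w - 1 - cc):
            if not (cr - ar >= 0 and cr + ar <= h - 1 and c - ac >= 0 and c + ac <= w - 1):
                raise SpecificationError("lesion ellipse does not fit inside the grid")
        # mirrored pair must not overlap (or coincide on the midline)
        if cc + ac >= (w - 1 - cc) - ac:
            raise SpecificationError("mirrored lesions overlap; move the center off the midline")

    @property
    def mirrored_center(self):
        return (self.lesion_center[0], self.shape[1] - 1 - self.lesion_center[1])


def _lesion_mask(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.shape
    rr, cc = np.mgrid[0:h, 0:w]
    ar, ac = spec.lesion_axes
    mask = np.zeros(spec.shape, dtype=bool)
    for cr, c0 in (spec.lesion_center, spec.mirrored_center):
        mask |= ((rr - cr) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
    return mask


def make_scalar_phantom(spec: PhantomSpec):
    """Piecewise-constant scalar phantom plus additive Gaussian noise.

    Returns ``(ScalarImage, ground_truth_mask)``; reproducible for fixed seed.
    """
    mask = _lesion_mask(spec)
    img = np.where(mask, spec.lesion_level, spec.background_level).astype(float)
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise, spec.shape)
    return ScalarImage(img), mask


def make_tensor_phantom(spec: PhantomSpec):
    """Tensor phantom: isotropic background, x-aligned anisotropic lesions.

    Noise is a symmetric Gaussian perturbation of the matrix log (independent
    SD ``spec.noise`` on each of the 6 free components), mapped back with the
    matrix exponential, so every voxel is SPD at any noise level. Returns
    ``(TensorField, ground_truth_mask)``.
    """
    mask = _lesion_mask(spec)
    log_bg = np.diag(np.log(np.asarray(spec.background_eigs, float)))
    log_lesion = np.diag(np.log(np.asarray(spec.lesion_eigs, float)))
    logs = np.where(mask[..., None, None], log_lesion, log_bg)
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        n6 = rng.normal(0.0, spec.noise, spec.shape + (6,))
        noise = np.zeros(spec.shape + (3, 3))
        idx = ((0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2))
        for k, (i, j) in enumerate(idx):
            noise[..., i, j] = n6[..., k]
            noise[..., j, i] = n6[..., k]
        logs = logs + noise
    tensors = spd_expm(logs)
    return TensorField(matrix_to_lower(tensors)), mask


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidInputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def default_phantom_seeds(spec: PhantomSpec) -> SeedSets:
    """Deterministic seeding protocol for the default phantom.

    One target seed at the center of each lesion; background seeds at the four
    corners (inset by 2 voxels) and the grid center on the midline.
    """
    h, w = spec.shape
    target = {spec.lesion_center, spec.mirrored_center}
    background = {(2, 2), (2, w - 3), (h - 3, 2), (h - 3, w - 3), (h // 2, w // 2)}
    lesions = _lesion_mask(spec)
    background = {b for b in background if not lesions[b]}
    return SeedSets(frozenset(target), frozenset(background))
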