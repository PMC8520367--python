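"""Diffusion-tensor containers and dissimilarity metrics.

A diffusion tensor is a symmetric positive-definite (SPD) 3x3 matrix
describing local water diffusion (units mm^2/s, nominal). On disk and in the
compact in-memory form a tensor is 6 components in lower-triangular order

    (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)

matching the common NIfTI 6-component convention.

The dissimilarity between two tensors is a pluggable strategy. The default is
the log-Euclidean distance ||log(A) - log(B)||_F: zero iff the tensors are
equal, symmetric, and diverging without bound as either tensor approaches the
SPD boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "LOWER_TRIANGULAR_ORDER",
    "DiffusionTensor",
    "TensorField",
    "ScalarImage",
    "TensorMetric",
    "LogEuclideanMetric",
    "FrobeniusMetric",
    "AffineInvariantMetric",
    "get_metric",
    "validate_spd",
    "tensor_dissimilarity",
    "lower_to_matrix",
    "matrix_to_lower",
    "spd_logm",
    "spd_expm",
]

#: Component names in storage order.
LOWER_TRIANGULAR_ORDER = ("Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz")

# (row, col) of each lower-triangular component in the 3x3 matrix.
_TRI_ROWS = (0, 0, 1, 0, 1, 2)
_TRI_COLS = (0, 1, 1, 2, 2, 2)

#: Default SPD tolerance: smallest eigenvalue must exceed this.
SPD_TOL = 1e-10


def lower_to_matrix(components: np.ndarray) -> np.ndarray:
    """Expand (..., 6) lower-triangular components to (..., 3, 3) symmetric matrices."""
    c = np.asarray(components, dtype=float)
    if c.shape[-1] != 6:
        raise InvalidInputError(
            f"expected 6 tensor components in order {LOWER_TRIANGULAR_ORDER}, got {c.shape[-1]}"
        )
    m = np.zeros(c.shape[:-1] + (3, 3), dtype=float)
    for k, (i, j) in enumerate(zip(_TRI_ROWS, _TRI_COLS)):
        m[..., i, j] = c[..., k]
        m[..., j, i] = c[..., k]
    return m


def matrix_to_lower(matrices: np.ndarray) -> np.ndarray:
    """Collapse (..., 3, 3) symmetric matrices to (..., 6) lower-triangular components."""
    m = np.asarray(matrices, dtype=float)
    if m.shape[-2:] != (3, 3):
        raise InvalidInputError(f"expected trailing (3, 3) matrix, got shape {m.shape}")
    out = np.empty(m.shape[:-2] + (6,), dtype=float)
    for k, (i, j) in enumerate(zip(_TRI_ROWS, _TRI_COLS)):
        out[..., k] = m[..., i, j]
    return out


def spd_logm(matrices: np.ndarray, tol: float = SPD_TOL) -> np.ndarray:
    """Matrix logarithm of (..., 3, 3) SPD matrices via eigendecomposition.

    Raises :class:`InvalidInputError` if any matrix is not SPD within ``tol``.
    """
    m = np.asarray(matrices, dtype=float)
    w, v = np.linalg.eigh(m)
    if not np.all(np.isfinite(w)):
        raise InvalidInputError("non-finite eigenvalues in tensor")
    if np.any(w <= tol):
        raise InvalidInputError(
            "matrix logarithm undefined: tensor is not SPD "
            f"(smallest eigenvalue {w.min():.3e} <= tol {tol:.1e})"
        )
    return np.einsum("...ik,...k,...jk->...ij", v, np.log(w), v)


def spd_expm(matrices: np.ndarray) -> np.ndarray:
    """Matrix exponential of (..., 3, 3) symmetric matrices (result is SPD)."""
    m = np.asarray(matrices, dtype=float)
    w, v = np.linalg.eigh(m)
    return np.einsum("...ik,...k,...jk->...ij", v, np.exp(w), v)


@dataclass(frozen=True)
class DiffusionTensor:
    """One diffusion tensor, stored as 6 lower-triangular components.

    Parameters
    ----------
    components
        ``(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)``, units mm^2/s (nominal).
    """

    components: tuple

    def __post_init__(self):
        c = np.asarray(self.components, dtype=float)
        if c.shape != (6,):
            raise InvalidInputError(f"a diffusion tensor has 6 components, got shape {c.shape}")
        if not np.all(np.isfinite(c)):
            raise InvalidInputError("tensor components must be finite")
        object.__setattr__(self, "components", tuple(float(x) for x in c))

    @property
    def matrix(self) -> np.ndarray:
        """The symmetric 3x3 matrix form."""
        return lower_to_matrix(np.array(self.components))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "DiffusionTensor":
        m = np.asarray(m, dtype=float)
        if not np.allclose(m, m.T, atol=1e-12):
            raise InvalidInputError("tensor matrix must be symmetric")
        return cls(tuple(matrix_to_lower(m)))

    @classmethod
    def from_eigenvalues(cls, eigs) -> "DiffusionTensor":
        """Diagonal (axis-aligned) tensor with the given eigenvalues."""
        l1, l2, l3 = (float(e) for e in eigs)
        return cls((l1, 0.0, l2, 0.0, 0.0, l3))

    def is_spd(self, tol: float = SPD_TOL) -> bool:
        return validate_spd(self, tol)


def validate_spd(t, tol: float = SPD_TOL) -> bool:
    """True iff the tensor's smallest eigenvalue exceeds ``tol``.

    Accepts a :class:`DiffusionTensor`, a 6-vector or a 3x3 matrix.
    """
    if isinstance(t, DiffusionTensor):
        m = t.matrix
    else:
        a = np.asarray(t, dtype=float)
        m = lower_to_matrix(a) if a.shape == (6,) else a
    if m.shape != (3, 3):
        raise InvalidInputError(f"expected a 3x3 tensor, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise InvalidInputError("tensor components must be finite")
    return bool(np.linalg.eigvalsh(m)[0] > tol)


# ---------------------------------------------------------------------------
# Metric strategies
# ---------------------------------------------------------------------------


class TensorMetric:
    """Strategy interface for tensor dissimilarity.

    ``distance`` acts on single 3x3 SPD matrices. ``transform_field`` may map a
    stack of matrices to flat feature vectors whose Euclidean distance equals
    the metric distance; metrics without such an embedding return ``None`` and
    callers fall back to pairwise evaluation.
    """

    name: str = "abstract"

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        raise NotImplementedError

    def transform_field(self, matrices: np.ndarray):
        return None


class LogEuclideanMetric(TensorMetric):
    """d(A, B) = ||log A - log B||_F. Zero iff A == B; diverges near singularity."""

    name = "log_euclidean"

    def distance(self, a, b):
        return float(np.linalg.norm(spd_logm(a) - spd_logm(b)))

    def transform_field(self, matrices):
        return spd_logm(matrices).reshape(matrices.shape[:-2] + (9,))


class FrobeniusMetric(TensorMetric):
    """Plain Euclidean distance ||A - B||_F on tensor components."""

    name = "frobenius"

    def distance(self, a, b):
        return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))

    def transform_field(self, matrices):
        return np.asarray(matrices, float).reshape(matrices.shape[:-2] + (9,))


class AffineInvariantMetric(TensorMetric):
    """Riemannian distance ||log(A^{-1/2} B A^{-1/2})||_F.

    No flat embedding exists, so field operations fall back to pairwise calls;
    intended for small problems and cross-checks.
    """

    name = "affine_invariant"

    def distance(self, a, b):
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        w, v = np.linalg.eigh(a)
        if np.any(w <= SPD_TOL):
            raise InvalidInputError("affine-invariant distance requires SPD inputs")
        inv_sqrt = (v * (1.0 / np.sqrt(w))) @ v.T
        return float(np.linalg.norm(spd_logm(inv_sqrt @ b @ inv_sqrt)))


_METRICS = {
    m.name: m for m in (LogEuclideanMetric(), FrobeniusMetric(), AffineInvariantMetric())
}

DEFAULT_METRIC = "log_euclidean"


def get_metric(name: str) -> TensorMetric:
    """Look up a tensor metric by name (``log_euclidean`` is the default)."""
    try:
        return _METRICS[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown metric {name!r}; available: {sorted(_METRICS)}"
        ) from None


def tensor_dissimilarity(a, b, metric: "TensorMetric | str" = DEFAULT_METRIC) -> float:
    """Dissimilarity between two diffusion tensors.

    Zero iff ``a == b``, symmetric, and unbounded as either argument approaches
    a singular tensor. Inputs must be valid SPD tensors.
    """
    if isinstance(metric, str):
        metric = get_metric(metric)
    ma = a.matrix if isinstance(a, DiffusionTensor) else lower_to_matrix(np.asarray(a, float)) if np.asarray(a).shape == (6,) else np.asarray(a, float)
    mb = b.matrix if isinstance(b, DiffusionTensor) else lower_to_matrix(np.asarray(b, float)) if np.asarray(b).shape == (6,) else np.asarray(b, float)
    for name, m in (("first", ma), ("second", mb)):
        if not validate_spd(m):
            raise InvalidInputError(f"{name} tensor is not SPD; dissimilarity undefined")
    return metric.distance(ma, mb)


# ---------------------------------------------------------------------------
# Field containers
# ---------------------------------------------------------------------------


@dataclass
class TensorField:
    """A grid of diffusion tensors (2D slice or 3D volume).

    ``lower`` has shape ``grid_shape + (6,)`` in lower-triangular order;
    ``mask`` marks in-image voxels (True = inside). Voxel indexing is 0-based,
    row-major.
    """

    lower: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        if self.lower.ndim < 2 or self.lower.shape[-1] != 6:
            raise InvalidInputError(
                f"tensor field needs a trailing axis of 6 components, got shape {self.lower.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.shape:
                raise InvalidInputError(
                    f"mask shape {self.mask.shape} != grid shape {self.shape}"
                )

    @property
    def shape(self):
        return self.lower.shape[:-1]

    @property
    def ndim(self):
        return self.lower.ndim - 1

    def matrices(self) -> np.ndarray:
        """All tensors as ``grid_shape + (3, 3)`` symmetric matrices."""
        return lower_to_matrix(self.lower)

    @classmethod
    def from_matrices(cls, matrices: np.ndarray, mask=None) -> "TensorField":
        return cls(matrix_to_lower(matrices), mask)

    def spd_valid_mask(self, tol: float = SPD_TOL) -> np.ndarray:
        """Boolean grid: True where the voxel tensor is SPD within ``tol``."""
        w = np.linalg.eigvalsh(self.matrices())
        return np.all(np.isfinite(w), axis=-1) & (w[..., 0] > tol)

    def tensor_at(self, index) -> DiffusionTensor:
        return DiffusionTensor(tuple(self.lower[tuple(index)]))


@dataclass
class ScalarImage:
    """A scalar intensity grid (2D or 3D) with an optional in-image mask."""

    values: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise InvalidInputError(
                    f"mask shape {self.mask.shape} != image shape {self.values.shape}"
                )
        if not np.all(np.isfinite(self.values[self.mask])):
            raise InvalidInputError("scalar image contains non-finite values")

    @property
    def shape(self):
        return self.values.shape

    @property
    def ndim(self):
        return self.values.ndim
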