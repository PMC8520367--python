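"""Seed sets, effective distances and the two-term segmentation energy.

The seeded-cut objective over a binary labeling x is

    E(x) = alpha * sum_i R_i(x_i)  +  (1 - alpha) * sum_{(i,j) in N, x_i != x_j} W_ij

with 0 < alpha < 1 the expansion factor trading off the regional against the
boundary term.

Regional term R_i (four penalties):
  * target seeds:  0 for label target, K for label background (hard constraint);
  * background seeds: mirrored;
  * unknown voxels: R_i(target) = D_i^O / (D_i^O + D_i^B) and
    R_i(background) = D_i^B / (D_i^O + D_i^B), where D_i^O (resp. D_i^B) is the
    effective distance from voxel i to the target (background) seed set — the
    average feature dissimilarity between i and every seed in the set. If both
    distances vanish the two penalties tie at 0.5.

Boundary term: W_ij = exp(-d(f_i, f_j)^2 / (2 sigma^2)) across 8-neighbor
pairs (2D; in-slice by default for volumes), charged only where the labels
disagree — so cutting through homogeneous tissue is maximally expensive.

K, the hard-constraint weight, is resolved per problem instance as
(1 + (1 - alpha) * max over nodes of the incident boundary-weight sum) / alpha,
which guarantees that flipping a seed can never be part of a minimum cut once
the regional term is scaled by alpha in the graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, ContractViolationError, InvalidInputError
from .tensors import (
    DEFAULT_METRIC,
    ScalarImage,
    TensorField,
    TensorMetric,
    get_metric,
)

__all__ = [
    "SeedSets",
    "EnergyParams",
    "EffectiveDistances",
    "effective_distance",
    "compute_effective_distances",
    "regional_penalty",
    "boundary_penalty",
    "total_energy",
    "neighbor_pairs",
    "field_features",
    "resolve_params",
]

TARGET = "target"
BACKGROUND = "background"


@dataclass(frozen=True)
class SeedSets:
    """User-marked seed voxels: O (target), B (background); the rest is U (unknown).

    Indices are voxel coordinate tuples, 0-based row-major.
    """

    target: frozenset
    background: frozenset

    def __post_init__(self):
        object.__setattr__(self, "target", frozenset(tuple(i) for i in self.target))
        object.__setattr__(self, "background", frozenset(tuple(i) for i in self.background))
        if self.target & self.background:
            raise ConfigurationError("target and background seed sets overlap")

    def validate_for(self, shape, mask=None):
        """Check the seeds are well-posed on the given grid (raises otherwise)."""
        if not self.target:
            raise ConfigurationError("target seed set O is empty; mark at least one target voxel")
        if not self.background:
            raise ConfigurationError(
                "background seed set B is empty; mark at least one background voxel"
            )
        for name, seeds in ((TARGET, self.target), (BACKGROUND, self.background)):
            for idx in seeds:
                if len(idx) != len(shape) or any(
                    not (0 <= c < s) for c, s in zip(idx, shape)
                ):
                    raise ConfigurationError(f"{name} seed {idx} outside grid shape {shape}")
                if mask is not None and not mask[idx]:
                    raise ConfigurationError(f"{name} seed {idx} lies outside the image mask")

    def label_of(self, index):
        index = tuple(index)
        if index in self.target:
            return TARGET
        if index in self.background:
            return BACKGROUND
        return None


@dataclass(frozen=True)
class EnergyParams:
    """Tunable weights of the segmentation energy.

    alpha: expansion factor in (0, 1); weights the regional term (default 0.5).
    sigma: boundary kernel scale; None means data-adaptive (mean neighbor
        dissimilarity over the image, with fallback 1.0 when that mean is 0).
    hard_constraint_weight: K; None means resolved per instance so that a seed
        flip always costs more than any achievable cut.
    metric: tensor dissimilarity strategy name, recorded in all outputs.
    """

    alpha: float = 0.5
    sigma: float = None
    hard_constraint_weight: float = None
    metric: str = DEFAULT_METRIC

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.sigma is not None and not (self.sigma > 0):
            raise ConfigurationError(f"sigma must be positive, got {self.sigma}")
        if self.hard_constraint_weight is not None and not (self.hard_constraint_weight > 0):
            raise ConfigurationError("hard_constraint_weight must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "sigma": self.sigma,
                "hard_constraint_weight": self.hard_constraint_weight,
                "metric": self.metric,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EnergyParams":
        d = json.loads(text)
        return cls(
            alpha=d.get("alpha", 0.5),
            sigma=d.get("sigma"),
            hard_constraint_weight=d.get("hard_constraint_weight"),
            metric=d.get("metric", DEFAULT_METRIC),
        )


@dataclass
class EffectiveDistances:
    """Per-voxel average dissimilarity to the target (D^O) and background (D^B) seeds.

    Stored as full-grid float arrays; NaN outside the mask.
    """

    to_target: np.ndarray
    to_background: np.ndarray


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def field_features(field, metric=None):
    """Return ``(features, dist)`` for a scalar or tensor field.

    ``features`` is an array of shape ``grid_shape + (k,)`` such that the
    Euclidean distance between two feature vectors equals the configured
    dissimilarity; ``dist(fa, fb)`` evaluates it for single voxels. For metrics
    without a flat embedding, features are the raw 3x3 matrices and ``dist``
    is the metric itself.
    """
    if isinstance(field, ScalarImage):
        feats = field.values[..., None]
        return feats, lambda a, b: float(abs(a[0] - b[0]))
    if isinstance(field, TensorField):
        if metric is None:
            metric = get_metric(DEFAULT_METRIC)
        elif isinstance(metric, str):
            metric = get_metric(metric)
        mats = field.matrices()
        flat = metric.transform_field(mats)
        if flat is not None:
            return flat, lambda a, b: float(np.linalg.norm(a - b))
        return mats, lambda a, b: metric.distance(a, b)
    raise InvalidInputError(f"unsupported field type {type(field).__name__}")


def _is_flat(features) -> bool:
    # flat embeddings end in a single feature axis; raw matrices end in (3, 3)
    return features.shape[-2:] != (3, 3)


def effective_distance(index, seeds, field, metric=None) -> float:
    """Average dissimilarity between voxel ``index`` and a seed set.

    Implements D_i^S = (1/|S|) * sum_{s in S} d(f_i, f_s).
    """
    seeds = [tuple(s) for s in seeds]
    if not seeds:
        raise ConfigurationError("effective distance over an empty seed set is undefined")
    feats, dist = field_features(field, metric)
    fi = feats[tuple(index)]
    return float(np.mean([dist(fi, feats[s]) for s in seeds]))


def compute_effective_distances(field, seeds: SeedSets, metric=None) -> EffectiveDistances:
    """Vectorized D^O / D^B over every in-mask voxel."""
    seeds.validate_for(field.shape, field.mask)
    feats, dist = field_features(field, metric)
    shape = field.shape
    out_t = np.full(shape, np.nan)
    out_b = np.full(shape, np.nan)
    voxels = [tuple(v) for v in np.argwhere(field.mask)]
    if _is_flat(feats):
        fv = np.stack([feats[v] for v in voxels])
        for out, sset in ((out_t, seeds.target), (out_b, seeds.background)):
            fs = np.stack([feats[s] for s in sorted(sset)])
            mean_d = cdist(fv, fs).mean(axis=1)
            for v, d in zip(voxels, mean_d):
                out[v] = d
    else:
        for out, sset in ((out_t, seeds.target), (out_b, seeds.background)):
            slist = sorted(sset)
            for v in voxels:
                out[v] = np.mean([dist(feats[v], feats[s]) for s in slist])
    return EffectiveDistances(out_t, out_b)


# ---------------------------------------------------------------------------
# Penalties
# ---------------------------------------------------------------------------


def regional_penalty(index, label, seeds: SeedSets, dists: EffectiveDistances, params: EnergyParams) -> float:
    """Regional penalty R_i(label) — the first three penalties of the energy."""
    if label not in (TARGET, BACKGROUND):
        raise InvalidInputError(f"label must be {TARGET!r} or {BACKGROUND!r}, got {label!r}")
    K = params.hard_constraint_weight
    if K is None:
        raise ConfigurationError(
            "hard_constraint_weight is unresolved; use resolve_params() first"
        )
    index = tuple(index)
    seeded = seeds.label_of(index)
    if seeded is not None:
        return 0.0 if label == seeded else float(K)
    d_o = float(dists.to_target[index])
    d_b = float(dists.to_background[index])
    total = d_o + d_b
    if total == 0.0:
        return 0.5
    return (d_o if label == TARGET else d_b) / total


def _check_neighbors(i, j):
    i, j = tuple(i), tuple(j)
    diffs = [abs(a - b) for a, b in zip(i, j)]
    if len(i) != len(j) or max(diffs) != 1:
        raise ContractViolationError(f"{i} and {j} are not grid neighbors")


def boundary_penalty(i, j, field, params: EnergyParams, metric=None) -> float:
    """Boundary penalty W_ij = exp(-d(f_i, f_j)^2 / (2 sigma^2)) for neighbors i, j.

    Equals 1 for identical features (cutting homogeneous tissue is most
    expensive) and decays to 0 as the feature contrast grows.
    """
    _check_neighbors(i, j)
    sigma = params.sigma
    if sigma is None:
        raise ConfigurationError("sigma is unresolved; use resolve_params() first")
    feats, dist = field_features(field, metric if metric is not None else params.metric)
    d = dist(feats[tuple(i)], feats[tuple(j)])
    return float(np.exp(-(d * d) / (2.0 * sigma * sigma)))


# ---------------------------------------------------------------------------
# Neighborhood structure and parameter resolution
# ---------------------------------------------------------------------------


def neighbor_offsets(ndim: int, full_3d: bool = False):
    """Positive-direction neighbor offsets.

    2D: 8-neighborhood (4 offsets up to symmetry). 3D: in-slice 8-neighborhood
    per axial slice by default, or the 6-neighborhood when ``full_3d``.
    """
    if ndim == 2:
        return [(0, 1), (1, 0), (1, 1), (1, -1)]
    if ndim == 3:
        if full_3d:
            return [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        return [(0, 0, 1), (0, 1, 0), (0, 1, 1), (0, 1, -1)]
    raise InvalidInputError(f"only 2D and 3D grids are supported, got {ndim}D")


def neighbor_pairs(shape, mask, full_3d: bool = False):
    """All unordered in-mask neighbor pairs, in deterministic row-major order."""
    offsets = neighbor_offsets(len(shape), full_3d)
    pairs = []
    for i in map(tuple, np.argwhere(mask)):
        for off in offsets:
            j = tuple(a + b for a, b in zip(i, off))
            if all(0 <= c < s for c, s in zip(j, shape)) and mask[j]:
                pairs.append((i, j))
    return pairs


def resolve_params(field, seeds: SeedSets, params: EnergyParams, full_3d: bool = False):
    """Fill in data-adaptive sigma and the per-instance K.

    Returns ``(resolved_params, pairs, pair_weights, dists)`` where ``pairs``
    are in-mask neighbor pairs, ``pair_weights`` the boundary penalties W_ij,
    and ``dists`` the effective distances (None when there are no unknowns).
    """
    seeds.validate_for(field.shape, field.mask)
    feats, dist = field_features(field, params.metric)
    pairs = neighbor_pairs(field.shape, field.mask, full_3d)

    if pairs:
        if _is_flat(feats):
            fa = np.stack([feats[i] for i, _ in pairs])
            fb = np.stack([feats[j] for _, j in pairs])
            dvals = np.linalg.norm(fa - fb, axis=1)
        else:
            dvals = np.array([dist(feats[i], feats[j]) for i, j in pairs])
    else:
        dvals = np.zeros(0)

    sigma = params.sigma
    if sigma is None:
        mean_d = float(dvals.mean()) if dvals.size else 0.0
        sigma = mean_d if mean_d > 0 else 1.0

    weights = np.exp(-(dvals**2) / (2.0 * sigma * sigma)) if dvals.size else dvals

    K = params.hard_constraint_weight
    if K is None:
        incident = {}
        for (i, j), w in zip(pairs, weights):
            incident[i] = incident.get(i, 0.0) + w
            incident[j] = incident.get(j, 0.0) + w
        max_sum = max(incident.values()) if incident else 0.0
        K = (1.0 + (1.0 - params.alpha) * max_sum) / params.alpha

    resolved = replace(params, sigma=sigma, hard_constraint_weight=K)

    n_unknown = int(field.mask.sum()) - len(seeds.target) - len(seeds.background)
    dists = compute_effective_distances(field, seeds, params.metric) if n_unknown > 0 else None
    return resolved, pairs, weights, dists


# ---------------------------------------------------------------------------
# Total energy
# ---------------------------------------------------------------------------


def total_energy(labeling, field, seeds: SeedSets, params: EnergyParams, metric=None,
                 full_3d: bool = False, _resolved=None) -> float:
    """E(x) = alpha * regional + (1 - alpha) * boundary for a full labeling.

    ``labeling`` is a boolean grid (True = target). Labelings that violate a
    hard seed constraint are permitted — each violation simply scores K — so
    optimality probes can explore the full labeling space.
    """
    labeling = np.asarray(labeling, dtype=bool)
    if labeling.shape != field.shape:
        raise InvalidInputError(
            f"labeling shape {labeling.shape} != field shape {field.shape}"
        )
    if metric is not None:
        params = replace(params, metric=metric if isinstance(metric, str) else metric.name)
    if _resolved is None:
        resolved, pairs, weights, dists = resolve_params(field, seeds, params, full_3d)
    else:
        resolved, pairs, weights, dists = _resolved

    regional = 0.0
    for i in map(tuple, np.argwhere(field.mask)):
        label = TARGET if labeling[i] else BACKGROUND
        regional += regional_penalty(i, label, seeds, dists, resolved) if dists is not None \
            else _seed_only_penalty(i, label, seeds, resolved)

    boundary = 0.0
    for (i, j), w in zip(pairs, weights):
        if labeling[i] != labeling[j]:
            boundary += w

    return float(resolved.alpha * regional + (1.0 - resolved.alpha) * boundary)


def _seed_only_penalty(index, label, seeds, params):
    seeded = seeds.label_of(index)
    if seeded is None:  # unreachable when all voxels are seeded
        return 0.5
    return 0.0 if label == seeded else float(params.hard_constraint_weight)
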