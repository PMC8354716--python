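"""Gaussian age kernel and kernel-weighted averaging.

The age kernel assigns every participant a weight that decays with the
distance between their (baseline) age and a target age ``t``:

    w(t_i, t) = 1/(sigma*sqrt(2*pi)) * exp(-(t_i - t)^2 / (2*sigma^2))

Sliding ``t`` across the sample's age range and forming the weighted mean
of per-participant quantities (voxel activation maps or scalar behavioral
scores) yields an age-specific "template" per target year -- a compromise
between a grand mean (no age specificity) and single participants (maximal
noise). The normalising constant cancels in the weighted mean and is kept
only for fidelity to the usual Gaussian density form; no code may depend
on it.

All participants contribute at every target age (no truncation); tails of
the age distribution are merely down-weighted. Near the extremes of the
sampled range the weighted mean draws on one-sided support, a known
boundary bias that division by the weight sum does not remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "KernelSpec",
    "KernelWeights",
    "ActivationMatrix",
    "AgeWeightedSeries",
    "gaussian_weights",
    "weighted_average",
    "weighted_series",
    "weighted_scalar_series",
]

DEFAULT_SIGMA = 4.0
DEFAULT_TARGET_AGES = tuple(range(20, 81))


@dataclass(frozen=True)
class KernelSpec:
    """Kernel width and the ordered target ages it slides over.

    Parameters
    ----------
    sigma : float
        Kernel SD in years. Default 4; widths between 3 and 5 give similar
        templates on smooth trajectories.
    target_ages : tuple of int
        Strictly increasing target ages in years. Default 20..80 inclusive
        (61 ages).
    """

    sigma: float = DEFAULT_SIGMA
    target_ages: tuple = DEFAULT_TARGET_AGES

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        ages = np.asarray(self.target_ages)
        if ages.size == 0:
            raise ValueError("target_ages must be nonempty")
        if ages.size > 1 and not np.all(np.diff(ages) > 0):
            raise ValueError("target_ages must be strictly increasing")
        object.__setattr__(self, "target_ages", tuple(int(a) for a in ages))

    @property
    def ages_array(self) -> np.ndarray:
        return np.asarray(self.target_ages, dtype=float)


@dataclass(frozen=True)
class KernelWeights:
    """Per-participant Gaussian weights for one target age."""

    target_age: float
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        # mathematically all weights are > 0; in float64 a weight may
        # underflow to exact 0 beyond ~38 sigma, which is harmless because
        # the weight *sum* is dominated by the nearest participants
        if not np.all(np.isfinite(w)) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("kernel weights must be finite, nonnegative, with a positive sum")
        object.__setattr__(self, "weights", w)


@dataclass
class ActivationMatrix:
    """Participants x masked-voxels matrix of activation (beta) values.

    ``voxel_index`` maps columns to linear indices into the gray-matter
    mask grid (Fortran order: first/x axis fastest); the column order must
    be identical across every matrix used in one analysis.
    """

    values: np.ndarray
    participant_ids: np.ndarray
    voxel_index: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (participants x voxels)")
        self.participant_ids = np.asarray(self.participant_ids)
        if self.participant_ids.shape[0] != self.values.shape[0]:
            raise ValueError("participant_ids length must match row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activation values must be finite")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class AgeWeightedSeries:
    """Kernel-weighted values indexed by target age.

    ``values`` is (n_target_ages, n_voxels) for map series, or 1-D of
    length n_target_ages for scalar (behavioral) series.
    """

    target_ages: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.target_ages = np.asarray(self.target_ages)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.target_ages.shape[0]:
            raise ValueError("one value row per target age required")

    @property
    def n_ages(self) -> int:
        return self.target_ages.shape[0]


def gaussian_weights(participant_ages, target_age: float, sigma: float = DEFAULT_SIGMA) -> KernelWeights:
    """Gaussian kernel weights for every participant at one target age.

    w_i = 1/(sigma*sqrt(2*pi)) * exp(-(t_i - t)^2 / (2*sigma^2)); weights
    depend only on |t_i - t| and are strictly positive for all finite ages.
    """
    ages = np.asarray(participant_ages, dtype=float)
    if ages.size == 0:
        raise ValueError("participant_ages must be nonempty")
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    w = norm.pdf(ages, loc=float(target_age), scale=float(sigma))
    return KernelWeights(target_age=float(target_age), weights=w)


def _values_of(matrix) -> np.ndarray:
    if isinstance(matrix, ActivationMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def weighted_average(matrix, weights: KernelWeights) -> np.ndarray:
    """Kernel-weighted mean across participants: sum_i w_i*x_i / sum_i w_i.

    A convex combination of the rows, so every voxel of the result lies in
    the per-voxel range of the inputs.
    """
    x = _values_of(matrix)
    w = weights.weights if isinstance(weights, KernelWeights) else np.asarray(weights, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("cannot average zero participants")
    if w.shape[0] != x.shape[0]:
        raise ValueError(f"weight count {w.shape[0]} != participant count {x.shape[0]}")
    return np.average(x, axis=0, weights=w)


def _weight_matrix(participant_ages: np.ndarray, target_ages: np.ndarray, sigma: float) -> np.ndarray:
    # (n_targets, n_participants); rows never all-underflow for sigma >= 1
    # over a 60-year span (exp(-60^2/2) is ~1e-391 but the nearest
    # participants dominate and float64 holds exp(-|d|^2/2s^2) down to
    # |d|/s ~ 38, far beyond any human age span at sigma >= 1).
    return norm.pdf(
        participant_ages[None, :], loc=np.asarray(target_ages, dtype=float)[:, None], scale=sigma
    )


def weighted_series(matrix, ages, spec: KernelSpec = KernelSpec()) -> AgeWeightedSeries:
    """One kernel-weighted map per target age (61 under defaults)."""
    x = _values_of(matrix)
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != x.shape[0]:
        raise ValueError("ages must align with matrix rows")
    if x.shape[0] == 0:
        raise ValueError("cannot build a weighted series from zero participants")
    w = _weight_matrix(ages, spec.ages_array, spec.sigma)
    values = (w @ x) / w.sum(axis=1, keepdims=True)
    return AgeWeightedSeries(target_ages=spec.ages_array.astype(int), values=values)


def weighted_scalar_series(values, ages, spec: KernelSpec = KernelSpec()) -> AgeWeightedSeries:
    """Kernel-weighted series of a per-participant scalar (e.g. a domain
    performance score); identical to :func:`weighted_series` with a single
    'voxel'."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("scalar series expects a 1-D per-participant vector")
    series = weighted_series(v[:, None], ages, spec)
    return AgeWeightedSeries(target_ages=series.target_ages, values=series.values[:, 0])
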