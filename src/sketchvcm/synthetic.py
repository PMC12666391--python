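"""Synthetic data with the generative structure of the simulation study.

Locations are drawn uniformly on the unit hypercube, the varying-coefficient
surfaces are mean-zero Gaussian-process fields with exponential covariance,
predictors are an intercept plus standard-normal columns, and the response adds
iid Gaussian noise.  Every draw is reproducible from a single master seed;
locations, predictors, coefficient fields and noise use independent child
streams so each component can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "GPKernelSpec",
    "SimulationConfig",
    "VCMDataset",
    "exponential_kernel",
    "kernel_matrix",
    "draw_gp_field",
    "simulate_dataset",
]

#: relative jitter added to the kernel diagonal before factorisation
JITTER = 1e-8


@dataclass(frozen=True)
class GPKernelSpec:
    """Exponential covariance kernel ``C(u, v) = variance * exp(-||u-v|| / (2 range))``.

    Parameters
    ----------
    variance : float
        Marginal variance (delta^2), strictly positive.
    range : float
        Range parameter (phi) in domain-distance units, strictly positive.
        Larger values give smoother, longer-range fields.
    """

    variance: float
    range: float

    def __post_init__(self) -> None:
        if not (self.variance > 0):
            raise ValueError(f"kernel variance must be > 0, got {self.variance}")
        if not (self.range > 0):
            raise ValueError(f"kernel range must be > 0, got {self.range}")


# True kernel/noise settings of the reference simulation design: three
# varying coefficients with delta^2 = (1, 0.8, 1.1), phi = (1, 1.25, 2),
# noise variance 0.1.
DEFAULT_KERNELS = (
    GPKernelSpec(1.0, 1.0),
    GPKernelSpec(0.8, 1.25),
    GPKernelSpec(1.1, 2.0),
)
DEFAULT_NOISE_VARIANCE = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration for one simulated varying-coefficient dataset."""

    n_locations: int
    kernels: Sequence[GPKernelSpec] = DEFAULT_KERNELS
    noise_variance: float = DEFAULT_NOISE_VARIANCE
    n_dim: int = 2
    seed: int = 0
    n_holdout: int = 500

    def __post_init__(self) -> None:
        if self.n_locations < 1:
            raise ValueError("n_locations must be >= 1")
        if len(self.kernels) < 1:
            raise ValueError("need at least one varying coefficient kernel")
        if not (self.noise_variance > 0):
            raise ValueError("noise_variance must be > 0")
        if self.n_dim not in (1, 2):
            raise ValueError("only d=1 and d=2 domains are supported")
        if self.n_holdout < 0:
            raise ValueError("n_holdout must be >= 0")

    @property
    def n_varying(self) -> int:
        return len(self.kernels)


@dataclass
class VCMDataset:
    """Point-referenced varying-coefficient regression data.

    Attributes
    ----------
    locations : (N, d) array
        Index coordinates in the domain.
    X : (N, P) array
        Predictor values; column order fixed.
    varying_index : (Ptilde,) int array
        Which columns of ``X`` have varying coefficients.
    y : (N,) array
        Responses.
    truth : (N, Ptilde) array, optional
        True varying-coefficient values at the observed locations
        (simulation mode only).
    noise_variance : float, optional
        True noise variance used to generate ``y`` (simulation mode only).
    holdout : VCMDataset, optional
        Disjoint holdout set generated from the same law.
    """

    locations: np.ndarray
    X: np.ndarray
    varying_index: np.ndarray
    y: np.ndarray
    truth: Optional[np.ndarray] = None
    noise_variance: Optional[float] = None
    holdout: Optional["VCMDataset"] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.varying_index = np.asarray(self.varying_index, dtype=int).ravel()
        n = self.locations.shape[0]
        if self.X.shape[0] != n or self.y.shape[0] != n:
            raise ValueError(
                f"row mismatch: locations {n}, X {self.X.shape[0]}, y {self.y.shape[0]}"
            )
        P = self.X.shape[1]
        if len(np.unique(self.varying_index)) != len(self.varying_index):
            raise ValueError("varying_index entries must be distinct")
        if self.varying_index.size and (
            self.varying_index.min() < 0 or self.varying_index.max() >= P
        ):
            raise ValueError("varying_index out of range")
        if self.truth is not None:
            self.truth = np.atleast_2d(np.asarray(self.truth, dtype=float))
            if self.truth.shape != (n, len(self.varying_index)):
                raise ValueError("truth must be (N, Ptilde)")

    @property
    def n(self) -> int:
        return self.locations.shape[0]

    @property
    def n_dim(self) -> int:
        return self.locations.shape[1]

    @property
    def X_varying(self) -> np.ndarray:
        """The (N, Ptilde) submatrix of predictors with varying coefficients."""
        return self.X[:, self.varying_index]


def exponential_kernel(u, v, spec: GPKernelSpec) -> float:
    """Exponential covariance between two coordinates.

    ``C(u, v) = variance * exp(-||u - v|| / (2 * range))``; symmetric in
    its arguments and equal to ``variance`` at zero distance.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"coordinate dimensions differ: {u.shape} vs {v.shape}")
    dist = float(np.linalg.norm(u - v))
    return spec.variance * np.exp(-dist / (2.0 * spec.range))


def kernel_matrix(locations, spec: GPKernelSpec, other=None) -> np.ndarray:
    """Covariance matrix of the exponential kernel over location sets."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    other_ = locations if other is None else np.atleast_2d(np.asarray(other, dtype=float))
    D = cdist(locations, other_)
    # in place: the matrix is O(N^2) and simulation-side N can be large
    D *= -1.0 / (2.0 * spec.range)
    np.exp(D, out=D)
    D *= spec.variance
    return D


def _chol_with_jitter(K: np.ndarray, variance: float) -> np.ndarray:
    jitter = JITTER * variance
    for _ in range(4):
        try:
            return np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise np.linalg.LinAlgError(
        "kernel matrix not positive definite even after jitter "
        f"(final jitter {jitter:.2e}); check for duplicate locations at scale"
    )


def draw_gp_field(locations, spec: GPKernelSpec, seed) -> np.ndarray:
    """One draw of a mean-zero Gaussian field with exponential covariance.

    ``seed`` may be an int, ``SeedSequence`` or ``Generator``.  The field is
    drawn exactly (dense Cholesky of the N x N covariance), so this is a
    simulation-side tool for moderate N, not a model component.
    """
    rng = np.random.default_rng(seed)
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    K = kernel_matrix(locations, spec)
    L = _chol_with_jitter(K, spec.variance)
    return L @ rng.standard_normal(locations.shape[0])


def simulate_dataset(config: SimulationConfig) -> VCMDataset:
    """Simulate one dataset (plus disjoint holdout) from the reference design.

    Locations are iid uniform on ``[0,1]^d``; the first varying predictor is
    the intercept (identically 1) and the remaining ones are iid N(0,1); the
    coefficient surfaces are GP fields drawn jointly over training and holdout
    locations; ``y | fields`` is Gaussian with variance ``noise_variance``.

    Returns the training :class:`VCMDataset` with the holdout attached as
    ``.holdout`` and the true surfaces stored in ``.truth``.
    """
    cfg = config
    n_total = cfg.n_locations + cfg.n_holdout
    ss = np.random.SeedSequence(cfg.seed)
    s_loc, s_pred, s_field, s_noise = ss.spawn(4)

    locations = np.random.default_rng(s_loc).uniform(size=(n_total, cfg.n_dim))

    Ptilde = cfg.n_varying
    X = np.empty((n_total, Ptilde))
    X[:, 0] = 1.0  # intercept carries the varying "mean surface"
    if Ptilde > 1:
        X[:, 1:] = np.random.default_rng(s_pred).standard_normal((n_total, Ptilde - 1))

    # joint draw over training + holdout so the holdout truth is coherent
    field_streams = s_field.spawn(Ptilde)
    W = np.column_stack(
        [
            draw_gp_field(locations, k, np.random.default_rng(st))
            for k, st in zip(cfg.kernels, field_streams)
        ]
    )

    mean = np.einsum("nj,nj->n", X, W)
    y = mean + np.sqrt(cfg.noise_variance) * np.random.default_rng(
        s_noise
    ).standard_normal(n_total)

    varying_index = np.arange(Ptilde)
    n = cfg.n_locations
    holdout = None
    if cfg.n_holdout:
        holdout = VCMDataset(
            locations[n:], X[n:], varying_index, y[n:],
            truth=W[n:], noise_variance=cfg.noise_variance,
        )
    return VCMDataset(
        locations[:n], X[:n], varying_index, y[:n],
        truth=W[:n], noise_variance=cfg.noise_variance, holdout=holdout,
    )
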