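"""Tensor-product B-spline bases for the varying coefficients.

Each varying coefficient w_j(u) is expanded as B(u)^T gamma_j, where B(u) is a
tensor product of clamped marginal B-splines of order q (default 4, cubic) on
equally spaced knots.  The same basis is shared by all varying coefficients.
The design matrix Z has row n equal to the concatenation over j of
x_j(u_n) * B(u_n), i.e. the N x (H Ptilde) realisation of the block product
without materialising the N x (N Ptilde) block-diagonal predictor matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import BSpline

from .synthetic import VCMDataset

__all__ = [
    "TensorBasisSpec",
    "BasisDesign",
    "make_knots",
    "eval_basis",
    "assemble_design",
    "reconstruct_coefficient",
    "domain_from_locations",
]

#: tolerance for clamping numerically exterior points to the domain boundary
BOUNDARY_TOL = 1e-10


@dataclass(frozen=True)
class TensorBasisSpec:
    """Specification of a tensor-product B-spline basis.

    Parameters
    ----------
    n_basis : tuple of int
        Number of basis functions per dimension (H_1, ..., H_d); the total
        basis size is H = prod(H_k).  Each H_k must be >= order.
    domain : tuple of (low, high)
        Domain bounds per dimension.
    order : int
        Spline order q (degree + 1); q = 4 gives cubic splines.
    """

    n_basis: Tuple[int, ...]
    domain: Tuple[Tuple[float, float], ...] = ((0.0, 1.0), (0.0, 1.0))
    order: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_basis", tuple(int(h) for h in np.atleast_1d(self.n_basis)))
        dom = tuple((float(a), float(b)) for a, b in self.domain)
        object.__setattr__(self, "domain", dom)
        if len(dom) != len(self.n_basis):
            raise ValueError("domain and n_basis must have the same length")
        if self.order < 1:
            raise ValueError("spline order must be >= 1")
        for h in self.n_basis:
            if h < self.order:
                raise ValueError(f"need n_basis >= order per dimension, got {h} < {self.order}")
        for a, b in dom:
            if not b > a:
                raise ValueError(f"empty domain interval ({a}, {b})")

    @property
    def n_dim(self) -> int:
        return len(self.n_basis)

    @property
    def H(self) -> int:
        """Total number of tensor-product basis functions."""
        return int(np.prod(self.n_basis))

    def to_dict(self) -> dict:
        return {
            "n_basis": list(self.n_basis),
            "domain": [list(d) for d in self.domain],
            "order": self.order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TensorBasisSpec":
        return cls(
            n_basis=tuple(d["n_basis"]),
            domain=tuple(tuple(x) for x in d["domain"]),
            order=int(d["order"]),
        )


def make_knots(spec: TensorBasisSpec) -> list[np.ndarray]:
    """Clamped, equally spaced knot vector for each dimension.

    Boundary knots are repeated ``order`` times; the H_k - order interior
    knots are equally spaced, so the basis count per dimension is exactly H_k.
    """
    knots = []
    q = spec.order
    for h, (lo, hi) in zip(spec.n_basis, spec.domain):
        n_int = h - q
        interior = lo + (hi - lo) * np.arange(1, n_int + 1) / (n_int + 1)
        knots.append(np.r_[[lo] * q, interior, [hi] * q])
    return knots


def _clamp(points: np.ndarray, spec: TensorBasisSpec) -> np.ndarray:
    out = np.array(points, dtype=float, copy=True)
    for k, (lo, hi) in enumerate(spec.domain):
        col = out[:, k]
        scale = max(abs(lo), abs(hi), 1.0)
        tol = BOUNDARY_TOL * scale
        bad = (col < lo - tol) | (col > hi + tol)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"coordinate {k} of point {i} ({col[i]!r}) lies outside the "
                f"basis domain [{lo}, {hi}]"
            )
        np.clip(col, lo, hi, out=col)
    return out


def eval_basis(points, spec: TensorBasisSpec) -> np.ndarray:
    """Evaluate all H tensor-product basis functions at one or more points.

    Returns an (n, H) array (or (H,) for a single point).  Tensor index
    ordering is row-major over (h_1, ..., h_d): for d=2,
    h = (h_1 - 1) * H_2 + h_2.  Entries are in [0, 1] and each row sums to 1
    (partition of unity of clamped B-splines).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    single = np.asarray(points).ndim == 1
    if pts.shape[1] != spec.n_dim:
        raise ValueError(f"points have dimension {pts.shape[1]}, basis expects {spec.n_dim}")
    pts = _clamp(pts, spec)
    knots = make_knots(spec)
    deg = spec.order - 1
    marg = [
        BSpline.design_matrix(pts[:, k], knots[k], deg, extrapolate=False).toarray()
        for k in range(spec.n_dim)
    ]
    B = marg[0]
    for Mk in marg[1:]:
        B = (B[:, :, None] * Mk[:, None, :]).reshape(pts.shape[0], -1)
    return B[0] if single else B


@dataclass
class BasisDesign:
    """Assembled varying-coefficient design Z = "X-tilde B" and its evaluator."""

    spec: TensorBasisSpec
    Z: np.ndarray
    varying_index: np.ndarray

    @property
    def n_varying(self) -> int:
        return len(self.varying_index)

    def evaluate(self, locations) -> np.ndarray:
        """Basis-evaluation matrix at new locations, (n, H)."""
        return eval_basis(locations, self.spec)


def assemble_design(data: VCMDataset, spec: TensorBasisSpec) -> BasisDesign:
    """Build the N x (H Ptilde) varying-coefficient design matrix.

    Column block j equals the basis-evaluation matrix scaled rowwise by the
    j-th varying predictor, which realises the block-diagonal product
    directly without forming the N x (N Ptilde) factor.
    """
    if data.n_dim != spec.n_dim:
        raise ValueError(
            f"location dimension {data.n_dim} does not match basis dimension {spec.n_dim}"
        )
    B = eval_basis(data.locations, spec)
    H = spec.H
    Xv = data.X_varying
    Z = np.empty((data.n, H * Xv.shape[1]))
    for j in range(Xv.shape[1]):
        Z[:, j * H : (j + 1) * H] = Xv[:, [j]] * B
    return BasisDesign(spec=spec, Z=Z, varying_index=data.varying_index.copy())


def reconstruct_coefficient(gamma_j, locations, spec: TensorBasisSpec) -> np.ndarray:
    """Varying-coefficient surface w_j(u) = B(u)^T gamma_j at requested locations."""
    gamma_j = np.asarray(gamma_j, dtype=float).ravel()
    if gamma_j.shape[0] != spec.H:
        raise ValueError(f"gamma has length {gamma_j.shape[0]}, basis has H={spec.H}")
    return np.atleast_2d(eval_basis(locations, spec)) @ gamma_j


def domain_from_locations(locations, pad: float = 0.001) -> Tuple[Tuple[float, float], ...]:
    """Domain bounds derived from observed coordinates, padded by a relative margin."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    out = []
    for k in range(locations.shape[1]):
        lo, hi = float(locations[:, k].min()), float(locations[:, k].max())
        width = (hi - lo) or 1.0
        out.append((lo - pad * width, hi + pad * width))
    return tuple(out)
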