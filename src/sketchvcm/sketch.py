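"""Data-oblivious Gaussian sketching.

The compression matrix Phi is M x N with entries iid N(0, 1/N), drawn once
from a recorded seed and never stored: only (M, N, seed) are persisted, and
regenerating Phi from them reproduces every compressed quantity bit-for-bit.
Products Phi @ A are accumulated over fixed-width column blocks so that large
N never requires the dense M x N matrix in memory; the block scheme is part of
the determinism contract (the generator stream is consumed in the same order
whether or not the full matrix is materialised).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .basis import BasisDesign
from .synthetic import VCMDataset

__all__ = [
    "SketchSpec",
    "SketchOutput",
    "default_M",
    "make_sketch",
    "apply_sketch",
    "compress",
    "identity_sketch",
    "spectrum_check",
]

#: column-block width used when generating Phi (fixed: part of reproducibility)
CHUNK = 2048


@dataclass(frozen=True)
class SketchSpec:
    """Shape and seed of a Gaussian compression matrix."""

    M: int
    N: int
    seed: int

    def __post_init__(self) -> None:
        if not (1 <= self.M <= self.N):
            raise ValueError(f"need 1 <= M <= N, got M={self.M}, N={self.N}")


def default_M(N: int) -> int:
    """Default compressed size: ceil(10 sqrt(N)), capped at N.

    The 10 sqrt(N) scaling is the empirically effective choice from the
    compression-size study; e.g. N=10000 gives M=1000.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return min(N, int(np.ceil(10.0 * np.sqrt(N))))


def _blocks(spec: SketchSpec) -> Iterable[tuple[slice, np.ndarray]]:
    rng = np.random.default_rng(spec.seed)
    scale = 1.0 / np.sqrt(spec.N)
    for start in range(0, spec.N, CHUNK):
        stop = min(start + CHUNK, spec.N)
        yield slice(start, stop), scale * rng.standard_normal((spec.M, stop - start))


def make_sketch(spec: SketchSpec) -> np.ndarray:
    """Materialise the full M x N compression matrix (small-N / testing use)."""
    Phi = np.empty((spec.M, spec.N))
    for sl, block in _blocks(spec):
        Phi[:, sl] = block
    return Phi


def apply_sketch(spec: SketchSpec, *arrays: np.ndarray) -> list[np.ndarray]:
    """Compute Phi @ A for each array without holding Phi in memory.

    Each array must have N rows; 1-d arrays are treated as column vectors and
    returned 1-d.
    """
    prepped = []
    for A in arrays:
        A = np.asarray(A, dtype=float)
        if A.shape[0] != spec.N:
            raise ValueError(f"array has {A.shape[0]} rows, sketch expects N={spec.N}")
        prepped.append(A)
    outs = [
        np.zeros((spec.M,) + A.shape[1:]) for A in prepped
    ]
    for sl, block in _blocks(spec):
        for A, out in zip(prepped, outs):
            out += block @ A[sl]
    return outs


@dataclass
class SketchOutput:
    """Compressed data {y_Phi, X_Phi, Z_Phi} plus the spec that regenerates Phi.

    ``spec`` is None for the uncompressed (identity) path, in which case the
    fields are the original arrays and M = N.
    """

    y_phi: np.ndarray
    X_phi: np.ndarray
    Z_phi: np.ndarray
    spec: Optional[SketchSpec]
    n_varying: int
    H: int

    def __post_init__(self) -> None:
        M = self.y_phi.shape[0]
        if self.X_phi.shape[0] != M or self.Z_phi.shape[0] != M:
            raise ValueError("compressed arrays have inconsistent row counts")
        if self.Z_phi.shape[1] != self.H * self.n_varying:
            raise ValueError("Z_phi width does not equal H * n_varying")

    @property
    def M(self) -> int:
        return self.y_phi.shape[0]


def compress(data: VCMDataset, basis_design: BasisDesign, spec: SketchSpec) -> SketchOutput:
    """Apply the Gaussian sketch to y, X and the assembled design Z.

    Z_Phi = Phi Z equals the compressed block product since Z already realises
    the basis expansion; the original data are not retained in the output.
    """
    if spec.N != data.n:
        raise ValueError(f"sketch N={spec.N} does not match data rows {data.n}")
    if basis_design.Z.shape[0] != data.n:
        raise ValueError("basis design rows do not match data rows")
    y_phi, X_phi, Z_phi = apply_sketch(spec, data.y, data.X, basis_design.Z)
    return SketchOutput(
        y_phi=y_phi, X_phi=X_phi, Z_phi=Z_phi, spec=spec,
        n_varying=basis_design.n_varying, H=basis_design.spec.H,
    )


def identity_sketch(data: VCMDataset, basis_design: BasisDesign) -> SketchOutput:
    """Uncompressed path: the full-data model with M = N (identity 'sketch')."""
    return SketchOutput(
        y_phi=data.y.copy(), X_phi=data.X.copy(), Z_phi=basis_design.Z,
        spec=None, n_varying=basis_design.n_varying, H=basis_design.spec.H,
    )


def spectrum_check(spec: SketchSpec, widen: float = 0.1) -> dict:
    """Eigenvalue diagnostics of Phi Phi^T against the asymptotic band.

    For M = o(N) the eigenvalues of Phi Phi^T concentrate in
    [(1 - sqrt(M/N))^2, (1 + sqrt(M/N))^2]; the reported band is widened on
    each side by ``widen`` times the band width.  Also reports the Frobenius
    norm of Phi Phi^T - I, which should be of order M / sqrt(N).
    """
    Phi = make_sketch(spec)
    G = Phi @ Phi.T
    eig = np.linalg.eigvalsh(G)
    r = np.sqrt(spec.M / spec.N)
    lo, hi = (1.0 - r) ** 2, (1.0 + r) ** 2
    width = hi - lo
    band = (lo - widen * width, hi + widen * width)
    fro = float(np.linalg.norm(G - np.eye(spec.M), "fro"))
    return {
        "emin": float(eig[0]),
        "emax": float(eig[-1]),
        "band": band,
        "in_band": bool(eig[0] >= band[0] and eig[-1] <= band[1]),
        "frobenius_dev": fro,
        "frobenius_scale": spec.M / np.sqrt(spec.N),
    }
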