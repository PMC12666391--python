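"""Tabular input/output, run manifests and reproducibility plumbing.

All tabular IO is plain delimited text with a header row.  Every ``fit`` run
writes a manifest (JSON) holding the config snapshot, all seeds, the basis
spec and a fingerprint of the input data; together with the input table it
reproduces the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .basis import TensorBasisSpec
from .sampler import PosteriorDraws
from .synthetic import VCMDataset

__all__ = [
    "RunManifest",
    "read_dataset",
    "write_dataset",
    "write_draws",
    "read_draws",
    "write_report",
    "data_fingerprint",
]


def data_fingerprint(df: pd.DataFrame) -> dict:
    h = hashlib.sha256()
    for col in df.columns:
        h.update(str(col).encode())
        h.update(np.ascontiguousarray(df[col].to_numpy(dtype=float)).tobytes())
    return {"n_rows": int(len(df)), "sha256": h.hexdigest()}


@dataclass
class RunManifest:
    """Everything needed to reproduce a fit given the input table."""

    config: dict
    seeds: dict
    basis_spec: dict
    fingerprint: dict
    version: str

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def read_dataset(path, coord_cols: Sequence[str], response_col: Optional[str],
                 predictor_cols: Sequence[str], varying_cols: Sequence[str],
                 add_intercept: bool = True, sep: str = "\t") -> VCMDataset:
    """Read a delimited text table into a validated :class:`VCMDataset`.

    ``varying_cols`` names the subset of ``predictor_cols`` with varying
    coefficients; the intercept (if added) is prepended and always varying.
    ``response_col`` may be None for prediction-input tables (y filled with 0).
    """
    df = pd.read_csv(path, sep=sep)
    needed = list(coord_cols) + list(predictor_cols) + (
        [response_col] if response_col else [])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) in {path}: {missing}")
    bad = [c for c in varying_cols if c not in predictor_cols]
    if bad:
        raise ValueError(f"varying column(s) not among predictors: {bad}")
    sub = df[needed].apply(pd.to_numeric, errors="coerce")
    nan_rows = sub.index[sub.isna().any(axis=1)].tolist()
    if nan_rows:
        raise ValueError(
            f"non-numeric or missing values in rows {nan_rows[:10]}"
            + ("..." if len(nan_rows) > 10 else "")
        )
    locs = sub[list(coord_cols)].to_numpy()
    X = sub[list(predictor_cols)].to_numpy()
    names = list(predictor_cols)
    if add_intercept:
        X = np.column_stack([np.ones(len(df)), X])
        names = ["(intercept)"] + names
        vidx = [0] + [names.index(c) for c in varying_cols]
    else:
        vidx = [names.index(c) for c in varying_cols]
    y = sub[response_col].to_numpy() if response_col else np.zeros(len(df))
    return VCMDataset(locations=locs, X=X, varying_index=np.array(vidx), y=y)


def write_dataset(path, data: VCMDataset, sep: str = "\t",
                  include_truth: bool = True) -> None:
    """Write a dataset as delimited text: u1..ud, x1..xP, y [, w_true_j]."""
    cols = {f"u{k + 1}": data.locations[:, k] for k in range(data.n_dim)}
    for p in range(data.X.shape[1]):
        cols[f"x{p + 1}"] = data.X[:, p]
    cols["y"] = data.y
    if include_truth and data.truth is not None:
        for j in range(data.truth.shape[1]):
            cols[f"w_true_{j + 1}"] = data.truth[:, j]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def write_draws(path, draws: PosteriorDraws, sep: str = "\t") -> None:
    """Retained draws as one delimited text table; deterministic column order."""
    cols = {}
    for p in range(draws.beta.shape[1]):
        cols[f"beta_{p + 1}"] = draws.beta[:, p]
    cols["sigma2"] = draws.sigma2
    for j in range(draws.tau2.shape[1]):
        cols[f"tau2_{j + 1}"] = draws.tau2[:, j]
    for i in range(draws.gamma.shape[1]):
        cols[f"gamma_{i + 1}"] = draws.gamma[:, i]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_draws(path, H: int, n_varying: int, *, n_iter: int, burn_in: int,
               thin: int = 1, sep: str = "\t") -> PosteriorDraws:
    df = pd.read_csv(path, sep=sep)
    beta = df[[c for c in df.columns if c.startswith("beta_")]].to_numpy()
    tau2 = df[[c for c in df.columns if c.startswith("tau2_")]].to_numpy()
    gamma = df[[c for c in df.columns if c.startswith("gamma_")]].to_numpy()
    return PosteriorDraws(
        beta=beta, gamma=gamma, sigma2=df["sigma2"].to_numpy(), tau2=tau2,
        n_iter=n_iter, burn_in=burn_in, thin=thin, seed=None,
        sampler="loaded", H=H, n_varying=n_varying,
    )


def write_report(path, report, sep: str = "\t") -> None:
    """MetricsReport -> two text files: per-replicate table and summary."""
    path = Path(path)
    report.replicates.to_csv(path, sep=sep, index=False)
    summary = report.summary()
    summary.insert(0, "metric", summary.index)
    summary.to_csv(path.with_suffix(".summary" + path.suffix), sep=sep, index=False)
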