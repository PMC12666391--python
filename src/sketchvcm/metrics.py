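"""Posterior-predictive inference and the simulation-study evaluation metrics.

Prediction at new locations uses composition sampling: for every retained
posterior draw (beta, gamma, sigma2), reconstruct each varying coefficient
w_j(u0) = B(u0)^T gamma_j, then draw y(u0) from
N(x(u0)^T beta + sum_j x_j(u0) w_j(u0), sigma2).  Point prediction is the
posterior-predictive median; intervals are equal-tailed, from the 2.5% and
97.5% sample quantiles.

Metrics mirror the simulation-study definitions: MSE(SVC) is the average
squared error of posterior-median coefficient surfaces against the stored
truth; CI coverage/length are evaluated at the training locations; MSPE and
PI coverage/length on a disjoint holdout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .basis import TensorBasisSpec, assemble_design, eval_basis
from .sampler import PosteriorDraws, PriorSpec, run_mcmc
from .sketch import SketchSpec, compress, identity_sketch
from .synthetic import DEFAULT_KERNELS, SimulationConfig, VCMDataset

__all__ = [
    "PredictiveDraws",
    "MetricsReport",
    "ExperimentScenario",
    "predict",
    "coefficient_summaries",
    "mse_svc",
    "interval_metrics",
    "mspe",
    "evaluate_fit",
    "run_experiment",
]

#: minimum number of draws for quantile-based intervals
MIN_DRAWS = 40


@dataclass
class PredictiveDraws:
    """Composition-sampled posterior-predictive draws at new locations."""

    y_draws: np.ndarray       # (n0, L) includes observation noise
    mean_draws: np.ndarray    # (n0, L) latent mean surface draws
    w_summaries: np.ndarray   # (Ptilde, n0, 3): median, 2.5%, 97.5%

    @property
    def median(self) -> np.ndarray:
        return np.median(self.y_draws, axis=1)

    @property
    def mean(self) -> np.ndarray:
        return self.y_draws.mean(axis=1)

    def interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        a = 0.5 * (1.0 - level)
        return (np.quantile(self.y_draws, a, axis=1),
                np.quantile(self.y_draws, 1.0 - a, axis=1))


def predict(draws: PosteriorDraws, new_locations, new_X, varying_index,
            basis_spec: TensorBasisSpec, seed=None,
            noise: bool = True) -> PredictiveDraws:
    """Composition sampling of the posterior predictive at new locations.

    ``new_X`` is the (n0, P) predictor matrix at the new locations (same
    column order as the fit); ``varying_index`` selects the varying columns.
    With ``noise=False`` the y draws are the latent mean surface (test hook
    for a degenerate observation model).
    """
    locs = np.atleast_2d(np.asarray(new_locations, dtype=float))
    X0 = np.atleast_2d(np.asarray(new_X, dtype=float))
    varying_index = np.asarray(varying_index, dtype=int).ravel()
    if X0.shape[0] != locs.shape[0]:
        raise ValueError("new_X rows do not match new_locations")
    if basis_spec.H != draws.H:
        raise ValueError(
            f"basis spec (H={basis_spec.H}) does not match fit (H={draws.H})"
        )
    B0 = eval_basis(locs, basis_spec)            # (n0, H)
    n0, L = locs.shape[0], draws.n_retained
    Pt = draws.n_varying

    mean = X0 @ draws.beta.T                      # (n0, L)
    w_summ = np.empty((Pt, n0, 3))
    for j in range(Pt):
        Wj = B0 @ draws.gamma_block(j).T          # (n0, L)
        # the summarised coefficient surface is the total effect of the
        # predictor, beta_j + w_j(u); the mean below adds the static part
        # through X0 @ beta already
        Wtot = Wj + draws.beta[None, :, varying_index[j]]
        w_summ[j, :, 0] = np.median(Wtot, axis=1)
        w_summ[j, :, 1] = np.quantile(Wtot, 0.025, axis=1)
        w_summ[j, :, 2] = np.quantile(Wtot, 0.975, axis=1)
        mean += X0[:, [varying_index[j]]] * Wj
    y = mean
    if noise:
        rng = np.random.default_rng(seed)
        y = mean + np.sqrt(draws.sigma2)[None, :] * rng.standard_normal((n0, L))
    return PredictiveDraws(y_draws=y, mean_draws=mean, w_summaries=w_summ)


def coefficient_summaries(draws: PosteriorDraws, locations,
                          basis_spec: TensorBasisSpec,
                          varying_index=None, include_static: bool = True,
                          chunk: int = 2000) -> np.ndarray:
    """Posterior median and 95% bounds of each varying coefficient.

    Since a predictor with a varying coefficient appears both in the static
    term x^T beta and in the varying term, the coefficient surface of
    predictor j is beta_j + w_j(u); ``include_static=False`` summarises the
    basis part w_j(u) alone.  ``varying_index`` maps coefficient block j to
    its beta column (defaults to 0..Ptilde-1).

    Returns (Ptilde, n, 3) with columns (median, 2.5%, 97.5%); computed in
    location chunks so large n never materialises an n x L draw matrix.
    """
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    n = locs.shape[0]
    vidx = (np.arange(draws.n_varying) if varying_index is None
            else np.asarray(varying_index, dtype=int))
    out = np.empty((draws.n_varying, n, 3))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        B = eval_basis(locs[start:stop], basis_spec)
        for j in range(draws.n_varying):
            Wj = B @ draws.gamma_block(j).T
            if include_static:
                Wj = Wj + draws.beta[None, :, vidx[j]]
            out[j, start:stop, 0] = np.median(Wj, axis=1)
            out[j, start:stop, 1] = np.quantile(Wj, 0.025, axis=1)
            out[j, start:stop, 2] = np.quantile(Wj, 0.975, axis=1)
    return out


def mse_svc(draws: PosteriorDraws, truth: np.ndarray, basis_spec: TensorBasisSpec,
            locations, varying_index=None) -> float:
    """Mean squared error of posterior-median coefficient surfaces.

    sum_j sum_n (what_j(u_n) - w*_j(u_n))^2 / (Ptilde N), with what_j the
    posterior median.
    """
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    summ = coefficient_summaries(draws, locations, basis_spec, varying_index)
    est = summ[:, :, 0].T  # (n, Ptilde)
    if est.shape != truth.shape:
        raise ValueError(f"truth shape {truth.shape} != estimates {est.shape}")
    return float(np.mean((est - truth) ** 2))


def interval_metrics(samples: np.ndarray, targets: np.ndarray,
                     level: float = 0.95) -> tuple[float, float]:
    """Coverage and mean length of equal-tailed sample-quantile intervals.

    ``samples`` is (n_targets, L).  Refuses fewer than 40 draws, where the
    2.5%/97.5% sample quantiles are too unstable to define a 95% interval.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    targets = np.asarray(targets, dtype=float).ravel()
    if samples.shape[0] != targets.shape[0]:
        raise ValueError("samples rows must match number of targets")
    if samples.shape[1] < MIN_DRAWS:
        raise ValueError(
            f"need at least {MIN_DRAWS} draws for quantile intervals, got {samples.shape[1]}"
        )
    a = 0.5 * (1.0 - level)
    lo = np.quantile(samples, a, axis=1)
    hi = np.quantile(samples, 1.0 - a, axis=1)
    coverage = float(np.mean((targets >= lo) & (targets <= hi)))
    length = float(np.mean(hi - lo))
    return coverage, length


def mspe(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean squared prediction error of point predictions against held-out y."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.shape != observed.shape:
        raise ValueError("prediction/observation length mismatch")
    return float(np.mean((predicted - observed) ** 2))


METRIC_NAMES = ("mse_svc", "ci_coverage_95", "ci_length_95",
                "mspe", "pi_coverage_95", "pi_length_95")


def evaluate_fit(draws: PosteriorDraws, data: VCMDataset,
                 basis_spec: TensorBasisSpec, predict_seed=None) -> dict:
    """All simulation-study metrics for one fitted replicate.

    Coefficient MSE and CI metrics are evaluated at the training locations
    against the stored truth; predictive metrics on ``data.holdout``.
    """
    if data.truth is None:
        raise ValueError("evaluate_fit requires the simulation truth")
    if data.holdout is None:
        raise ValueError("evaluate_fit requires a holdout set")
    summ = coefficient_summaries(draws, data.locations, basis_spec,
                                 varying_index=data.varying_index)
    est = summ[:, :, 0].T
    res = {
        "mse_svc": float(np.mean((est - data.truth) ** 2)),
        "ci_coverage_95": float(
            np.mean((data.truth.T >= summ[:, :, 1]) & (data.truth.T <= summ[:, :, 2]))
        ),
        "ci_length_95": float(np.mean(summ[:, :, 2] - summ[:, :, 1])),
    }
    hold = data.holdout
    pred = predict(draws, hold.locations, hold.X, hold.varying_index,
                   basis_spec, seed=predict_seed)
    lo, hi = pred.interval(0.95)
    res["mspe"] = mspe(pred.median, hold.y)
    res["pi_coverage_95"] = float(np.mean((hold.y >= lo) & (hold.y <= hi)))
    res["pi_length_95"] = float(np.mean(hi - lo))
    return res


@dataclass
class MetricsReport:
    """Per-replicate metrics with across-replicate median and 95% spread."""

    replicates: pd.DataFrame
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        q = self.replicates[list(METRIC_NAMES)].quantile([0.5, 0.025, 0.975])
        q.index = ["median", "q2.5", "q97.5"]
        return q.T

    def median(self, name: str) -> float:
        return float(self.replicates[name].median())

    def __str__(self) -> str:  # Table-shaped text report
        s = self.summary()
        lines = [f"{'metric':<16}{'median':>10}{'2.5%':>10}{'97.5%':>10}"]
        for name, row in s.iterrows():
            lines.append(
                f"{name:<16}{row['median']:>10.4f}{row['q2.5']:>10.4f}{row['q97.5']:>10.4f}"
            )
        if self.n_failed:
            lines.append(f"(excluded {self.n_failed} failed replicate(s))")
        return "\n".join(lines)


@dataclass
class ExperimentScenario:
    """One simulation scenario: data-generating law, model settings, replication."""

    N: int
    M: Optional[int] = None          # None -> uncompressed; "auto" handled upstream
    n_basis: tuple = (15, 15)
    K: int = 5
    n_iter: int = 5000
    burn_in: Optional[int] = None
    thin: int = 1
    seed: int = 0
    n_holdout: int = 500
    kernels: Optional[Sequence] = None   # default reference kernels
    noise_variance: float = 0.1
    sampler: str = "auto"
    priors: Optional[PriorSpec] = None
    uncompressed_guard: int = 20000


def _fit_replicate(data: VCMDataset, scenario: ExperimentScenario,
                   sketch_seed: int, chain_seed: int, predict_seed: int) -> dict:
    spec = TensorBasisSpec(n_basis=scenario.n_basis,
                           domain=((0.0, 1.0),) * data.n_dim)
    design = assemble_design(data, spec)
    if scenario.M is None:
        if data.n > scenario.uncompressed_guard:
            raise ValueError(
                f"uncompressed fit requested at N={data.n} > guard "
                f"{scenario.uncompressed_guard}; raise uncompressed_guard to override"
            )
        out = identity_sketch(data, design)
    else:
        out = compress(data, design, SketchSpec(M=scenario.M, N=data.n, seed=sketch_seed))
    draws = run_mcmc(out, scenario.priors, n_iter=scenario.n_iter,
                     burn_in=scenario.burn_in, thin=scenario.thin,
                     seed=chain_seed, sampler=scenario.sampler)
    return evaluate_fit(draws, data, spec, predict_seed=predict_seed)


def run_experiment(scenario: ExperimentScenario, verbose: bool = False) -> MetricsReport:
    """Simulate -> (sketch) -> fit -> predict -> metrics over K replicates.

    Each replicate gets independent child seeds for simulation, sketch, chain
    and predictive noise, all derived from ``scenario.seed``.  Failed
    replicates are excluded and counted.
    """
    ss = np.random.SeedSequence(scenario.seed)
    rows, failed = [], 0
    for k, child in enumerate(ss.spawn(scenario.K)):
        s_sim, s_sketch, s_chain, s_pred = [
            int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(4)
        ]
        cfg = SimulationConfig(
            n_locations=scenario.N,
            kernels=scenario.kernels or DEFAULT_KERNELS,
            noise_variance=scenario.noise_variance,
            seed=s_sim, n_holdout=scenario.n_holdout,
        )
        try:
            data = simulate_dataset_cached(cfg)
            row = _fit_replicate(data, scenario, s_sketch, s_chain, s_pred)
        except Exception as e:
            failed += 1
            if verbose:
                print(f"replicate {k} failed: {e}")
            continue
        rows.append(row)
        if verbose:
            print(f"replicate {k}: " + ", ".join(f"{k_}={v:.4f}" for k_, v in row.items()))
    if not rows:
        raise RuntimeError(f"all {scenario.K} replicates failed")
    return MetricsReport(replicates=pd.DataFrame(rows), n_failed=failed)


# simulation is the dominant cost when sweeping M at fixed N/seed; memoise the
# most recent dataset so sweeps reuse it
_sim_cache: dict = {}


def simulate_dataset_cached(cfg: SimulationConfig) -> VCMDataset:
    from .synthetic import simulate_dataset

    key = (cfg.n_locations, cfg.seed, cfg.n_holdout, cfg.noise_variance,
           tuple((k.variance, k.range) for k in cfg.kernels), cfg.n_dim)
    if key not in _sim_cache:
        while len(_sim_cache) >= 8:  # bound memory: keep the 8 most recent
            _sim_cache.pop(next(iter(_sim_cache)))
        _sim_cache[key] = simulate_dataset(cfg)
    return _sim_cache[key]
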