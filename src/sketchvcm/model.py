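"""Scikit-learn style estimator for sketched Bayesian varying-coefficient regression.

`SketchedVCM` ties the pipeline together: derive the basis domain from the
training coordinates, assemble the tensor-product B-spline design, apply the
Gaussian sketch, run the conjugate Gibbs sampler, and expose posterior and
posterior-predictive summaries.  It follows the estimator contract
(get_params/set_params, fitted attributes with trailing underscores,
``fit(X, y)`` / ``predict(X)``) so it composes with sklearn tooling; the
feature matrix ``X`` carries the coordinates in its first ``n_coords`` columns
and the predictors in the remaining ones.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import basis as _basis
from .metrics import PredictiveDraws, coefficient_summaries, predict as _predict
from .sampler import PriorSpec, run_mcmc
from .sketch import SketchSpec, compress, default_M, identity_sketch
from .synthetic import VCMDataset

__all__ = ["SketchedVCM"]


class SketchedVCM(BaseEstimator, RegressorMixin):
    """Bayesian varying-coefficient regression on Gaussian-sketched data.

    Parameters
    ----------
    n_coords : int, default 2
        Number of leading columns of ``X`` holding the index coordinates
        (d = 1 or 2).
    varying : "all" or sequence of int, default "all"
        Which predictor columns (0-based, counted after the coordinates and
        including the intercept if added) have varying coefficients.
    add_intercept : bool, default True
        Prepend an intercept column to the predictors.
    n_basis : tuple of int, default (15, 15)
        Tensor B-spline basis size per coordinate dimension.
    spline_order : int, default 4
        B-spline order (4 = cubic).
    domain : tuple of (low, high) or None
        Basis domain; derived from the training coordinates (padded by 0.1%)
        when None.
    M : int, "auto", or None, default "auto"
        Compressed size.  "auto" uses ceil(10 sqrt(N)); None fits the
        uncompressed full-data model.
    priors : PriorSpec or None
        Conjugate prior settings; defaults to IG(2, 0.1) variances and a
        standard-normal beta prior.
    n_iter, burn_in, thin : MCMC schedule; burn_in defaults to 60% of n_iter.
    sampler : {"auto", "fast", "cholesky"}
        Gamma-update implementation; "auto" picks the smaller linear system.
    random_state : int or None
        Master seed; sketch and chain use independent derived streams.

    Attributes
    ----------
    basis_spec_ : TensorBasisSpec
    sketch_spec_ : SketchSpec or None (None for the uncompressed fit)
    draws_ : PosteriorDraws
    varying_index_ : indices of varying predictor columns
    """

    def __init__(self, n_coords: int = 2, varying: Union[str, Sequence[int]] = "all",
                 add_intercept: bool = True, n_basis=(15, 15), spline_order: int = 4,
                 domain=None, M: Union[int, str, None] = "auto",
                 priors: Optional[PriorSpec] = None, n_iter: int = 5000,
                 burn_in: Optional[int] = None, thin: int = 1,
                 sampler: str = "auto", random_state: Optional[int] = None):
        self.n_coords = n_coords
        self.varying = varying
        self.add_intercept = add_intercept
        self.n_basis = n_basis
        self.spline_order = spline_order
        self.domain = domain
        self.M = M
        self.priors = priors
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.sampler = sampler
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d: [coordinates | predictors]")
        if X.shape[1] < self.n_coords:
            raise ValueError(
                f"X has {X.shape[1]} columns but n_coords={self.n_coords}"
            )
        locs, preds = X[:, : self.n_coords], X[:, self.n_coords:]
        if self.add_intercept:
            preds = np.column_stack([np.ones(len(X)), preds])
        if preds.shape[1] == 0:
            raise ValueError("no predictor columns (and add_intercept=False)")
        return locs, preds

    def _dataset(self, X, y=None) -> VCMDataset:
        locs, preds = self._split(X)
        if self.varying == "all":
            vidx = np.arange(preds.shape[1])
        else:
            vidx = np.asarray(self.varying, dtype=int)
        return VCMDataset(locations=locs, X=preds, varying_index=vidx,
                          y=np.zeros(len(locs)) if y is None else y)

    def fit(self, X, y):
        """Fit the model on ``X = [coords | predictors]`` and responses ``y``."""
        data = self._dataset(X, y)
        n_basis = tuple(np.atleast_1d(self.n_basis).astype(int))
        if len(n_basis) != data.n_dim:
            raise ValueError(
                f"n_basis has {len(n_basis)} entries for {data.n_dim}-d coordinates"
            )
        domain = self.domain or _basis.domain_from_locations(data.locations)
        spec = _basis.TensorBasisSpec(n_basis=n_basis, domain=domain,
                                      order=self.spline_order)
        design = _basis.assemble_design(data, spec)

        ss = np.random.SeedSequence(self.random_state)
        s_sketch, s_chain = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
        if self.M is None:
            out = identity_sketch(data, design)
            self.sketch_spec_ = None
        else:
            M = default_M(data.n) if self.M == "auto" else int(self.M)
            self.sketch_spec_ = SketchSpec(M=M, N=data.n, seed=s_sketch)
            out = compress(data, design, self.sketch_spec_)

        self.draws_ = run_mcmc(out, self.priors, n_iter=self.n_iter,
                               burn_in=self.burn_in, thin=self.thin,
                               seed=s_chain, sampler=self.sampler)
        self.basis_spec_ = spec
        self.varying_index_ = data.varying_index
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    # ------------------------------------------------------------------
    def sample_predictive(self, X, noise: bool = True, seed=None) -> PredictiveDraws:
        """Posterior-predictive draws at new rows of ``X`` (composition sampling)."""
        check_is_fitted(self, "draws_")
        data = self._dataset(X)
        if seed is None and self.random_state is not None:
            # deterministic predictive stream derived from the master seed
            seed = int(np.random.SeedSequence(self.random_state).spawn(3)[2]
                       .generate_state(1)[0] % (2**31))
        return _predict(self.draws_, data.locations, data.X, data.varying_index,
                        self.basis_spec_, seed=seed, noise=noise)

    def predict(self, X) -> np.ndarray:
        """Point prediction: the posterior-predictive median."""
        return self.sample_predictive(X).median

    def predict_interval(self, X, level: float = 0.95):
        """Equal-tailed posterior-predictive interval bounds (lower, upper)."""
        return self.sample_predictive(X).interval(level)

    def coefficient_surface(self, locations) -> np.ndarray:
        """Posterior (median, 2.5%, 97.5%) of each varying coefficient, (Ptilde, n, 3)."""
        check_is_fitted(self, "draws_")
        return coefficient_summaries(self.draws_, locations, self.basis_spec_,
                                     varying_index=self.varying_index_)
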