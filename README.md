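# sketchvcm

Bayesian **varying-coefficient regression** for large point-referenced
(spatial or functional) datasets via **data sketching**: instead of fitting
the full model to all N observations, the response and design matrices are
compressed once with a random Gaussian projection, and a standard conjugate
Gibbs sampler runs on the M ≪ N compressed records.  The package is aimed at
spatial statisticians and epidemiologists who need full Bayesian uncertainty
quantification for regression effects that vary over a map (or over time) at
sample sizes where classical Gaussian-process machinery is impractical.

## Model

For an index u ∈ 𝒟 ⊆ ℝᵈ (d = 1 or 2),

    y(u) = x(u)ᵀβ + x̃(u)ᵀw(u) + ε(u),      ε(u) ~ N(0, σ²),

where β are static coefficients and w(u) = (w₁(u), …, w_P̃(u))ᵀ are varying
coefficients for the predictor subset x̃(u).  Each coefficient is expanded in
a shared tensor-product cubic B-spline basis, w_j(u) = B(u)ᵀγ_j with
H = H₁·H₂ basis functions, giving the linear mixed model
y = Xβ + Zγ + ε with Z the N × (H·P̃) assembled design.

A compression matrix Φ (M × N, entries iid N(0, 1/N), drawn once from a
recorded seed) produces the sketched data y_Φ = Φy, X_Φ = ΦX, Z_Φ = ΦZ, which
are modelled hierarchically as

    y_Φ ~ N(X_Φβ + Z_Φγ, σ² I_M),   γ_j ~ N(0, τ_j² I_H),
    τ_j², σ² ~ IG(2, 0.1),           β ~ N(μ_β, V_β).

Because ΦΦᵀ ≈ I_M for M ≪ N, this is an accurate surrogate for the full-data
model, at a fraction of the cost; the raw data are not recoverable from the
compressed records.  All four full conditionals are conjugate.  The
high-dimensional γ update is available two ways: a direct Cholesky draw of
the (H·P̃)-dimensional conditional, and a structured fast sampler that only
solves an M × M system (cost O(M³ + M²·H·P̃)) — both exact, verified against
each other in the test suite.  Prediction at new locations uses composition
sampling through the posterior draws.

## Worked example

```python
import numpy as np
from sketchvcm import SimulationConfig, SketchedVCM, simulate_dataset, mspe

# simulate: coordinates uniform on [0,1]^2, three varying coefficients drawn
# from exponential-covariance GP fields, noise variance 0.1
data = simulate_dataset(SimulationConfig(n_locations=5000, seed=7))

X = np.column_stack([data.locations, data.X[:, 1:]])   # [coords | predictors]
model = SketchedVCM(n_basis=(15, 15), M=700, n_iter=5000,
                    domain=((0, 1), (0, 1)), random_state=0)
model.fit(X, data.y)

hold = data.holdout
Xh = np.column_stack([hold.locations, hold.X[:, 1:]])
print("MSPE:", round(mspe(model.predict(Xh), hold.y), 4))
surf = model.coefficient_surface(data.locations)       # (3, N, 3) summaries
print("coefficient MSE:", round(float(np.mean((surf[:, :, 0].T - data.truth)**2)), 4))
```

Output:

```
MSPE: 0.1867
coefficient MSE: 0.0292
```

The MSPE of ≈ 0.19 decomposes as the irreducible noise floor (σ*² = 0.1)
plus the estimation error of the three coefficient surfaces; the coefficient
MSE of ≈ 0.03 is the average squared error of the posterior-median surfaces
against the simulated truth.  A command-line interface with `simulate`,
`fit`, `predict` and `experiment` subcommands wraps the same pipeline
(`sketchvcm --help`).

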