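import numpy as np
import pytest

from sketchvcm import (GPKernelSpec, SimulationConfig, SketchSpec, TensorBasisSpec,
                       assemble_design, compress, simulate_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_data():
    """Small simulated dataset with three varying coefficients."""
    cfg = SimulationConfig(n_locations=60, seed=5, n_holdout=30)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_fit_inputs(tiny_data):
    """Compressed inputs for sampler tests: N=60, M=25, H=16, Ptilde=3."""
    spec = TensorBasisSpec(n_basis=(4, 4), domain=((0, 1), (0, 1)))
    design = assemble_design(tiny_data, spec)
    out = compress(tiny_data, design, SketchSpec(M=25, N=tiny_data.n, seed=3))
    return tiny_data, spec, design, out


def make_sketch_output(M, H, n_varying, P=1, seed=0, scale=1.0):
    """Random small SketchOutput for direct sampler tests."""
    from sketchvcm.sketch import SketchOutput

    r = np.random.default_rng(seed)
    Z = scale * r.standard_normal((M, H * n_varying))
    X = r.standard_normal((M, P))
    y = r.standard_normal(M)
    return SketchOutput(y_phi=y, X_phi=X, Z_phi=Z, spec=None,
                        n_varying=n_varying, H=H)
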