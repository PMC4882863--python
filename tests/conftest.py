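import numpy as np
import pytest

from respstyle import (
    ItemParameters,
    ResponseMatrix,
    build_constrained_model,
    load_neoffi_params,
)
from respstyle.estimate import FittedModel


@pytest.fixture(scope="session")
def neoffi():
    """Packaged NEO-FFI parameters with the ERS dimension."""
    return load_neoffi_params(ers=True)


@pytest.fixture(scope="session")
def toy2d():
    """Two correlated substantive dimensions, 4 items, mild intercepts."""
    rng = np.random.default_rng(3)
    spec, params = build_constrained_model(("X", "Y"), 2, ers=False)
    c = rng.normal(0, 1.2, (4, 5))
    params = ItemParameters(spec.slope_array(), c - c.mean(1, keepdims=True))
    data = ResponseMatrix(rng.integers(1, 6, size=(6, 4)))
    corr = np.array([[1.0, 0.4], [0.4, 1.0]])
    return spec, params, data, corr


def truth_fit(spec, params, corr, nodes_per_dim=10):
    """A FittedModel wrapper around known (generating) parameters, for
    exercising scoring without running the estimator."""
    return FittedModel(
        spec=spec, params=params, latent_correlations=np.asarray(corr, float),
        log_likelihood=0.0, log_prior=0.0, log_posterior=0.0, n_parameters=0,
        criteria={}, converged=True, iteration_trace=[], n_persons=0,
        prior_sd=3.0, nodes_per_dim=nodes_per_dim,
    )


@pytest.fixture(scope="session")
def palindromic_bank():
    """Item bank symmetric under category reversal: palindromic intercepts
    (1, -1, 0, -1, 1) with the standard slope vectors, one scale + ERS."""
    spec, params = build_constrained_model(("X",), 12, ers=True)
    pal = np.tile([1.0, -1.0, 0.0, -1.0, 1.0], (12, 1))
    params = ItemParameters(spec.slope_array(), pal)
    return spec, params
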