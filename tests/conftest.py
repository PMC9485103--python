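"""Shared fixtures: small seeded targets and finite-difference oracles."""

import numpy as np
import pytest

from irrlangevin import (gaussian_posterior, gen_ica_data, gen_logistic_data,
                         gen_normal_data, ica_model, logistic_model,
                         normal_params_model)


def fd_gradient(fn, x, eps=1e-6):
    """Central finite-difference gradient of a scalar function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    for i in range(x.size):
        step = eps * max(1.0, abs(x[i]))
        up, dn = x.copy(), x.copy()
        up[i] += step
        dn[i] -= step
        out[i] = (fn(up) - fn(dn)) / (2 * step)
    return out


def fd_matrix_deriv(fn, x, eps=1e-5):
    """Central finite differences of a matrix-valued function.

    Returns T with T[i, j, k] = d fn(x)_ij / d x_k.
    """
    x = np.asarray(x, dtype=float)
    base = np.asarray(fn(x))
    out = np.empty(base.shape + (x.size,))
    for k in range(x.size):
        step = eps * max(1.0, abs(x[k]))
        up, dn = x.copy(), x.copy()
        up[k] += step
        dn[k] -= step
        out[..., k] = (np.asarray(fn(up)) - np.asarray(fn(dn))) / (2 * step)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def normal30_target():
    """The (mu, sigma) posterior for 30 draws from Normal(0, 10^2)."""
    return normal_params_model(gen_normal_data(30, 0.0, 10.0, seed=7))


@pytest.fixture(scope="session")
def gaussian3_spec():
    rng = np.random.default_rng(11)
    prior = np.diag([0.2, 0.01, 0.05])
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    prior = q @ prior @ q.T
    noise = 0.25 * np.eye(3)
    data = rng.normal(0.0, 2.0, size=(10, 3))
    return gaussian_posterior(prior, noise, data)


@pytest.fixture(scope="session")
def logistic_small():
    features, labels = gen_logistic_data(25, 4, seed=3)
    return logistic_model(features, labels, alpha=1.0)


@pytest.fixture(scope="session")
def ica_small():
    mixed, _, _ = gen_ica_data(3, 40, mixing_seed=5, source_seed=6)
    return ica_model(mixed, lam=1.0)
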