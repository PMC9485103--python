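"""Posterior targets and their geometric quantities.

Each target is an (unnormalized) log-density ``log pi`` together with the
quantities the perturbed Langevin samplers need:

* the score ``grad_log_density`` and its prior / per-datum decomposition
  (for minibatch gradient estimates),
* a symmetric positive-definite metric ``B(theta)`` (the inverse of a
  Riemannian metric, typically built from expected Fisher information),
* a factor ``sqrt(B)`` with ``sqrt(B) sqrt(B)^T = B`` used for the
  multiplicative noise,
* the divergence ``(div B)_i = sum_j dB_ij/dtheta_j`` and the full
  derivative tensor ``T[i, j, k] = dB_ij/dtheta_k`` needed by the
  geometry-informed irreversible correction.

All state-dependent methods are vectorized over a leading batch axis:
a state may be a single ``(d,)`` vector or an ``(M, d)`` stack, and
results follow the same convention.  This batching is what makes the
lock-step ensemble integrator fast in pure numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import InvalidInputError, NumericalDomainError

__all__ = [
    "TargetModel",
    "LinearGaussianSpec",
    "gaussian_posterior",
    "normal_params_model",
    "logistic_model",
    "ica_model",
    "load_feature_table",
]


def _promote(state, dim):
    """Return (states (M, d), was_single)."""
    arr = np.asarray(state, dtype=float)
    if arr.ndim == 1:
        if arr.shape[0] != dim:
            raise InvalidInputError(
                f"state has dimension {arr.shape[0]}, expected {dim}"
            )
        return arr[None, :], True
    if arr.ndim != 2 or arr.shape[1] != dim:
        raise InvalidInputError(f"states must be (d,) or (M, d) with d={dim}")
    return arr, False


def _desqueeze(value, single):
    return value[0] if single else value


def _check_spd(mat, name):
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise InvalidInputError(f"{name} must be a square matrix")
    if not np.allclose(mat, mat.T, rtol=1e-10, atol=1e-12):
        raise InvalidInputError(f"{name} is not symmetric")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() <= 0:
        raise InvalidInputError(
            f"{name} is not positive definite (min eigenvalue {eigvals.min():.3g})"
        )
    return 0.5 * (mat + mat.T)


def spd_sqrt(mat):
    """Symmetric PSD square root via eigendecomposition (batched)."""
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)[..., None, :]) @ np.swapaxes(v, -1, -2)


class TargetModel:
    """Contract shared by all sampling targets.

    Subclasses must set ``dim`` and ``n_data`` and implement the batched
    ``_log_density``, ``_grad``, ``_minibatch_grad`` and (if they carry a
    metric) ``_metric*`` methods on ``(M, d)`` state stacks.
    """

    dim: int
    n_data: int
    has_metric: bool = False
    #: metric independent of the state (lets the sampler pre-assemble drifts)
    constant_metric: bool = False

    # -- densities and scores ------------------------------------------------
    def log_density(self, state):
        x, single = _promote(state, self.dim)
        return _desqueeze(self._log_density(x), single)

    def grad_log_density(self, state):
        x, single = _promote(state, self.dim)
        return _desqueeze(self._grad(x), single)

    def prior_grad(self, state):
        x, single = _promote(state, self.dim)
        return _desqueeze(self._prior_grad(x), single)

    def datum_grad(self, state, i):
        """Gradient of the log-likelihood term of data point ``i``."""
        if not 0 <= int(i) < self.n_data:
            raise InvalidInputError(f"datum index {i} outside [0, {self.n_data})")
        x, single = _promote(state, self.dim)
        idx = np.full((x.shape[0], 1), int(i))
        # N/n scaling with n=1 gives N * datum term; undo it.
        scaled = self._minibatch_grad(x, idx) - self._prior_grad(x)
        return _desqueeze(scaled / self.n_data, single)

    def minibatch_grad(self, state, idx):
        """Stochastic gradient: prior term plus (N/n)-scaled subsample sum.

        ``idx`` has shape ``(M, n)`` (or ``(n,)`` for a single state) and
        holds data indices.
        """
        x, single = _promote(state, self.dim)
        idx = np.asarray(idx)
        if idx.ndim == 1:
            idx = np.broadcast_to(idx, (x.shape[0], idx.shape[0]))
        return _desqueeze(self._minibatch_grad(x, idx), single)

    # -- geometry ------------------------------------------------------------
    def metric(self, state):
        x, single = _promote(state, self.dim)
        return _desqueeze(self._metric(x), single)

    def metric_sqrt(self, state):
        x, single = _promote(state, self.dim)
        return _desqueeze(self._metric_sqrt(x), single)

    def metric_div(self, state):
        x, single = _promote(state, self.dim)
        return _desqueeze(self._metric_div(x), single)

    def metric_deriv(self, state):
        x, single = _promote(state, self.dim)
        return _desqueeze(self._metric_deriv(x), single)

    # -- admissibility -------------------------------------------------------
    def admissible(self, states):
        """Boolean mask over a batch: states at which the model is defined."""
        x, single = _promote(states, self.dim)
        mask = np.isfinite(x).all(axis=1)
        return bool(mask[0]) if single else mask

    def check_state(self, state, step=None):
        """Raise :class:`NumericalDomainError` if the state is inadmissible."""
        if not np.all(self.admissible(state)):
            raise NumericalDomainError(
                f"state outside the admissible domain of {type(self).__name__}"
                + (f" at step {step}" if step is not None else ""),
                step=step,
                state=np.asarray(state),
            )

    # -- defaults ------------------------------------------------------------
    def _metric(self, x):  # pragma: no cover - overridden where has_metric
        raise NotImplementedError(f"{type(self).__name__} carries no metric")

    _metric_sqrt = _metric
    _metric_div = _metric
    _metric_deriv = _metric


# ---------------------------------------------------------------------------
# Linear Gaussian posterior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearGaussianSpec:
    """Conjugate Gaussian posterior for a normal mean with known noise.

    With prior N(0, Gamma_theta^-1) on the mean and N(theta, Gamma_X^-1)
    observations, the posterior is Gaussian with precision
    ``Gamma_p = Gamma_theta + N Gamma_X`` and mean
    ``mu_p = Gamma_p^-1 Gamma_X sum_i X_i``.  ``drift_matrix`` and
    ``drift_offset`` are the coefficients of the Euler-Maruyama recurrence
    of the unperturbed sampler at temperature 1/2:
    ``theta' = (I - A h) theta + D h + sqrt(h) xi``.
    """

    prior_precision: np.ndarray
    noise_precision: np.ndarray
    data: np.ndarray
    posterior_mean: np.ndarray
    posterior_precision: np.ndarray
    drift_matrix: np.ndarray
    drift_offset: np.ndarray

    @property
    def dim(self):
        return self.posterior_mean.shape[0]

    def make_target(self, metric="posterior_covariance"):
        """Build the sampling target.

        ``metric`` is ``"posterior_covariance"`` (B = Gamma_p^-1, the choice
        that equilibrates the reversible dynamics exactly) or ``"identity"``.
        """
        return GaussianPosterior(self, metric=metric)


def gaussian_posterior(prior_precision, noise_precision, data) -> LinearGaussianSpec:
    """Assemble the conjugate Gaussian posterior from data and precisions."""
    prior_precision = np.atleast_2d(np.asarray(prior_precision, dtype=float))
    noise_precision = np.atleast_2d(np.asarray(noise_precision, dtype=float))
    prior_precision = _check_spd(prior_precision, "prior_precision")
    noise_precision = _check_spd(noise_precision, "noise_precision")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    d = prior_precision.shape[0]
    if noise_precision.shape[0] != d or data.shape[1] != d:
        raise InvalidInputError("precisions and data must share one dimension")
    if data.shape[0] < 1:
        raise InvalidInputError("need at least one data vector")
    n = data.shape[0]
    post_prec = prior_precision + n * noise_precision
    data_sum = data.sum(axis=0)
    post_mean = np.linalg.solve(post_prec, noise_precision @ data_sum)
    return LinearGaussianSpec(
        prior_precision=prior_precision,
        noise_precision=noise_precision,
        data=data,
        posterior_mean=post_mean,
        posterior_precision=post_prec,
        drift_matrix=0.5 * post_prec,
        drift_offset=0.5 * noise_precision @ data_sum,
    )


class GaussianPosterior(TargetModel):
    """Gaussian target; the constant metric defaults to Gamma_p^-1."""

    has_metric = True
    constant_metric = True

    def __init__(self, spec: LinearGaussianSpec, metric="posterior_covariance"):
        self.spec = spec
        self.dim = spec.dim
        self.n_data = spec.data.shape[0]
        if metric == "posterior_covariance":
            self._B = np.linalg.inv(spec.posterior_precision)
        elif metric == "identity":
            self._B = np.eye(self.dim)
        else:
            raise InvalidInputError(f"unknown metric choice {metric!r}")
        self._B = 0.5 * (self._B + self._B.T)
        self._sqrtB = spd_sqrt(self._B)

    def _log_density(self, x):
        r = x - self.spec.posterior_mean
        return -0.5 * np.einsum("mi,ij,mj->m", r, self.spec.posterior_precision, r)

    def _grad(self, x):
        return -(x - self.spec.posterior_mean) @ self.spec.posterior_precision

    def _prior_grad(self, x):
        return -x @ self.spec.prior_precision

    def _minibatch_grad(self, x, idx):
        n = idx.shape[1]
        scale = self.n_data / n
        data_sum = self.spec.data[idx].sum(axis=1)  # (M, d)
        lik = scale * (data_sum - n * x) @ self.spec.noise_precision
        return self._prior_grad(x) + lik

    def _metric(self, x):
        return np.broadcast_to(self._B, (x.shape[0],) + self._B.shape)

    def _metric_sqrt(self, x):
        return np.broadcast_to(self._sqrtB, (x.shape[0],) + self._B.shape)

    def _metric_div(self, x):
        return np.zeros_like(x)

    def _metric_deriv(self, x):
        d = self.dim
        return np.zeros((x.shape[0], d, d, d))


# ---------------------------------------------------------------------------
# Parameters of a normal distribution
# ---------------------------------------------------------------------------

class NormalParamsTarget(TargetModel):
    """Posterior over (mu, sigma) of scalar normal data under a flat prior.

    log pi = -N log sigma - sum_i (X_i - mu)^2 / (2 sigma^2), sigma > 0.
    The metric is the inverse expected Fisher information,
    B = (sigma^2/N) diag(1, 1/2).
    """

    has_metric = True

    def __init__(self, data):
        data = np.asarray(data, dtype=float).ravel()
        if data.size == 0:
            raise InvalidInputError("data must be non-empty")
        self.data = data
        self.dim = 2
        self.n_data = data.size
        self._sq = np.square(data)
        self._s1 = data.sum()
        self._s2 = self._sq.sum()

    def _split(self, x):
        return x[:, 0], x[:, 1]

    def _require_positive_sigma(self, sigma):
        if np.any(sigma <= 0):
            raise NumericalDomainError(
                "sigma <= 0 in normal-parameters target", state=sigma
            )

    def _log_density(self, x):
        mu, sigma = self._split(x)
        self._require_positive_sigma(sigma)
        n = self.n_data
        m2 = self._s2 - 2 * mu * self._s1 + n * mu**2
        return -n * np.log(sigma) - m2 / (2 * sigma**2)

    def _grad(self, x):
        mu, sigma = self._split(x)
        self._require_positive_sigma(sigma)
        n = self.n_data
        m1 = self._s1 - n * mu
        m2 = self._s2 - 2 * mu * self._s1 + n * mu**2
        out = np.empty_like(x)
        out[:, 0] = m1 / sigma**2
        out[:, 1] = -n / sigma + m2 / sigma**3
        return out

    def _prior_grad(self, x):
        return np.zeros_like(x)

    def _minibatch_grad(self, x, idx):
        mu, sigma = self._split(x)
        self._require_positive_sigma(sigma)
        n_sub = idx.shape[1]
        scale = self.n_data / n_sub
        s1 = self.data[idx].sum(axis=1)
        s2 = self._sq[idx].sum(axis=1)
        m1 = scale * (s1 - n_sub * mu)
        m2 = scale * (s2 - 2 * mu * s1 + n_sub * mu**2)
        out = np.empty_like(x)
        out[:, 0] = m1 / sigma**2
        out[:, 1] = -self.n_data / sigma + m2 / sigma**3
        return out

    def _metric(self, x):
        sigma = x[:, 1]
        m = x.shape[0]
        out = np.zeros((m, 2, 2))
        out[:, 0, 0] = sigma**2 / self.n_data
        out[:, 1, 1] = sigma**2 / (2 * self.n_data)
        return out

    def _metric_sqrt(self, x):
        sigma = x[:, 1]
        m = x.shape[0]
        out = np.zeros((m, 2, 2))
        out[:, 0, 0] = sigma / np.sqrt(self.n_data)
        out[:, 1, 1] = sigma / np.sqrt(2 * self.n_data)
        return out

    def _metric_div(self, x):
        out = np.zeros_like(x)
        out[:, 1] = x[:, 1] / self.n_data
        return out

    def _metric_deriv(self, x):
        sigma = x[:, 1]
        out = np.zeros((x.shape[0], 2, 2, 2))
        out[:, 0, 0, 1] = 2 * sigma / self.n_data
        out[:, 1, 1, 1] = sigma / self.n_data
        return out

    def admissible(self, states):
        x, single = _promote(states, self.dim)
        mask = np.isfinite(x).all(axis=1) & (x[:, 1] > 0)
        return bool(mask[0]) if single else mask


def normal_params_model(data) -> NormalParamsTarget:
    """Target over (mu, sigma) for i.i.d. scalar normal data, flat prior."""
    return NormalParamsTarget(data)


# ---------------------------------------------------------------------------
# Bayesian logistic regression
# ---------------------------------------------------------------------------

class LogisticRegressionTarget(TargetModel):
    """Bayesian logistic regression with N(0, alpha^-1 I) prior on weights.

    The metric is B(w) = I + G(w)^-1 with
    G(w) = alpha^-1 I + X Lambda(w) X^T, Lambda_ii = phi_i (1 - phi_i),
    which keeps B - I positive definite everywhere.
    """

    has_metric = True

    def __init__(self, features, labels, alpha=1.0):
        features = np.atleast_2d(np.asarray(features, dtype=float))
        labels = np.asarray(labels, dtype=float).ravel()
        if features.shape[0] != labels.shape[0]:
            raise InvalidInputError("features and labels disagree in length")
        if not np.all(np.isin(labels, (0.0, 1.0))):
            raise InvalidInputError("labels must lie in {0, 1}")
        if alpha <= 0:
            raise InvalidInputError("prior precision alpha must be positive")
        self.features = features
        self.labels = labels
        self.alpha = float(alpha)
        self.n_data, self.dim = features.shape
        # per-observation triple products x_i x_j x_k, flattened: lets the
        # metric-derivative tensor assemble as one GEMM per batch
        self._f3 = np.einsum("ni,nj,nk->nijk", features, features,
                             features).reshape(self.n_data, -1)

    def _logits(self, x):
        return x @ self.features.T  # (M, N)

    def _log_density(self, x):
        z = self._logits(x)
        loglik = (self.labels * z).sum(axis=1) - np.logaddexp(0.0, z).sum(axis=1)
        return loglik - 0.5 * self.alpha * np.square(x).sum(axis=1)

    def _grad(self, x):
        resid = self.labels - expit(self._logits(x))  # (M, N)
        return -self.alpha * x + resid @ self.features

    def _prior_grad(self, x):
        return -self.alpha * x

    def _minibatch_grad(self, x, idx):
        n = idx.shape[1]
        scale = self.n_data / n
        feats = self.features[idx]  # (M, n, d)
        z = np.einsum("mnd,md->mn", feats, x)
        resid = self.labels[idx] - expit(z)
        return -self.alpha * x + scale * np.einsum("mn,mnd->md", resid, feats)

    def _lambda(self, x):
        p = expit(self._logits(x))
        return p * (1.0 - p)  # (M, N)

    def _fisher(self, x):
        lam = self._lambda(x)  # (M, N)
        g = np.matmul(self.features.T, lam[:, :, None] * self.features)
        g += np.eye(self.dim) / self.alpha
        return g

    def _metric(self, x):
        return np.linalg.inv(self._fisher(x)) + np.eye(self.dim)

    def _metric_sqrt(self, x):
        return spd_sqrt(self._metric(x))

    def _metric_deriv(self, x):
        # dB/dw_k = -G^-1 (X dLambda_k X^T) G^-1
        p = expit(self._logits(x))
        t = p * (1 - p) * (1 - 2 * p)  # (M, N)
        ginv = np.linalg.inv(self._fisher(x))
        d = self.dim
        # dG[m, i, j, k] = sum_n t[m,n] X[n,i] X[n,j] X[n,k]
        dg = (t @ self._f3).reshape(-1, d, d, d)
        dgk = dg.transpose(0, 3, 1, 2)  # (M, k, i, j)
        sand = np.matmul(np.matmul(ginv[:, None], dgk), ginv[:, None])
        return -sand.transpose(0, 2, 3, 1)

    def _metric_div(self, x):
        t = self._metric_deriv(x)
        return np.einsum("mijj->mi", t)


def logistic_model(features, labels, alpha=1.0) -> LogisticRegressionTarget:
    """Bayesian logistic regression target; see the class docstring."""
    return LogisticRegressionTarget(features, labels, alpha=alpha)


def load_feature_table(path):
    """Read a whitespace- or comma-separated numeric table.

    One row per observation; the last column is the {0, 1} label (the
    layout of the "german numeric" style files).  Returns (features, labels).
    """
    import pandas as pd

    try:
        frame = pd.read_csv(path, sep=None, engine="python", header=None)
    except Exception as exc:  # pragma: no cover - I/O failure path
        raise InvalidInputError(f"could not parse table {path}: {exc}") from exc
    values = frame.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise InvalidInputError("table must have at least two columns")
    if not np.isfinite(values).all():
        raise InvalidInputError(f"table {path} contains non-numeric entries")
    return values[:, :-1], values[:, -1]


# ---------------------------------------------------------------------------
# Bayesian independent component analysis
# ---------------------------------------------------------------------------

class ICATarget(TargetModel):
    """Posterior over a de-mixing matrix W for blind signal separation.

    The state is vec(W) with *column-major* stacking, so the natural-
    gradient identity vec(f W^T W) = (W^T W kron I) vec(f) holds.  The
    per-component source density is the standard logistic law
    p(y) = (1/4) sech^2(y/2), and the prior on each W_ij is N(0, 1/lambda).
    The metric is B(W) = (I + W^T W) kron I_m.
    """

    has_metric = True

    def __init__(self, mixed_signals, lam=1.0):
        x = np.atleast_2d(np.asarray(mixed_signals, dtype=float))
        if lam < 0:
            raise InvalidInputError("prior precision lambda must be >= 0")
        self.signals = x  # (N, m) rows = observations
        self.n_data, self.m = x.shape
        self.dim = self.m * self.m
        self.lam = float(lam)

    # -- vec <-> matrix ------------------------------------------------------
    def to_matrices(self, x):
        """(M, m^2) column-major vecs -> (M, m, m) matrices."""
        m = self.m
        return x.reshape(x.shape[0], m, m).transpose(0, 2, 1)

    def to_vecs(self, w):
        """(M, m, m) matrices -> (M, m^2) column-major vecs."""
        return w.transpose(0, 2, 1).reshape(w.shape[0], self.dim)

    # -- densities -----------------------------------------------------------
    def _log_density(self, x):
        w = self.to_matrices(x)
        sign, logdet = np.linalg.slogdet(w)
        if np.any(sign == 0):
            raise NumericalDomainError("singular de-mixing matrix", state=w)
        y = np.einsum("mij,nj->min", w, self.signals)  # (M, m, N)
        loglik = -2.0 * np.logaddexp(y / 2.0, -y / 2.0).sum(axis=(1, 2))
        prior = -0.5 * self.lam * np.square(x).sum(axis=1)
        return self.n_data * logdet + loglik + prior

    def _grad_matrix(self, w, signals, scale):
        """N W^-T - scale * sum_n tanh(y_n/2) x_n^T - lam W (batched)."""
        winv_t = np.linalg.inv(w).transpose(0, 2, 1)
        if signals.ndim == 2:  # shared data (N, m)
            y = np.einsum("mij,nj->min", w, signals)
            s = np.einsum("min,nj->mij", np.tanh(y / 2.0), signals)
        else:  # per-chain minibatches (M, n, m)
            y = np.einsum("mij,mnj->min", w, signals)
            s = np.einsum("min,mnj->mij", np.tanh(y / 2.0), signals)
        return self.n_data * winv_t - scale * s - self.lam * w

    def _grad(self, x):
        w = self.to_matrices(x)
        return self.to_vecs(self._grad_matrix(w, self.signals, 1.0))

    def _prior_grad(self, x):
        return -self.lam * x

    def _minibatch_grad(self, x, idx):
        w = self.to_matrices(x)
        sub = self.signals[idx]  # (M, n, m)
        scale = self.n_data / idx.shape[1]
        return self.to_vecs(self._grad_matrix(w, sub, scale))

    # -- geometry ------------------------------------------------------------
    def _gram_plus_eye(self, x):
        w = self.to_matrices(x)
        return np.eye(self.m) + np.einsum("mji,mjk->mik", w, w)  # I + W^T W

    def _kron_with_eye(self, s):
        """Batched kron(S, I_m) for column-major vec indexing."""
        m = self.m
        eye = np.eye(m)
        out = s[:, :, None, :, None] * eye[None, None, :, None, :]
        return out.reshape(s.shape[0], self.dim, self.dim)

    def _metric(self, x):
        return self._kron_with_eye(self._gram_plus_eye(x))

    def _metric_sqrt(self, x):
        return self._kron_with_eye(spd_sqrt(self._gram_plus_eye(x)))

    def _metric_div(self, x):
        # div of (I + W^T W) kron I_m is (m + 1) vec(W); cross-checked
        # against finite differences in the tests.
        return (self.m + 1) * x

    def _metric_deriv(self, x):
        m, d = self.m, self.dim
        batch = x.shape[0]
        w = self.to_matrices(x)  # (M, r, c)
        eye = np.eye(m)
        # dS[c, c', cs, rs] = delta(c, cs) W[rs, c'] + delta(c', cs) W[rs, c]
        ds = np.zeros((batch, m, m, m, m))  # [M, c, c', cs, rs]
        for cs in range(m):
            ds[:, cs, :, cs, :] += w.transpose(0, 2, 1)  # W[rs, c'] at c = cs
            ds[:, :, cs, cs, :] += w.transpose(0, 2, 1)  # W[rs, c] at c' = cs
        # T[(c,r), (c',r'), (cs,rs)] = ds[c, c', cs, rs] * delta(r, r')
        t = (ds[:, :, None, :, None, :, :] *
             eye[None, None, :, None, :, None, None])
        # axes: M, c, r, c', r', cs, rs -> flatten pairs with p = c*m + r
        return t.reshape(batch, d, d, d)

    def admissible(self, states):
        x, single = _promote(states, self.dim)
        mask = np.isfinite(x).all(axis=1)
        return bool(mask[0]) if single else mask


def ica_model(mixed_signals, lam=1.0) -> ICATarget:
    """Bayesian ICA target over vec(W); see the class docstring."""
    return ICATarget(mixed_signals, lam=lam)
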