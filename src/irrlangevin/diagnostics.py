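"""Estimator-quality diagnostics.

Three complementary views of sampler performance:

* ensemble bias / variance / MSE of the time-average estimator
  phi-bar_K = (1/K) sum_{k<K} phi(theta_k), against a supplied reference
  expectation;
* the asymptotic variance sigma^2(phi) = lim_t t Var(t^-1 int phi), via
  the batch-means method (twenty contiguous batches by default);
* the kernelized Stein discrepancy (KSD) with the inverse multiquadric
  base kernel r(x, y) = (c^2 + ||x - y||^2)^beta, beta in (-1, 0), which
  measures sample quality over a whole class of test functions and
  decays as K^{-1/2} for a well-behaved sampler.

``em_stationary_law`` is the exact discrete-time oracle for linear
(Ornstein-Uhlenbeck-like) recurrences, used to validate the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .errors import InvalidInputError

__all__ = [
    "KSDConfig",
    "MetricsReport",
    "running_average",
    "ensemble_bias_var_mse",
    "batch_means_avar",
    "stein_kernel",
    "ksd",
    "em_stationary_law",
]


def running_average(values):
    """Prefix means: element K-1 is the mean of the first K values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("running_average needs a non-empty sequence")
    return np.cumsum(arr) / np.arange(1, arr.size + 1)


def ensemble_bias_var_mse(observable_curves, reference):
    """Bias, variance and MSE of the time-average estimator across chains.

    ``observable_curves`` is an (M, P) array of per-chain running averages
    at P checkpoints; ``reference`` is E_pi[phi] (analytic or from a long
    reference run).  Variance uses the population (1/M) form, matching
    its definition as a plug-in second moment.  Returns (bias, var, mse),
    each of length P, with mse = bias^2 + var.
    """
    curves = np.atleast_2d(np.asarray(observable_curves, dtype=float))
    if curves.shape[0] < 2:
        raise InvalidInputError("variance needs at least two chains")
    bias = curves.mean(axis=0) - reference
    var = curves.var(axis=0, ddof=0)
    return bias, var, bias**2 + var


def batch_means_avar(series, h, burn_in_steps=0, n_batches=20):
    """Batch-means estimate of the asymptotic variance of one chain.

    Discards ``burn_in_steps`` values, splits the remaining K' into
    ``n_batches`` contiguous batches of L = floor(K'/n_batches) (tail
    remainder dropped), and returns L h Var(batch means) with the
    unbiased sample variance — the finite-K version of
    K h Var(phi-bar_K).
    """
    arr = np.asarray(series, dtype=float).ravel()
    usable = arr.size - burn_in_steps
    if usable < 2 * n_batches:
        raise InvalidInputError(
            f"series too short: need at least {burn_in_steps + 2 * n_batches} "
            f"values, got {arr.size}")
    batch_len = usable // n_batches
    trimmed = arr[burn_in_steps:burn_in_steps + n_batches * batch_len]
    means = trimmed.reshape(n_batches, batch_len).mean(axis=1)
    return batch_len * h * means.var(ddof=1)


# ---------------------------------------------------------------------------
# kernelized Stein discrepancy
# ---------------------------------------------------------------------------

@dataclass
class KSDConfig:
    """Inverse multiquadric kernel and evaluation settings.

    ``kernel_exponent`` must lie in (-1, 0); the defaults (c = 1,
    exponent -1/2) are the standard convergence-controlling choice.
    """

    kernel_scale: float = 1.0
    kernel_exponent: float = -0.5
    block_size: int = 1024
    evaluation_points: Optional[np.ndarray] = None
    normalized: bool = True

    def __post_init__(self):
        if self.kernel_scale <= 0:
            raise InvalidInputError("kernel_scale must be positive")
        if not -1.0 < self.kernel_exponent < 0.0:
            raise InvalidInputError("kernel_exponent must lie in (-1, 0)")
        if self.block_size < 1:
            raise InvalidInputError("block_size must be >= 1")


def stein_kernel(x, y, grad_log_density, config: Optional[KSDConfig] = None):
    """Componentwise Stein kernel r0^j(x, y), j = 1..d.

    r0^j = b_j(x) b_j(y) r + b_j(x) d_{y_j} r + b_j(y) d_{x_j} r
           + d_{x_j} d_{y_j} r,   b_j = d_j log pi,

    with analytic derivatives of the inverse multiquadric kernel.
    """
    config = config or KSDConfig()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidInputError("x and y must share a dimension")
    bx = np.asarray(grad_log_density(x), dtype=float).ravel()
    by = np.asarray(grad_log_density(y), dtype=float).ravel()
    c2 = config.kernel_scale**2
    p = config.kernel_exponent
    diff = x - y
    u = c2 + diff @ diff
    r = u**p
    # d_{x_j} r = 2 p u^{p-1} diff_j ; d_{y_j} r = -2 p u^{p-1} diff_j
    du = p * u**(p - 1)
    dxr = 2.0 * du * diff
    dyr = -dxr
    # d_{x_j} d_{y_j} r = -2 p u^{p-1} - 4 p (p-1) u^{p-2} diff_j^2
    dxdyr = -2.0 * du - 4.0 * p * (p - 1) * u**(p - 2) * diff**2
    return bx * by * r + bx * dyr + by * dxr + dxdyr


def _pair_block_sums(xa, sa, xb, sb, c2, p):
    """sum over pairs (a, b) of r0^j(x_a, x_b), componentwise (length d)."""
    diff = xa[:, None, :] - xb[None, :, :]          # (a, b, d)
    u = c2 + np.einsum("abd,abd->ab", diff, diff)
    r = u**p
    du = p * u**(p - 1)
    du2 = p * (p - 1) * u**(p - 2)
    t1 = np.einsum("aj,ab,bj->j", sa, r, sb)
    # b_j(x) d_{y_j} r + b_j(y) d_{x_j} r = 2 du diff_j (b_j(y) - b_j(x))
    t23 = 2.0 * (np.einsum("ab,abj,bj->j", du, diff, sb)
                 - np.einsum("ab,abj,aj->j", du, diff, sa))
    t4 = -2.0 * du.sum() - 4.0 * np.einsum("ab,abj->j", du2, diff**2)
    return t1 + t23 + t4


def ksd(samples, grad_log_density, config: Optional[KSDConfig] = None):
    """Kernelized Stein discrepancy of an empirical sample.

    Returns ``(value, curve)`` where ``value`` is the KSD of all K
    samples and ``curve`` is an array of KSD values at the prefix sizes
    ``config.evaluation_points`` (empty when unset).  In the normalized
    form (default) w_j = (1/K) sqrt(sum_{k,k'} r0^j) so the discrepancy
    of i.i.d. exact samples decays as K^{-1/2}; the raw pairwise sum is
    available with ``normalized=False``.  Pairwise sums are evaluated
    blockwise with cumulative prefix bookkeeping, so the whole curve
    costs a single O(K^2) pass.
    """
    config = config or KSDConfig()
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    n, d = x.shape
    if n < 1:
        raise InvalidInputError("ksd needs at least one sample")
    scores = np.atleast_2d(np.asarray(grad_log_density(x), dtype=float))
    c2 = config.kernel_scale**2
    p = config.kernel_exponent
    block = config.block_size

    if config.evaluation_points is None:
        points = np.array([n])
    else:
        points = np.asarray(sorted({int(q) for q in config.evaluation_points
                                    if 1 <= int(q) <= n}))
        if points.size == 0 or points[-1] != n:
            points = np.append(points, n)

    pair_sum = np.zeros(d)
    values = np.empty(points.size)
    prev = 0
    for pi, endpoint in enumerate(points):
        # add pairs involving samples [prev, endpoint)
        for a0 in range(prev, endpoint, block):
            a1 = min(a0 + block, endpoint)
            xa, sa = x[a0:a1], scores[a0:a1]
            # cross terms with everything before the new segment (x2 by symmetry)
            for b0 in range(0, prev, block):
                b1 = min(b0 + block, prev)
                pair_sum += 2.0 * _pair_block_sums(xa, sa, x[b0:b1],
                                                   scores[b0:b1], c2, p)
            # within the new segment: earlier new blocks (x2) plus own block
            for b0 in range(prev, a0, block):
                b1 = min(b0 + block, a0)
                pair_sum += 2.0 * _pair_block_sums(xa, sa, x[b0:b1],
                                                   scores[b0:b1], c2, p)
            pair_sum += _pair_block_sums(xa, sa, xa, sa, c2, p)
        if not np.all(np.isfinite(pair_sum)):
            raise InvalidInputError(
                f"non-finite Stein-kernel sum below prefix size {endpoint}")
        w = np.sqrt(np.clip(pair_sum, 0.0, None))
        if config.normalized:
            w = w / endpoint
        values[pi] = np.linalg.norm(w)
        prev = endpoint

    return values[-1], {"k": points, "ksd": values}


# ---------------------------------------------------------------------------
# exact discrete-time oracle for linear recurrences
# ---------------------------------------------------------------------------

def em_stationary_law(drift_matrix, drift_offset, noise_covariance, h):
    """Stationary mean and covariance of a linear Euler-Maruyama chain.

    The recurrence theta' = (I - h A) theta + h offset + sqrt(h) xi with
    xi ~ N(0, Q) has stationary mean solving A m = offset and covariance
    solving the discrete Lyapunov equation
    Sigma = (I - h A) Sigma (I - h A)^T + h Q.
    """
    a = np.atleast_2d(np.asarray(drift_matrix, dtype=float))
    offset = np.atleast_1d(np.asarray(drift_offset, dtype=float))
    q = np.atleast_2d(np.asarray(noise_covariance, dtype=float))
    d = a.shape[0]
    if a.shape != (d, d) or q.shape != (d, d) or offset.shape != (d,):
        raise InvalidInputError("drift matrix, offset and noise covariance "
                                "must be conformable")
    prop = np.eye(d) - h * a
    radius = np.abs(np.linalg.eigvals(prop)).max()
    if radius >= 1.0:
        raise InvalidInputError(
            f"unstable recurrence: spectral radius of (I - hA) is "
            f"{radius:.4f} >= 1; reduce the step size h")
    mean = np.linalg.solve(a, offset)
    cov = solve_discrete_lyapunov(prop, h * q)
    return mean, 0.5 * (cov + cov.T)


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Collected metrics of one ensemble run of one sampler kind.

    Curves are indexed by the chain-length checkpoints ``eval_points``.
    ``avar_mean``/``avar_std`` hold the across-chain mean and standard
    deviation of per-chain batch-means asymptotic-variance estimates.
    """

    kind: str
    observables: tuple
    eval_points: np.ndarray
    avar_mean: Dict[str, float]
    avar_std: Dict[str, float]
    avar_per_chain: Dict[str, np.ndarray]
    running_mean_curves: Dict[str, np.ndarray]  # name -> (P, M)
    bias_curve: Optional[Dict[str, np.ndarray]] = None
    variance_curve: Optional[Dict[str, np.ndarray]] = None
    mse_curve: Optional[Dict[str, np.ndarray]] = None
    ksd_curve: Optional[Dict[str, np.ndarray]] = None  # {"k":..., "mean":..., "per_chain":...}
    n_chains: int = 0
    n_failed: int = 0
    provenance: Dict = field(default_factory=dict)

    def to_json_dict(self):
        def _clean(value):
            if isinstance(value, dict):
                return {k: _clean(v) for k, v in value.items()}
            if isinstance(value, np.ndarray):
                return value.tolist()
            if isinstance(value, (np.floating, np.integer)):
                return value.item()
            return value

        return {
            "kind": self.kind,
            "observables": list(self.observables),
            "n_chains": self.n_chains,
            "n_failed": self.n_failed,
            "avar_mean": _clean(self.avar_mean),
            "avar_std": _clean(self.avar_std),
            "provenance": _clean(self.provenance),
        }

    def curves_frame(self):
        """Long-form curves table: (kind, chain_id, K, observable, value)."""
        import pandas as pd

        rows = []
        for name, curves in self.running_mean_curves.items():
            p, m = curves.shape
            for chain in range(m):
                rows.append(pd.DataFrame({
                    "kind": self.kind, "chain_id": chain,
                    "K": self.eval_points, "observable": name,
                    "value": curves[:, chain]}))
        if self.ksd_curve is not None:
            rows.append(pd.DataFrame({
                "kind": self.kind, "chain_id": -1,
                "K": self.ksd_curve["k"], "observable": "ksd_mean",
                "value": self.ksd_curve["mean"]}))
        if not rows:
            return pd.DataFrame(
                columns=["kind", "chain_id", "K", "observable", "value"])
        return pd.concat(rows, ignore_index=True)
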