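"""Skew-symmetric generators and drift/diffusion assembly.

Five Langevin SDEs share the invariant density pi(theta):

========  =====================================================  ==================
kind      drift b(theta)                                         diffusion sigma
========  =====================================================  ==================
LD        beta grad log pi                                       sqrt(2 beta) I
RM        beta B grad log pi + beta div B                        sqrt(2 beta B)
Irr       (beta I + J) grad log pi                               sqrt(2 beta) I
RMIrr     (beta B + J) grad log pi + beta div B                  sqrt(2 beta B)
GiIrr     (beta B + C) grad log pi + div(beta B + C)             sqrt(2 beta B)
========  =====================================================  ==================

with B(theta) a symmetric positive-definite metric, J a constant
skew-symmetric matrix, and the geometry-informed skew field
``C(theta) = (J B(theta) + B(theta) J) / 2``.  Because C inherits its
state dependence from B, the correction ``div C`` is assembled exactly
from the metric derivative tensor rather than by numerical
differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .targets import TargetModel

__all__ = [
    "KINDS",
    "PerturbationSpec",
    "DriftDiffusion",
    "build_skew",
    "giirr_C",
    "giirr_divC",
    "drift_diffusion",
    "drift_diffusion_multi",
]

#: canonical sampler kinds, in the order of the summary table above
KINDS = ("ld", "rm", "irr", "rmirr", "giirr")
_METRIC_KINDS = frozenset({"rm", "rmirr", "giirr"})
_SKEW_KINDS = frozenset({"irr", "rmirr", "giirr"})


def canonical_kind(kind: str) -> str:
    k = str(kind).lower()
    if k not in KINDS:
        raise InvalidInputError(f"unknown sampler kind {kind!r}; choose from {KINDS}")
    return k


def _check_skew(j, d=None):
    j = np.asarray(j, dtype=float)
    if j.ndim != 2 or j.shape[0] != j.shape[1]:
        raise InvalidInputError("skew matrix must be square")
    if d is not None and j.shape[0] != d:
        raise InvalidInputError(f"skew matrix has size {j.shape[0]}, expected {d}")
    if np.any(j + j.T != 0.0):
        raise InvalidInputError("matrix is not exactly skew-symmetric")
    return j


def build_skew(pattern, d, delta=1.0, seed=None, norm_target=None, norm="spectral"):
    """Construct a skew-symmetric matrix J.

    Patterns
    --------
    ``dense_upper_ones``
        All-ones strict upper triangle minus its transpose, scaled by
        ``delta`` (the canonical 3x3 choice has rows [0,1,1], [-1,0,1],
        [-1,-1,0]).  ``norm_target`` is ignored.
    ``random_pm1``
        Seeded lower-triangular matrix with entries drawn from {+1, -1},
        minus its transpose, zero diagonal, rescaled to ``norm_target``
        (default 1).
    ``kronecker``
        ``(I_m kron C0) + (C0 kron I_m)`` for ``d = m^2``, with C0
        following the dense-upper-ones sign pattern, rescaled to
        ``norm_target`` (default 1).

    ``norm`` selects the rescaling norm: ``"spectral"`` (default; it
    bounds the stiffness J contributes to the drift) or ``"fro"``.
    """
    if d < 2:
        raise InvalidInputError("skew matrices need dimension d >= 2")
    if norm_target is not None and norm_target <= 0:
        raise InvalidInputError("norm_target must be positive")

    def _rescale(j, target):
        size = np.linalg.norm(j, 2) if norm == "spectral" else np.linalg.norm(j, "fro")
        if size == 0:
            raise InvalidInputError("cannot rescale a zero matrix")
        return j * (target / size)

    if pattern == "dense_upper_ones":
        upper = np.triu(np.ones((d, d)), k=1)
        return delta * (upper - upper.T)
    if pattern == "random_pm1":
        rng = np.random.default_rng(seed)
        lower = np.tril(rng.choice([-1.0, 1.0], size=(d, d)), k=-1)
        j = lower - lower.T
        np.fill_diagonal(j, 0.0)
        return _rescale(j, 1.0 if norm_target is None else norm_target)
    if pattern == "kronecker":
        m = int(round(np.sqrt(d)))
        if m * m != d:
            raise InvalidInputError("kronecker pattern needs d = m^2")
        upper = np.triu(np.ones((m, m)), k=1)
        c0 = upper - upper.T
        j = np.kron(np.eye(m), c0) + np.kron(c0, np.eye(m))
        return _rescale(j, 1.0 if norm_target is None else norm_target)
    raise InvalidInputError(f"unknown skew pattern {pattern!r}")


def giirr_C(B, J):
    """Geometry-informed skew field C = (J B + B J) / 2 (batched over B)."""
    B = np.asarray(B, dtype=float)
    J = _check_skew(J)
    if B.shape[-1] != B.shape[-2] or B.shape[-1] != J.shape[0]:
        raise InvalidInputError("B and J must be conformable square matrices")
    return 0.5 * (J @ B + B @ J)


def giirr_divC(metric_deriv, J):
    """Divergence of C = (J B + B J)/2 from the metric derivative tensor.

    ``metric_deriv[..., i, j, k] = dB_ij / dtheta_k``; the result has
    components ``(div C)_i = sum_j dC_ij/dtheta_j``, i.e.

        (1/2) [ J (div B) ]_i + (1/2) sum_{j,k} dB_ik/dtheta_j J_kj.
    """
    t = np.asarray(metric_deriv, dtype=float)
    J = _check_skew(J)
    d = J.shape[0]
    if t.shape[-3:] != (d, d, d):
        raise InvalidInputError("metric_deriv must have trailing shape (d, d, d)")
    div_b = np.einsum("...kjj->...k", t)
    term1 = div_b @ J.T
    term2 = np.einsum("...ikj,kj->...i", t, J)
    return 0.5 * (term1 + term2)


@dataclass
class PerturbationSpec:
    """Which sampler to run and with what temperature / skew generator.

    ``skew`` is ignored by kinds ld and rm; the target's metric is ignored
    by kinds ld and irr.  ``scale`` records the delta used to build the
    skew matrix (provenance only; delta is already folded into ``skew``).
    """

    kind: str
    temperature: float = 0.5
    skew: Optional[np.ndarray] = None
    scale: float = 1.0

    def __post_init__(self):
        self.kind = canonical_kind(self.kind)
        if self.temperature <= 0:
            raise InvalidInputError("temperature beta must be positive")
        if self.skew is not None:
            self.skew = _check_skew(self.skew)
        if self.kind in _SKEW_KINDS and self.skew is None:
            raise ConfigurationError(f"kind {self.kind!r} needs a skew matrix J")


@dataclass
class DriftDiffusion:
    """Drift and diffusion-factor pair of one sampler, batched over states.

    ``diffusion_factor`` always satisfies sigma sigma^T = 2 beta B (B = I
    for the metric-free kinds).  When the factor does not depend on the
    state it is exposed through ``constant_factor`` (a scalar for
    sqrt(2 beta) I, else a (d, d) matrix) so integrators can skip the
    per-step matrix multiply.
    """

    kind: str
    dim: int
    _evaluate: Callable = field(repr=False)
    constant_factor: Optional[np.ndarray] = None
    _diffusion: Optional[Callable] = field(default=None, repr=False)

    def evaluate(self, states, minibatch_idx=None):
        """Return (drift (M, d), factor (M, d, d) or None if constant)."""
        return self._evaluate(states, minibatch_idx)

    def drift(self, state, minibatch_idx=None):
        arr = np.asarray(state, dtype=float)
        single = arr.ndim == 1
        b, _ = self._evaluate(arr[None, :] if single else arr, minibatch_idx)
        return b[0] if single else b

    def diffusion_factor(self, state):
        arr = np.asarray(state, dtype=float)
        single = arr.ndim == 1
        x = arr[None, :] if single else arr
        if self.constant_factor is not None:
            cf = np.asarray(self.constant_factor, dtype=float)
            if cf.ndim == 0:
                cf = cf * np.eye(self.dim)
            out = np.broadcast_to(cf, (x.shape[0], self.dim, self.dim))
        else:
            out = self._diffusion(x)
        return out[0] if single else out


def drift_diffusion(kind, target: TargetModel, pert: PerturbationSpec) -> DriftDiffusion:
    """Assemble the drift/diffusion pair of one sampler kind for a target."""
    kind = canonical_kind(kind)
    beta = pert.temperature
    d = target.dim
    needs_metric = kind in _METRIC_KINDS
    if needs_metric and not target.has_metric:
        raise ConfigurationError(
            f"kind {kind!r} requires a metric but {type(target).__name__} has none"
        )
    J = None
    if kind in _SKEW_KINDS:
        if pert.skew is None:
            raise ConfigurationError(f"kind {kind!r} needs a skew matrix J")
        J = _check_skew(pert.skew, d)

    def _grad(x, idx):
        if idx is None:
            return target._grad(x)
        return target._minibatch_grad(x, idx)

    sqrt_2b = np.sqrt(2.0 * beta)

    if kind == "ld":
        def evaluate(x, idx):
            return beta * _grad(x, idx), None
        return DriftDiffusion(kind, d, evaluate, constant_factor=np.asarray(sqrt_2b))

    if kind == "irr":
        mat = (beta * np.eye(d) + J).T  # right-multiplied below

        def evaluate(x, idx):
            return _grad(x, idx) @ mat, None
        return DriftDiffusion(kind, d, evaluate, constant_factor=np.asarray(sqrt_2b))

    if target.constant_metric:
        # Pre-assemble the affine pieces once; B, C, div-terms are constant.
        b_mat = target.metric(np.zeros(d))
        factor = sqrt_2b * target.metric_sqrt(np.zeros(d))
        if kind == "rm":
            eff = (beta * b_mat).T
        elif kind == "rmirr":
            eff = (beta * b_mat + J).T
        else:  # giirr
            eff = (beta * b_mat + giirr_C(b_mat, J)).T

        def evaluate(x, idx):
            return _grad(x, idx) @ eff, None
        return DriftDiffusion(kind, d, evaluate, constant_factor=factor)

    def diffusion(x):
        return sqrt_2b * target._metric_sqrt(x)

    if kind == "rm":
        def evaluate(x, idx):
            g = _grad(x, idx)
            b_mat = target._metric(x)
            drift = beta * (np.einsum("mij,mj->mi", b_mat, g) + target._metric_div(x))
            return drift, diffusion(x)
    elif kind == "rmirr":
        def evaluate(x, idx):
            g = _grad(x, idx)
            b_mat = target._metric(x)
            drift = (beta * np.einsum("mij,mj->mi", b_mat, g)
                     + g @ J.T
                     + beta * target._metric_div(x))
            return drift, diffusion(x)
    else:  # giirr
        def evaluate(x, idx):
            g = _grad(x, idx)
            b_mat = target._metric(x)
            c_mat = 0.5 * (J @ b_mat + b_mat @ J)
            div_b = target._metric_div(x)
            t = target._metric_deriv(x)
            div_c = 0.5 * (div_b @ J.T + np.einsum("mikj,kj->mi", t, J))
            drift = (np.einsum("mij,mj->mi", beta * b_mat + c_mat, g)
                     + beta * div_b + div_c)
            return drift, diffusion(x)

    return DriftDiffusion(kind, d, evaluate, _diffusion=diffusion)


def drift_diffusion_multi(kind_labels, target: TargetModel,
                          pert: PerturbationSpec) -> DriftDiffusion:
    """Drift/diffusion over a heterogeneous chain stack, one kind per chain.

    All chains share the target, temperature and skew matrix; chain ``i``
    follows sampler ``kind_labels[i]``.  Per-chain drifts and diffusion
    factors equal those of :func:`drift_diffusion` for the corresponding
    kind (the shared geometric quantities are computed once per step),
    which lets an ensemble mixing several kinds advance in one lock-step
    pass.  ``em_step``-level equality with the per-kind assembly is
    asserted in the test-suite.
    """
    labels = [canonical_kind(k) for k in kind_labels]
    beta = pert.temperature
    d = target.dim
    m_total = len(labels)
    metric_mask = np.array([k in _METRIC_KINDS for k in labels])
    irr_mask = np.array([k in ("irr", "rmirr") for k in labels])
    gi_mask = np.array([k == "giirr" for k in labels])
    need_metric = metric_mask.any()
    need_skew = (irr_mask | gi_mask).any()
    if need_metric and not target.has_metric:
        raise ConfigurationError("metric-based kinds on a metric-free target")
    J = None
    if need_skew:
        if pert.skew is None:
            raise ConfigurationError("irreversible kinds need a skew matrix J")
        J = _check_skew(pert.skew, d)
    sqrt_2b = np.sqrt(2.0 * beta)
    eye = np.eye(d)

    def _grad(x, idx):
        return target._grad(x) if idx is None else target._minibatch_grad(x, idx)

    if not need_metric:
        mat = np.where(irr_mask[:, None, None], beta * eye + (J if J is not None
                                                              else eye), beta * eye)

        def evaluate(x, idx):
            g = _grad(x, idx)
            return np.einsum("mij,mj->mi", mat, g), None
        return DriftDiffusion("multi", d, evaluate,
                              constant_factor=np.asarray(sqrt_2b))

    if target.constant_metric:
        b_mat = target.metric(np.zeros(d))
        sqrt_b = target.metric_sqrt(np.zeros(d))
        eff = np.empty((m_total, d, d))
        factor = np.empty((m_total, d, d))
        for i, k in enumerate(labels):
            if k == "ld":
                eff[i], factor[i] = beta * eye, eye
            elif k == "irr":
                eff[i], factor[i] = beta * eye + J, eye
            elif k == "rm":
                eff[i], factor[i] = beta * b_mat, sqrt_b
            elif k == "rmirr":
                eff[i], factor[i] = beta * b_mat + J, sqrt_b
            else:
                eff[i], factor[i] = beta * b_mat + giirr_C(b_mat, J), sqrt_b
        factor = sqrt_2b * factor

        def evaluate(x, idx):
            g = _grad(x, idx)
            return np.einsum("mij,mj->mi", eff, g), factor
        return DriftDiffusion("multi", d, evaluate)

    mmask = metric_mask[:, None, None]
    vmask = metric_mask[:, None]
    iv = irr_mask[:, None]
    gv = gi_mask[:, None]
    need_gi = gi_mask.any()

    need_irr = irr_mask.any()
    jt = J.T if J is not None else None

    def evaluate(x, idx):
        g = _grad(x, idx)
        b_mat = np.where(mmask, target._metric(x), eye)
        div_b = target._metric_div(x)
        eff = beta * b_mat
        if need_gi:
            c_mat = 0.5 * (J @ b_mat + b_mat @ J)
            eff = eff + np.where(gi_mask[:, None, None], c_mat, 0.0)
        drift = np.einsum("mij,mj->mi", eff, g)
        drift += beta * (div_b * vmask)
        if need_irr:
            drift += (g @ jt) * iv
        if need_gi:
            t = target._metric_deriv(x)
            div_c = 0.5 * (div_b @ jt + np.einsum("mikj,kj->mi", t, J))
            drift += div_c * gv
        sigma = np.where(mmask, sqrt_2b * target._metric_sqrt(x), sqrt_2b * eye)
        return drift, sigma

    return DriftDiffusion("multi", d, evaluate)
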