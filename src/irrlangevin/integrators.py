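"""Euler-Maruyama simulation of the perturbed Langevin SDEs.

The integrator advances all chains of an ensemble in lock-step as one
``(M, d)`` state array, which is what makes ensembles of 10^6-step
chains feasible in pure numpy.  Determinism contract:

* every chain owns a named random stream derived from its seed;
* Gaussian noise and minibatch-index draws use *separate* substreams,
  so switching stochastic gradients on or off never perturbs the noise
  sequence;
* ensemble chain ``i`` uses a seed derived from ``(base_seed, i)``, and
  simulating chain ``i`` alone with that seed reproduces its trajectory
  bit for bit.

Observables are evaluated at theta_0 .. theta_{K-1} (the estimator
averages K terms starting at the initial state); stored states include
theta_0 and run through theta_K.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .errors import InvalidInputError, NumericalDomainError
from .perturbations import DriftDiffusion, PerturbationSpec, drift_diffusion
from .targets import TargetModel

__all__ = [
    "SamplerConfig",
    "ChainResult",
    "em_step",
    "stochastic_gradient",
    "draw_minibatch_indices",
    "run_chain",
    "run_ensemble",
    "simulate_ensemble",
    "derive_chain_seed",
    "BatchMeansCollector",
    "RunningMeanCollector",
    "StateCollector",
    "ObservableCollector",
]

#: steps simulated between bulk random draws; fixed so that chunking never
#: affects the random stream.
_CHUNK = 4096


@dataclass
class SamplerConfig:
    """Discretization, length, seeding and minibatching of one run."""

    step_size: float
    n_steps: int
    initial_state: np.ndarray
    burn_in_steps: int = 0
    seed: int = 0
    minibatch_size: Optional[int] = None
    with_replacement: bool = False

    def __post_init__(self):
        if self.step_size <= 0:
            raise InvalidInputError("step_size must be positive")
        if self.n_steps < 0:
            raise InvalidInputError("n_steps must be >= 0")
        if self.n_steps > 0 and not 0 <= self.burn_in_steps < self.n_steps:
            raise InvalidInputError("need 0 <= burn_in_steps < n_steps")
        if self.minibatch_size is not None and self.minibatch_size < 1:
            raise InvalidInputError("minibatch_size must be >= 1")
        self.initial_state = np.asarray(self.initial_state, dtype=float)

    @property
    def total_time(self):
        return self.n_steps * self.step_size

    def digest(self):
        payload = {
            "step_size": self.step_size,
            "n_steps": self.n_steps,
            "burn_in_steps": self.burn_in_steps,
            "seed": self.seed,
            "minibatch_size": self.minibatch_size,
            "with_replacement": self.with_replacement,
            "initial_state": np.asarray(self.initial_state).tolist(),
        }
        text = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class ChainResult:
    """States and observable series of one chain, with provenance."""

    states: np.ndarray  # (n_stored, d); includes the initial state
    observable_values: Dict[str, np.ndarray]  # name -> (K,)
    seed: int
    config_digest: str
    failed_at: Optional[int] = None  # step index of domain failure, if any


def derive_chain_seed(base_seed, chain_id):
    """Deterministic per-chain seed from (base_seed, chain_id); < 2^31."""
    state = np.random.SeedSequence([int(base_seed), int(chain_id)]).generate_state(1)
    return int(state[0] & 0x7FFFFFFF)


def _chain_streams(seed, want_minibatch):
    noise = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(0,)))
    mb = None
    if want_minibatch:
        mb = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(1,)))
    return noise, mb


def draw_minibatch_indices(rng, n_draws, n_data, n, with_replacement=False):
    """Draw ``n_draws`` index sets of size ``n`` from ``range(n_data)``."""
    if not 1 <= n <= n_data:
        raise InvalidInputError(f"minibatch size {n} outside [1, {n_data}]")
    if with_replacement:
        return rng.integers(0, n_data, size=(n_draws, n))
    if n == n_data:
        return np.broadcast_to(np.arange(n_data), (n_draws, n_data)).copy()
    keys = rng.random((n_draws, n_data))
    return np.argpartition(keys, n - 1, axis=1)[:, :n]


def stochastic_gradient(target: TargetModel, state, n, with_replacement=False,
                        rng=None):
    """One stochastic-gradient draw: prior + (N/n)-scaled subsample sum."""
    rng = np.random.default_rng(rng)
    idx = draw_minibatch_indices(rng, 1, target.n_data, n, with_replacement)
    return target.minibatch_grad(state, idx[0])


def em_step(state, dd: DriftDiffusion, h, noise):
    """One Euler-Maruyama step theta + h b(theta) + sqrt(h) sigma(theta) xi.

    ``noise`` carries externally supplied unit-variance components.
    """
    state = np.asarray(state, dtype=float)
    noise = np.asarray(noise, dtype=float)
    drift = dd.drift(state)
    if not np.all(np.isfinite(drift)):
        raise NumericalDomainError("non-finite drift in em_step", state=state)
    if dd.constant_factor is not None and np.ndim(dd.constant_factor) == 0:
        incr = h * drift + np.sqrt(h) * float(dd.constant_factor) * noise
    else:
        sigma = dd.diffusion_factor(state)
        incr = h * drift + np.sqrt(h) * sigma @ noise
    return state + incr


# ---------------------------------------------------------------------------
# streaming collectors
# ---------------------------------------------------------------------------

class _Collector:
    wants_states = False

    def start(self, n_obs, n_chains, n_steps, dim):
        pass

    def consume(self, offset, obs_chunk, state_chunk):
        """``obs_chunk``: (n_obs, L, M) values of f(theta_k), k = offset..;
        ``state_chunk``: (L, M, d) post-step states theta_{k+1} (or None)."""

    def finish(self, alive):
        pass


class ObservableCollector(_Collector):
    """Stores the full per-step observable series (memory permitting)."""

    def start(self, n_obs, n_chains, n_steps, dim):
        self.values = np.empty((n_obs, n_steps, n_chains))

    def consume(self, offset, obs_chunk, state_chunk):
        self.values[:, offset:offset + obs_chunk.shape[1]] = obs_chunk


class StateCollector(_Collector):
    """Stores every ``thin``-th state (step indices 0, thin, 2 thin, ...)."""

    wants_states = True

    def __init__(self, thin=1):
        if thin < 1:
            raise InvalidInputError("thin must be >= 1")
        self.thin = thin

    def start(self, n_obs, n_chains, n_steps, dim):
        n_stored = n_steps // self.thin + 1
        self.states = np.empty((n_stored, n_chains, dim))
        self.step_indices = np.arange(n_stored) * self.thin

    def set_initial(self, x0):
        self.states[0] = x0

    def consume(self, offset, obs_chunk, state_chunk):
        length = state_chunk.shape[0]
        # stored step k corresponds to state theta_k = state_chunk[k-offset-1]
        first = ((offset + self.thin) // self.thin) * self.thin
        ks = np.arange(first, offset + length + 1, self.thin)
        if ks.size:
            self.states[ks // self.thin] = state_chunk[ks - offset - 1]


class BatchMeansCollector(_Collector):
    """Streaming contiguous-batch sums for the batch-means estimator.

    Discards ``burn_in_steps``, splits the remaining K' observations into
    ``n_batches`` batches of length floor(K'/n_batches) (tail remainder
    dropped) and accumulates per-batch sums per chain.
    """

    def __init__(self, burn_in_steps, n_batches=20):
        self.burn_in = burn_in_steps
        self.n_batches = n_batches

    def start(self, n_obs, n_chains, n_steps, dim):
        usable = n_steps - self.burn_in
        self.batch_len = usable // self.n_batches
        if self.batch_len < 1:
            raise InvalidInputError(
                f"series too short for {self.n_batches} batches: needs at least "
                f"{self.burn_in + self.n_batches} steps")
        self.sums = np.zeros((n_obs, self.n_batches, n_chains))

    def consume(self, offset, obs_chunk, state_chunk):
        length = obs_chunk.shape[1]
        lo = max(self.burn_in, offset)
        hi = min(offset + length, self.burn_in + self.n_batches * self.batch_len)
        k = lo
        while k < hi:
            b = (k - self.burn_in) // self.batch_len
            batch_end = self.burn_in + (b + 1) * self.batch_len
            j = min(hi, batch_end)
            self.sums[:, b] += obs_chunk[:, k - offset:j - offset].sum(axis=1)
            k = j

    def batch_means(self):
        return self.sums / self.batch_len

    def asymptotic_variance(self, h):
        """Per-chain batch-means estimate: L h Var(batch means), ddof=1."""
        means = self.batch_means()
        return self.batch_len * h * means.var(axis=1, ddof=1)


class RunningMeanCollector(_Collector):
    """Running averages (1/K) sum_{k<K} f(theta_k) at chosen K values."""

    def __init__(self, eval_points):
        pts = np.asarray(sorted(set(int(p) for p in eval_points)))
        if pts.size and pts[0] < 1:
            raise InvalidInputError("evaluation points must be >= 1")
        self.eval_points = pts

    def start(self, n_obs, n_chains, n_steps, dim):
        self.eval_points = self.eval_points[self.eval_points <= n_steps]
        self.curves = np.empty((n_obs, self.eval_points.size, n_chains))
        self._running = np.zeros((n_obs, n_chains))
        self._next = 0

    def consume(self, offset, obs_chunk, state_chunk):
        length = obs_chunk.shape[1]
        end = offset + length
        while self._next < self.eval_points.size and self.eval_points[self._next] <= end:
            k = self.eval_points[self._next]
            partial = obs_chunk[:, :k - offset].sum(axis=1)
            self.curves[:, self._next] = (self._running + partial) / k
            self._next += 1
        self._running += obs_chunk.sum(axis=1)


# ---------------------------------------------------------------------------
# the lock-step kernel
# ---------------------------------------------------------------------------

def simulate_ensemble(target: TargetModel, dd: DriftDiffusion,
                      initial_states, h, n_steps, chain_seeds,
                      minibatch_size=None, with_replacement=False,
                      observables: Optional[Dict[str, Callable]] = None,
                      collectors: Sequence[_Collector] = ()):
    """Advance M chains in lock-step; feed observables/states to collectors.

    ``observables`` maps names to vectorized callables on ``(..., d)``
    state stacks returning ``(...)`` values.  Returns
    ``(final_states, alive_mask, fail_steps)``; a chain that leaves the
    admissible domain is frozen at its last valid state and flagged.
    """
    x = np.array(initial_states, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n_chains, d = x.shape
    observables = observables or {}
    obs_fns = list(observables.values())
    n_obs = len(obs_fns)
    want_states = any(c.wants_states for c in collectors)

    for c in collectors:
        c.start(n_obs, n_chains, n_steps, dim=d)
        if isinstance(c, StateCollector):
            c.set_initial(x)

    streams = [_chain_streams(s, minibatch_size is not None) for s in chain_seeds]
    if len(streams) != n_chains:
        raise InvalidInputError("need one seed per chain")
    noise_gens = [s[0] for s in streams]
    mb_gens = [s[1] for s in streams]

    sqrt_h = np.sqrt(h)
    alive = np.ones(n_chains, dtype=bool)
    fail_steps = np.full(n_chains, -1, dtype=int)
    const = dd.constant_factor
    const_scalar = const is not None and np.ndim(const) == 0
    if const is not None and not const_scalar:
        const_t = np.asarray(const).T

    for start in range(0, n_steps, _CHUNK):
        length = min(_CHUNK, n_steps - start)
        noise = np.stack([g.standard_normal((length, d)) for g in noise_gens], axis=1)
        idx = None
        if minibatch_size is not None:
            idx = np.stack(
                [draw_minibatch_indices(g, length, target.n_data, minibatch_size,
                                        with_replacement) for g in mb_gens],
                axis=1)  # (L, M, n)
        pre_states = np.empty((length, n_chains, d)) if (n_obs or want_states) else None
        post_states = np.empty((length, n_chains, d)) if want_states else None

        for j in range(length):
            if pre_states is not None:
                pre_states[j] = x
            b, sigma = dd.evaluate(x, idx[j] if idx is not None else None)
            if const_scalar:
                new = x + h * b + (sqrt_h * float(const)) * noise[j]
            elif const is not None:
                new = x + h * b + sqrt_h * (noise[j] @ const_t)
            else:
                new = x + h * b + sqrt_h * np.einsum("mij,mj->mi", sigma, noise[j])
            # target.admissible always subsumes finiteness of the state
            ok = target.admissible(new)
            if not ok.all() or not alive.all():
                newly = alive & ~ok
                if newly.any():
                    fail_steps[newly] = start + j
                    alive = alive & ok
                new = np.where(alive[:, None], new, x)
            x = new
            if post_states is not None:
                post_states[j] = x

        if n_obs:
            obs_chunk = np.stack([f(pre_states) for f in obs_fns])  # (n_obs, L, M)
        else:
            obs_chunk = np.empty((0, length, n_chains))
        for c in collectors:
            c.consume(start, obs_chunk, post_states)

    for c in collectors:
        c.finish(alive)
    return x, alive, fail_steps


def _single_chain(target, pert, config, observables, store_states, thin,
                  raise_on_failure):
    observables = observables or {}
    dd = drift_diffusion(pert.kind, target, pert)
    collectors = [ObservableCollector()]
    state_collector = None
    if store_states:
        state_collector = StateCollector(thin=thin)
        collectors.append(state_collector)
    target.check_state(config.initial_state, step=0)
    _, alive, fail_steps = simulate_ensemble(
        target, dd, config.initial_state[None, :], config.step_size,
        config.n_steps, [config.seed],
        minibatch_size=config.minibatch_size,
        with_replacement=config.with_replacement,
        observables=observables, collectors=collectors)
    failed_at = None if alive[0] else int(fail_steps[0])
    if failed_at is not None and raise_on_failure:
        raise NumericalDomainError(
            f"chain left the admissible domain at step {failed_at}",
            step=failed_at)
    obs = {name: collectors[0].values[i, :, 0]
           for i, name in enumerate(observables)}
    states = (state_collector.states[:, 0, :] if store_states
              else config.initial_state[None, :])
    return ChainResult(states=states, observable_values=obs,
                       seed=config.seed, config_digest=config.digest(),
                       failed_at=failed_at)


def run_chain(target: TargetModel, pert: PerturbationSpec, config: SamplerConfig,
              observables: Optional[Dict[str, Callable]] = None,
              store_states=True, thin=1, raise_on_failure=True) -> ChainResult:
    """Simulate one chain; deterministic given ``config.seed``."""
    return _single_chain(target, pert, config, observables, store_states,
                         thin, raise_on_failure)


def run_ensemble(target: TargetModel, pert: PerturbationSpec,
                 config: SamplerConfig, observables=None, n_chains=1,
                 base_seed=0, store_states=False, thin=1) -> List[ChainResult]:
    """Simulate ``n_chains`` chains with independent streams.

    Chain ``i`` is reproducible alone via
    ``run_chain(..., seed=derive_chain_seed(base_seed, i))``.  For large
    ensembles prefer :func:`simulate_ensemble` with streaming collectors;
    this convenience wrapper stores every observable value.
    """
    if n_chains < 1:
        raise InvalidInputError("n_chains must be >= 1")
    observables = observables or {}
    dd = drift_diffusion(pert.kind, target, pert)
    seeds = [derive_chain_seed(base_seed, i) for i in range(n_chains)]
    collectors = [ObservableCollector()]
    state_collector = None
    if store_states:
        state_collector = StateCollector(thin=thin)
        collectors.append(state_collector)
    x0 = np.broadcast_to(config.initial_state,
                         (n_chains, config.initial_state.shape[0]))
    target.check_state(config.initial_state, step=0)
    _, alive, fail_steps = simulate_ensemble(
        target, dd, x0, config.step_size, config.n_steps, seeds,
        minibatch_size=config.minibatch_size,
        with_replacement=config.with_replacement,
        observables=observables, collectors=collectors)
    results = []
    digest = config.digest()
    for i in range(n_chains):
        obs = {name: collectors[0].values[k, :, i]
               for k, name in enumerate(observables)}
        states = (state_collector.states[:, i, :] if store_states
                  else config.initial_state[None, :])
        results.append(ChainResult(
            states=states, observable_values=obs, seed=seeds[i],
            config_digest=digest,
            failed_at=None if alive[i] else int(fail_steps[i])))
    return results
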