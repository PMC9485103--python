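"""Seeded synthetic-data generators, experiment presets, and the runner.

Four study presets wire targets, perturbations, integrators and
diagnostics together:

``gaussian``
    d = 3 conjugate Gaussian posterior; N = 10 observations with total
    data precision N Gamma_X = 0.25 I; prior precision with eigenvalues
    (0.2, 0.01, 0.05) and seeded random eigenvectors; h = 0.005,
    K = 10^5, minibatches of n = 2, zero initial state, metric
    B = Gamma_p^-1 (eigenvalues above one by design; see get_preset).
``normal_params``
    posterior over (mu, sigma) of N = 30 draws from Normal(0, 10^2);
    h = 10^-3, K = 10^6, minibatches of n = 6, burn-in time 10,
    delta = 2, initial state (5, 20), Fisher metric.
``logistic``
    d = 20 Bayesian logistic regression on N = 400 synthetic
    observations; h = 10^-4, K = 4 x 10^5, n = 10, zero initial state,
    metric B = I + G^-1, random +-1 skew normalized to 1.
``ica``
    3 x 3 Bayesian ICA (d = 9) on N = 400 mixed signals (one Laplace and
    two logistic sources); n = 40, Kronecker-structured skew normalized
    to 1.  The default is a desk-scale run (T = 20 at h = 10^-4, 10
    chains); ``paper_scale=True`` restores T = 2000 at h = 2 x 10^-5
    with 100 chains.

All temperatures are beta = 1/2, so the invariant density is the
posterior itself.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from . import diagnostics, targets
from .diagnostics import KSDConfig, MetricsReport, ksd
from .errors import ChainFailureError, InvalidInputError
from .integrators import (BatchMeansCollector, RunningMeanCollector,
                          StateCollector, derive_chain_seed, simulate_ensemble)
from .perturbations import (KINDS, PerturbationSpec, build_skew,
                            canonical_kind, drift_diffusion,
                            drift_diffusion_multi)

__all__ = [
    "ExperimentPreset",
    "get_preset",
    "PRESET_NAMES",
    "make_random_spd",
    "gen_normal_data",
    "gen_ica_data",
    "gen_logistic_data",
    "run_experiment",
    "OBSERVABLES",
]

PRESET_NAMES = ("gaussian", "normal_params", "logistic", "ica")

#: vectorized observables on (..., d) state stacks
OBSERVABLES = {
    "phi1": lambda s: s.sum(axis=-1),
    "phi2": lambda s: np.square(s).sum(axis=-1),
    "phi3": lambda s: np.square(s.sum(axis=-1)),
}


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

def make_random_spd(eigenvalues, seed=None):
    """SPD matrix with the requested spectrum and seeded random eigenvectors."""
    eigs = np.asarray(eigenvalues, dtype=float)
    if np.any(eigs <= 0):
        raise InvalidInputError("all eigenvalues must be positive")
    d = eigs.size
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    q = q * np.sign(np.diag(r))  # fix the sign gauge for determinism
    out = (q * eigs) @ q.T
    return 0.5 * (out + out.T)


def gen_normal_data(n, mu_true=0.0, sigma_true=10.0, seed=None,
                    match_moments=False):
    """N i.i.d. draws from Normal(mu_true, sigma_true^2).

    With ``match_moments`` the realized sample is affinely rescaled so its
    sample mean and standard deviation equal the population values
    exactly.  Sampler-efficiency metrics on this posterior scale steeply
    (roughly quartic for the unperturbed dynamics) in the realized sample
    standard deviation, so pinning these ancillary statistics removes
    dataset-draw luck from cross-run comparisons; see the methods note.
    """
    if sigma_true <= 0:
        raise InvalidInputError("sigma_true must be positive")
    rng = np.random.default_rng(seed)
    data = rng.normal(mu_true, sigma_true, size=int(n))
    if match_moments:
        data = (data - data.mean()) / data.std(ddof=0) * sigma_true + mu_true
    return data


def gen_ica_data(m, n, mixing_seed=None, source_seed=None, max_condition=10.0):
    """Mixed signals X = M s for one Laplace and (m-1) logistic sources.

    The squared-hyperbolic-secant density (1/4) sech^2(y/2) is exactly
    the standard logistic law, so those sources are drawn from it
    directly.  The mixing matrix is seeded random Gaussian, redrawn until
    its condition number is at most ``max_condition``.  Returns
    ``(mixed (N, m) rows of observations, mixing matrix, sources (m, N))``.
    """
    if m < 2:
        raise InvalidInputError("need at least two sources")
    src_rng = np.random.default_rng(source_seed)
    sources = np.empty((m, int(n)))
    sources[0] = src_rng.laplace(0.0, 1.0, size=int(n))
    for i in range(1, m):
        sources[i] = src_rng.logistic(0.0, 1.0, size=int(n))
    mix_rng = np.random.default_rng(mixing_seed)
    for _ in range(1000):
        mixing = mix_rng.standard_normal((m, m))
        if np.linalg.cond(mixing) <= max_condition:
            break
    else:  # pragma: no cover - practically unreachable
        raise InvalidInputError("could not draw a well-conditioned mixing matrix")
    mixed = (mixing @ sources).T
    return mixed, mixing, sources


def gen_logistic_data(n, d, w_true=None, seed=None):
    """Synthetic logistic-regression data: Gaussian features, Bernoulli labels."""
    rng = np.random.default_rng(seed)
    if w_true is None:
        w_true = rng.normal(0.0, 1.0, size=d)
    w_true = np.asarray(w_true, dtype=float)
    features = rng.standard_normal((int(n), int(d)))
    probs = 1.0 / (1.0 + np.exp(-features @ w_true))
    labels = (rng.random(int(n)) < probs).astype(float)
    return features, labels


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass
class ExperimentPreset:
    """All parameters of one simulation study, with the study defaults."""

    name: str
    dim: int
    n_data: int
    minibatch_size: int
    step_size: float
    n_steps: int
    n_chains: int
    burn_in_steps: int = 0
    delta: float = 1.0
    beta: float = 0.5
    with_replacement: bool = False
    observables: Tuple[str, ...] = ("phi1", "phi2")
    skew_pattern: str = "dense_upper_ones"
    skew_norm_target: Optional[float] = None
    data_params: Dict = field(default_factory=dict)

    def replace(self, **overrides):
        """New preset with explicit overrides (unknown keys rejected)."""
        names = {f.name for f in dataclasses.fields(self)}
        bad = set(overrides) - names
        if bad:
            raise InvalidInputError(f"unknown preset overrides: {sorted(bad)}")
        return dataclasses.replace(self, **overrides)

    # -- construction hooks --------------------------------------------------
    def make_data(self, seed):
        p = self.data_params
        if self.name == "gaussian":
            spd_seed, data_seed = _sub_seeds(seed, 2)
            prior_prec = make_random_spd(p["prior_eigenvalues"], spd_seed)
            noise_prec = p["noise_precision_scale"] * np.eye(self.dim)
            rng = np.random.default_rng(data_seed)
            noise_cov_sqrt = targets.spd_sqrt(np.linalg.inv(noise_prec))
            data = rng.standard_normal((self.n_data, self.dim)) @ noise_cov_sqrt.T
            return {"prior_precision": prior_prec, "noise_precision": noise_prec,
                    "data": data}
        if self.name == "normal_params":
            return {"data": gen_normal_data(self.n_data, p["mu_true"],
                                            p["sigma_true"], seed)}
        if self.name == "logistic":
            return dict(zip(("features", "labels"),
                            gen_logistic_data(self.n_data, self.dim, seed=seed)))
        if self.name == "ica":
            mix_seed, src_seed = _sub_seeds(seed, 2)
            mixed, mixing, sources = gen_ica_data(p["m"], self.n_data,
                                                  mix_seed, src_seed)
            return {"mixed": mixed, "mixing": mixing, "sources": sources}
        raise InvalidInputError(f"unknown preset {self.name!r}")

    def make_target(self, data):
        p = self.data_params
        if self.name == "gaussian":
            spec = targets.gaussian_posterior(data["prior_precision"],
                                              data["noise_precision"],
                                              data["data"])
            return spec.make_target(metric="posterior_covariance")
        if self.name == "normal_params":
            return targets.normal_params_model(data["data"])
        if self.name == "logistic":
            return targets.logistic_model(data["features"], data["labels"],
                                          alpha=p["alpha"])
        if self.name == "ica":
            return targets.ica_model(data["mixed"], lam=p["lam"])
        raise InvalidInputError(f"unknown preset {self.name!r}")

    def make_skew(self, seed=None):
        return build_skew(self.skew_pattern, self.dim, delta=self.delta,
                          seed=seed, norm_target=self.skew_norm_target)

    def make_initial(self, seed=None):
        if self.name == "normal_params":
            return np.array([5.0, 20.0])
        if self.name == "ica":
            rng = np.random.default_rng(seed)
            m = self.data_params["m"]
            w0 = np.diag(rng.choice([-1.0, 1.0], size=m))
            return w0.T.reshape(-1)  # column-major vec (diagonal: order moot)
        return np.zeros(self.dim)


def _sub_seeds(seed, n):
    return [int(s) for s in
            np.random.SeedSequence(int(seed)).generate_state(n) & 0x7FFFFFFF]


def get_preset(name, paper_scale=False) -> ExperimentPreset:
    """Study presets with the study defaults (``ica`` defaults to a
    desk-scale run unless ``paper_scale`` is set)."""
    if name == "gaussian":
        # The per-datum noise precision is 0.025 I so the total data
        # precision is N Gamma_X = 0.25 I and the posterior precision has
        # eigenvalues below one: the study's design requires the metric
        # B = Gamma_p^-1 to have eigenvalues greater than one (B - I
        # positive definite), which is what makes the reversible
        # perturbation — and the geometry-informed skew field C, whose
        # norm grows with B — accelerate rather than slow the sampler.
        return ExperimentPreset(
            name="gaussian", dim=3, n_data=10, minibatch_size=2,
            step_size=0.005, n_steps=10**5, n_chains=100, burn_in_steps=0,
            delta=1.0, skew_pattern="dense_upper_ones",
            data_params={"prior_eigenvalues": (0.2, 0.01, 0.05),
                         "noise_precision_scale": 0.025})
    if name == "normal_params":
        return ExperimentPreset(
            name="normal_params", dim=2, n_data=30, minibatch_size=6,
            step_size=1e-3, n_steps=10**6, n_chains=1000,
            burn_in_steps=10**4,  # burn-in time 10 at h = 1e-3
            delta=2.0, skew_pattern="dense_upper_ones",
            data_params={"mu_true": 0.0, "sigma_true": 10.0})
    if name == "logistic":
        return ExperimentPreset(
            name="logistic", dim=20, n_data=400, minibatch_size=10,
            step_size=1e-4, n_steps=4 * 10**5, n_chains=100, burn_in_steps=0,
            delta=1.0, skew_pattern="random_pm1", skew_norm_target=1.0,
            data_params={"alpha": 1.0})
    if name == "ica":
        if paper_scale:
            n_steps, h, chains, burn = 10**8, 2e-5, 100, 10**6  # T=2000, T_b=20
        else:
            n_steps, h, chains, burn = 2 * 10**5, 1e-4, 10, 2 * 10**4  # T=20, T_b=2
        return ExperimentPreset(
            name="ica", dim=9, n_data=400, minibatch_size=40,
            step_size=h, n_steps=n_steps, n_chains=chains, burn_in_steps=burn,
            delta=1.0, skew_pattern="kronecker", skew_norm_target=1.0,
            observables=("phi1", "phi2", "phi3"),
            data_params={"m": 3, "lam": 1.0})
    raise InvalidInputError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------

def _default_eval_points(n_steps, n_points=50):
    if n_steps < 1:
        return np.array([], dtype=int)
    pts = np.unique(np.round(np.logspace(0, np.log10(n_steps), n_points))
                    .astype(int))
    return pts[pts >= 1]


def _empty_report(kind, preset):
    return MetricsReport(
        kind=kind, observables=preset.observables,
        eval_points=np.array([], dtype=int),
        avar_mean={}, avar_std={}, avar_per_chain={},
        running_mean_curves={name: np.empty((0, preset.n_chains))
                             for name in preset.observables},
        n_chains=preset.n_chains, n_failed=0)


def run_experiment(preset: ExperimentPreset, kinds, overrides=None,
                   base_seed=0, references: Optional[Dict[str, float]] = None,
                   compute_ksd=False, ksd_max_k=10**4, ksd_chains=5,
                   ksd_points=15, eval_points=None,
                   failure_tolerance=0.1) -> Dict[str, MetricsReport]:
    """Run an ensemble of each requested sampler kind on one preset.

    Returns ``{kind: MetricsReport}``.  Per-chain domain failures are
    tolerated up to ``failure_tolerance`` (fraction of the ensemble);
    beyond that a :class:`ChainFailureError` carrying the partial
    reports is raised.  All randomness derives from ``base_seed``:
    dataset, skew matrix, initial state and one noise stream per
    (kind, chain).
    """
    if overrides:
        preset = preset.replace(**overrides)
    kinds = [canonical_kind(k) for k in kinds]
    data_seed, skew_seed, init_seed, chain_entropy = _sub_seeds(base_seed, 4)
    data = preset.make_data(data_seed)
    target = preset.make_target(data)
    skew = preset.make_skew(skew_seed)
    x0 = preset.make_initial(init_seed)
    if eval_points is None:
        eval_points = _default_eval_points(preset.n_steps)
    obs_fns = {name: OBSERVABLES[name] for name in preset.observables}
    h = preset.step_size

    kinds = list(dict.fromkeys(kinds))  # dedupe, order-stable
    reports: Dict[str, MetricsReport] = {}
    if preset.n_steps == 0:
        return {kind: _empty_report(kind, preset) for kind in kinds}

    # One lock-step pass advances every (kind, chain) pair; per-chain noise
    # streams depend only on (base_seed, kind, chain index), so the joint
    # run reproduces per-kind runs exactly.
    kind_seeds = {kind: int(np.random.SeedSequence(
        [chain_entropy, KINDS.index(kind)]).generate_state(1)[0] & 0x7FFFFFFF)
        for kind in kinds}
    labels, seeds = [], []
    for kind in kinds:
        labels += [kind] * preset.n_chains
        seeds += [derive_chain_seed(kind_seeds[kind], i)
                  for i in range(preset.n_chains)]
    needs_skew = any(k in ("irr", "rmirr", "giirr") for k in kinds)
    pert = PerturbationSpec(kind=kinds[0], temperature=preset.beta,
                            skew=skew if needs_skew else None,
                            scale=preset.delta)
    dd = drift_diffusion_multi(labels, target, pert)
    bm = BatchMeansCollector(preset.burn_in_steps, n_batches=20)
    rm = RunningMeanCollector(eval_points)
    x0_stack = np.broadcast_to(x0, (len(labels), target.dim))
    _, alive_all, fail_all = simulate_ensemble(
        target, dd, x0_stack, h, preset.n_steps, seeds,
        minibatch_size=preset.minibatch_size,
        with_replacement=preset.with_replacement,
        observables=obs_fns, collectors=[bm, rm])
    avar_all = bm.asymptotic_variance(h)  # (n_obs, M_total)

    excessive = []
    for kind_index, kind in enumerate(kinds):
        sel = slice(kind_index * preset.n_chains,
                    (kind_index + 1) * preset.n_chains)
        alive, fail_steps = alive_all[sel], fail_all[sel]
        n_failed = int((~alive).sum())
        avar_mean, avar_std, avar_chain, curves = {}, {}, {}, {}
        bias_c, var_c, mse_c = {}, {}, {}
        for i, name in enumerate(preset.observables):
            per_chain = avar_all[i, sel][alive]
            avar_chain[name] = per_chain
            avar_mean[name] = float(per_chain.mean()) if per_chain.size else np.nan
            avar_std[name] = (float(per_chain.std(ddof=1))
                              if per_chain.size > 1 else np.nan)
            curves[name] = rm.curves[i, :, sel]
            if references and name in references and alive.sum() >= 2:
                b, v, m = diagnostics.ensemble_bias_var_mse(
                    curves[name][:, alive].T, references[name])
                bias_c[name], var_c[name], mse_c[name] = b, v, m

        ksd_curve = None
        if compute_ksd:
            kind_dd = drift_diffusion(
                kind, target,
                PerturbationSpec(kind=kind, temperature=preset.beta,
                                 skew=skew if kind in ("irr", "rmirr", "giirr")
                                 else None, scale=preset.delta))
            ksd_curve = _ksd_curves(target, kind_dd, preset, x0,
                                    kind_seeds[kind], ksd_max_k, ksd_chains,
                                    ksd_points)

        reports[kind] = MetricsReport(
            kind=kind, observables=preset.observables,
            eval_points=rm.eval_points,
            avar_mean=avar_mean, avar_std=avar_std, avar_per_chain=avar_chain,
            running_mean_curves=curves,
            bias_curve=bias_c or None, variance_curve=var_c or None,
            mse_curve=mse_c or None, ksd_curve=ksd_curve,
            n_chains=preset.n_chains, n_failed=n_failed,
            provenance={
                "preset": preset.name, "base_seed": base_seed,
                "kind_seed": kind_seeds[kind], "data_seed": data_seed,
                "skew_seed": skew_seed, "init_seed": init_seed,
                "chain_seeds": seeds[sel], "step_size": h,
                "n_steps": preset.n_steps, "burn_in_steps": preset.burn_in_steps,
                "minibatch_size": preset.minibatch_size,
                "delta": preset.delta, "beta": preset.beta,
                "failed_chain_steps": fail_steps[~alive].tolist(),
            })
        if n_failed > failure_tolerance * preset.n_chains:
            excessive.append(kind)

    if excessive:
        raise ChainFailureError(
            f"more than {failure_tolerance:.0%} of chains failed for kinds "
            f"{excessive}", reports=reports)
    return reports


def _ksd_curves(target, dd, preset, x0, kind_seed, max_k, n_chains, n_points):
    """Mean normalized-KSD curve over short auxiliary chains."""
    k = min(max_k, preset.n_steps)
    points = np.unique(np.round(np.logspace(
        np.log10(max(10, k // 100)), np.log10(k), n_points)).astype(int))
    seeds = [derive_chain_seed(kind_seed, 10**6 + i) for i in range(n_chains)]
    sc = StateCollector(thin=1)
    x0_stack = np.broadcast_to(x0, (n_chains, target.dim))
    simulate_ensemble(target, dd, x0_stack, preset.step_size, k, seeds,
                      minibatch_size=preset.minibatch_size,
                      with_replacement=preset.with_replacement,
                      observables={}, collectors=[sc])
    cfg = KSDConfig(evaluation_points=points)
    per_chain = []
    for i in range(n_chains):
        samples = sc.states[:k, i, :]  # theta_0 .. theta_{k-1}
        _, curve = ksd(samples, target.grad_log_density, cfg)
        per_chain.append(curve["ksd"])
    per_chain = np.asarray(per_chain)
    return {"k": curve["k"], "mean": per_chain.mean(axis=0),
            "per_chain": per_chain}
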