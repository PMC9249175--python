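"""Minibatch ABC-SMC: likelihood-free inference with data subsampling.

Sequential importance sampling for approximate Bayesian computation in
which the discrepancy between a proposed parameter and the data is
estimated on a random minibatch of the observations rather than on the
whole dataset.  For each proposal theta, ``n_batch`` observation indices
are drawn uniformly with replacement; for each index one model realisation
is simulated from that observation's own initial condition and compared to
that observation's final snapshot; the proposal's score is the mean of the
per-observation distances.  Per generation, ``n_gen_samples`` proposals are
scored and the ``n_accept`` with smallest score are accepted (rank-based
acceptance, so the tolerance schedule is implicit).  Accepted particles are
weighted by prior density over estimated importance density and perturbed
into the next generation with a multivariate normal kernel whose covariance
is twice the weighted empirical covariance of the previous generation
(the standard 'optimal' normal-kernel choice for ABC-SMC).

Setting ``n_batch`` equal to the number of observations with
``replace=False`` recovers the classical full-data mean-distance scheme.
The expected number of model simulations drops by a factor
``n_obs / n_batch``; the probability that a whole generation never touches
a given observation is ``(1 - 1/n_obs)^(n_gen * n_batch)``, which is
negligible at practical settings (see ``coverage_bound``).
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, NamedTuple, Optional, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import gaussian_kde

from . import ibm
from .ibm import CellPopulation, ModelParams
from .summaries import SummaryVector, pairwise_distance, summary

__all__ = [
    "PARAM_NAMES",
    "PriorSpec",
    "Particle",
    "ParticlePopulation",
    "ABCConfig",
    "sample_prior",
    "kernel_covariance",
    "propose",
    "importance_density",
    "minibatch_distance",
    "run_generation",
    "run_abc_smc",
    "kl_between_generations",
    "coverage_bound",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("m", "p", "d", "gamma_m", "gamma_p", "gamma_b")

# default prior box: m in (0,10) /h; p, d in (0, 0.05) /h;
# gamma_m in (-2.5, 2.5) /h; gamma_p in (0, 0.05) /h; gamma_b in (0, 50) um
_DEFAULT_LOWER = np.array([0.0, 0.0, 0.0, -2.5, 0.0, 0.0])
_DEFAULT_UPPER = np.array([10.0, 0.05, 0.05, 2.5, 0.05, 50.0])


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors on the six model parameters."""

    lower: np.ndarray = field(default_factory=lambda: _DEFAULT_LOWER.copy())
    upper: np.ndarray = field(default_factory=lambda: _DEFAULT_UPPER.copy())

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != (6,) or hi.shape != (6,):
            raise ValueError("prior bounds must have six entries "
                             f"(order {PARAM_NAMES})")
        if not np.all(lo < hi):
            raise ValueError("each lower bound must be below its upper bound")

    @property
    def volume(self) -> float:
        return float(np.prod(self.upper - self.lower))

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        """Independent uniform draw(s) from the box."""
        if size is None:
            return rng.uniform(self.lower, self.upper)
        return rng.uniform(self.lower, self.upper, size=(size, 6))

    def contains(self, theta) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return np.all((theta > self.lower) & (theta < self.upper), axis=1)

    def pdf(self, theta):
        """Prior density: 1/volume inside the box, 0 outside."""
        inside = self.contains(theta)
        out = np.where(inside, 1.0 / self.volume, 0.0)
        return float(out[0]) if np.asarray(theta).ndim == 1 else out


class Particle(NamedTuple):
    theta: np.ndarray
    weight: float
    distance: float


@dataclass
class ParticlePopulation:
    """One SMC generation: accepted parameter vectors with weights."""

    thetas: np.ndarray
    weights: np.ndarray
    distances: np.ndarray
    generation: int = 1
    kernel_cov: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        n = len(self.thetas)
        if self.thetas.ndim != 2 or self.thetas.shape[1] != 6:
            raise ValueError("thetas must have shape (N, 6)")
        if len(self.weights) != n or len(self.distances) != n:
            raise ValueError("weights/distances length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("total weight must be positive")
        self.weights = self.weights / total

    def __len__(self) -> int:
        return len(self.thetas)

    @property
    def particles(self) -> List[Particle]:
        return [Particle(t, w, d) for t, w, d
                in zip(self.thetas, self.weights, self.distances)]

    def posterior_mean(self) -> np.ndarray:
        return self.weights @ self.thetas

    def posterior_std(self) -> np.ndarray:
        mu = self.posterior_mean()
        var = self.weights @ (self.thetas - mu) ** 2
        return np.sqrt(var)


@dataclass(frozen=True)
class ABCConfig:
    """Algorithm settings; defaults match the full-scale screen protocol."""

    n_gen_samples: int = 20_000
    n_accept: int = 500
    n_batch: int = 10
    n_generations: int = 4
    kl_tolerance: Optional[float] = None
    kernel_scale: float = 2.0
    phi: float = 24.0
    t_end: float = 24.0

    def __post_init__(self) -> None:
        if self.n_accept > self.n_gen_samples:
            raise ValueError("n_accept cannot exceed n_gen_samples")
        if self.n_batch < 1 or self.n_generations < 1:
            raise ValueError("n_batch and n_generations must be >= 1")

    @property
    def acceptance_rate(self) -> float:
        return self.n_accept / self.n_gen_samples

    def simulation_reduction(self, n_obs: int) -> float:
        """Simulation-count reduction of the minibatch over full-data scheme."""
        return n_obs / self.n_batch


def sample_prior(prior: PriorSpec, rng: np.random.Generator) -> ModelParams:
    """One model-parameter draw from the prior (phi left at its default)."""
    return ModelParams(*prior.sample(rng))


def kernel_covariance(prev: ParticlePopulation,
                      scale: float = 2.0) -> np.ndarray:
    """Perturbation-kernel covariance: scale x weighted empirical covariance.

    The multivariate-normal kernel with twice the weighted sample
    covariance of the previous generation; a small diagonal jitter is added
    if the matrix is (near-)singular.
    """
    if len(prev) < 2:
        raise ValueError("need at least two particles")
    w = prev.weights
    mu = w @ prev.thetas
    diff = prev.thetas - mu
    cov = scale * (diff.T * w) @ diff
    # jitter if degenerate in any direction
    eig = np.linalg.eigvalsh(cov)
    scale_ref = max(np.max(np.abs(cov)), 1e-300)
    if eig[0] <= 1e-12 * scale_ref:
        if np.all(np.abs(diff) < 1e-15):
            warnings.warn("degenerate particle population; "
                          "kernel covariance is jitter only")
        cov = cov + 1e-10 * scale_ref * np.eye(6)
    return cov


def _propose_batch(prev: ParticlePopulation, prior: PriorSpec, n: int,
                   rng: np.random.Generator,
                   max_tries: int = 10 ** 6,
                   return_parents: bool = False):
    """n kernel-perturbed proposals with positive prior density."""
    cov = prev.kernel_cov
    if cov is None:
        cov = kernel_covariance(prev)
    chol = np.linalg.cholesky(cov)
    out = np.empty((n, 6))
    parent_of = np.zeros(n, dtype=int)
    need = np.arange(n)
    tries = 0
    while need.size:
        parents = rng.choice(len(prev), size=need.size, p=prev.weights)
        cand = prev.thetas[parents] + rng.standard_normal((need.size, 6)) @ chol.T
        ok = prior.contains(cand)
        out[need[ok]] = cand[ok]
        parent_of[need[ok]] = parents[ok]
        need = need[~ok]
        tries += 1
        if tries > max_tries:
            raise RuntimeError("perturbation kernel keeps proposing outside "
                               "the prior support")
    return (out, parent_of) if return_parents else out


def propose(prev: ParticlePopulation, prior: PriorSpec,
            rng: np.random.Generator) -> np.ndarray:
    """A single in-support proposal from the importance distribution."""
    return _propose_batch(prev, prior, 1, rng)[0]


def importance_density(theta, prev: ParticlePopulation,
                       cov: Optional[np.ndarray] = None) -> np.ndarray:
    """Mixture density q(theta) = sum_j w_j N(theta; theta_j, cov).

    Evaluated at one or many parameter vectors; strictly positive
    everywhere, so accepted-particle weights are always finite.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if cov is None:
        cov = prev.kernel_cov if prev.kernel_cov is not None \
            else kernel_covariance(prev)
    chol = np.linalg.cholesky(cov)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    # whiten the differences: z = L^-1 (theta - theta_j)
    diff = theta[:, None, :] - prev.thetas[None, :, :]
    z = solve_triangular(chol, diff.reshape(-1, 6).T, lower=True).T
    maha = np.sum(z ** 2, axis=1).reshape(theta.shape[0], len(prev))
    lognorm = -0.5 * (6 * np.log(2.0 * np.pi) + logdet)
    dens = np.exp(lognorm - 0.5 * maha) @ prev.weights
    return dens if dens.size > 1 else float(dens[0])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _default_simulator(theta: np.ndarray, obs, config: ABCConfig,
                       seed: int) -> CellPopulation:
    """One fast-engine realisation from an observation's initial condition."""
    params = ModelParams(*theta, phi=getattr(obs, "phi", config.phi))
    initial = obs.initial
    x, y = ibm._simulate_arrays(
        np.ascontiguousarray(initial.positions[:, 0]),
        np.ascontiguousarray(initial.positions[:, 1]),
        initial.time, config.t_end, params, initial.domain, seed,
    )
    return CellPopulation(np.column_stack([x, y]), config.t_end, initial.domain)


def minibatch_distance(theta, dataset: Sequence, n_batch: int,
                       rng: np.random.Generator,
                       simulate: Optional[Callable] = None,
                       summarise: Optional[Callable] = None,
                       obs_summaries: Optional[List[SummaryVector]] = None,
                       config: Optional[ABCConfig] = None,
                       replace: bool = True) -> float:
    """Mean distance of theta to a random minibatch of the observations.

    Draws ``n_batch`` observation indices uniformly (with replacement by
    default); for each, simulates one realisation from that observation's
    initial condition and scores it against that observation's final
    summary.  ``n_batch = len(dataset)`` with ``replace=False`` reproduces
    the classical full-data mean distance.

    ``simulate(theta, obs, config, seed) -> CellPopulation`` and
    ``summarise(pop) -> SummaryVector`` may be overridden (e.g. by stubs in
    tests); defaults run the compiled model engine and the standard summary.
    """
    n_obs = len(dataset)
    if n_obs == 0:
        raise ValueError("dataset is empty")
    config = config or ABCConfig()
    simulate = simulate or _default_simulator
    summarise = summarise or summary
    if obs_summaries is None:
        obs_summaries = [summarise(o.final) for o in dataset]
    idx = rng.choice(n_obs, size=n_batch, replace=replace)
    total = 0.0
    for i in idx:
        seed = int(rng.integers(0, 2 ** 31 - 1))
        sim_pop = simulate(np.asarray(theta, dtype=float), dataset[i],
                           config, seed)
        total += pairwise_distance(summarise(sim_pop), obs_summaries[i])
    return total / n_batch


# ---------------------------------------------------------------------------
# the SMC loop
# ---------------------------------------------------------------------------


def run_generation(dataset: Sequence, config: ABCConfig, prior: PriorSpec,
                   rng: np.random.Generator,
                   prev: Optional[ParticlePopulation] = None,
                   simulate: Optional[Callable] = None,
                   summarise: Optional[Callable] = None,
                   obs_summaries: Optional[List[SummaryVector]] = None,
                   ) -> ParticlePopulation:
    """One minibatch importance-sampling generation.

    Proposes ``config.n_gen_samples`` parameters (from the prior at
    generation 1, else from the perturbed previous generation), scores each
    on a fresh minibatch, accepts the ``config.n_accept`` with smallest
    score (ties broken by proposal order) and assigns importance weights
    prior/q (uniform at generation 1).

    Scoring is lazy: because the per-observation distances are non-negative,
    the partial batch sum divided by the batch size is a lower bound on a
    proposal's final score.  Once ``n_accept`` proposals have complete
    scores, any proposal whose lower bound strictly exceeds the running
    ``n_accept``-th best score is rejected without simulating the rest of
    its batch.  The accepted set (including tie-breaking) is identical to
    exhaustive scoring of the same draws; only provably-rejected
    simulations are skipped.
    """
    summarise_fn = summarise or summary
    simulate_fn = simulate or _default_simulator
    if obs_summaries is None:
        obs_summaries = [summarise_fn(o.final) for o in dataset]
    n_obs = len(dataset)
    if n_obs == 0:
        raise ValueError("dataset is empty")

    n_gen = config.n_gen_samples
    if prev is None:
        thetas = prior.sample(rng, size=n_gen)
        cov = None
        # evaluate cheap proposals first so the lazy-rejection threshold
        # tightens before the expensive (high event-rate) ones are scored
        eval_order = np.argsort(thetas[:, 0], kind="stable")
    else:
        cov = kernel_covariance(prev, scale=config.kernel_scale)
        prev = ParticlePopulation(prev.thetas, prev.weights, prev.distances,
                                  prev.generation, kernel_cov=cov)
        thetas, parent_of = _propose_batch(prev, prior, n_gen, rng,
                                           return_parents=True)
        # children of well-fitting parents first, for the same reason
        eval_order = np.argsort(prev.distances[parent_of], kind="stable")

    eps = np.full(n_gen, np.inf)
    best = []  # max-heap (negated) of the n_accept smallest complete scores
    n_sims = 0
    for i in eval_order:
        threshold = -best[0] if len(best) >= config.n_accept else np.inf
        idx = rng.choice(n_obs, size=config.n_batch, replace=True)
        partial = 0.0
        complete = True
        for j in idx:
            seed = int(rng.integers(0, 2 ** 31 - 1))
            sim_pop = simulate_fn(thetas[i], dataset[j], config, seed)
            partial += pairwise_distance(summarise_fn(sim_pop),
                                         obs_summaries[j])
            n_sims += 1
            if partial / config.n_batch > threshold:
                complete = False
                break
        if complete:
            eps[i] = partial / config.n_batch
            if len(best) < config.n_accept:
                heapq.heappush(best, -eps[i])
            elif eps[i] < -best[0]:
                heapq.heapreplace(best, -eps[i])
    logger.info("scored %d proposals with %d simulations (of %d maximal)",
                n_gen, n_sims, n_gen * config.n_batch)

    order = np.argsort(eps, kind="stable")[:config.n_accept]
    acc_thetas = thetas[order]
    acc_eps = eps[order]
    if prev is None:
        weights = np.full(config.n_accept, 1.0 / config.n_accept)
        generation = 1
    else:
        q = importance_density(acc_thetas, prev, cov=cov)
        weights = prior.pdf(acc_thetas) / q
        generation = prev.generation + 1
    logger.info(
        "generation %d: eps quantiles %.4g / %.4g / %.4g",
        generation, *np.quantile(acc_eps, [0.0, 0.5, 1.0]),
    )
    return ParticlePopulation(acc_thetas, weights, acc_eps,
                              generation=generation, kernel_cov=cov)


def run_abc_smc(dataset: Sequence, config: Optional[ABCConfig] = None,
                prior: Optional[PriorSpec] = None, rng=None,
                simulate: Optional[Callable] = None,
                summarise: Optional[Callable] = None,
                ) -> List[ParticlePopulation]:
    """Full minibatch ABC-SMC run; returns one population per generation.

    Runs ``config.n_generations`` generations, stopping early if
    ``config.kl_tolerance`` is set and the estimated KL divergence between
    successive generations falls below it.  Fully reproducible given the
    seed (``rng`` may be a seed or a Generator).
    """
    config = config or ABCConfig()
    prior = prior or PriorSpec()
    rng = np.random.default_rng(rng)
    summarise_fn = summarise or summary
    obs_summaries = [summarise_fn(o.final) for o in dataset]

    generations: List[ParticlePopulation] = []
    prev = None
    for t in range(config.n_generations):
        pop = run_generation(dataset, config, prior, rng, prev=prev,
                             simulate=simulate, summarise=summarise,
                             obs_summaries=obs_summaries)
        generations.append(pop)
        if prev is not None and config.kl_tolerance is not None:
            kl = kl_between_generations(prev, pop)
            logger.info("generation %d: KL change %.4g", pop.generation, kl)
            if kl < config.kl_tolerance:
                break
        prev = pop
    return generations


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def kl_between_generations(a: ParticlePopulation, b: ParticlePopulation,
                           n_grid: int = 512) -> float:
    """Estimated KL(b || a), averaged over the six 1-D parameter marginals.

    Each marginal pair is estimated with weighted Gaussian KDEs on a shared
    grid; degenerate marginals are skipped with a warning.
    """
    kls = []
    for k in range(a.thetas.shape[1]):
        xa, wa = a.thetas[:, k], a.weights
        xb, wb = b.thetas[:, k], b.weights
        sa = np.sqrt(np.average((xa - np.average(xa, weights=wa)) ** 2,
                                weights=wa))
        sb = np.sqrt(np.average((xb - np.average(xb, weights=wb)) ** 2,
                                weights=wb))
        if sa <= 0 or sb <= 0 or not np.isfinite(sa + sb):
            warnings.warn(f"parameter {PARAM_NAMES[k]}: degenerate marginal "
                          "skipped in KL estimate")
            continue
        lo = min(xa.min(), xb.min()) - 3.0 * max(sa, sb)
        hi = max(xa.max(), xb.max()) + 3.0 * max(sa, sb)
        grid = np.linspace(lo, hi, n_grid)
        pa = gaussian_kde(xa, weights=wa)(grid)
        pb = gaussian_kde(xb, weights=wb)(grid)
        pa = np.maximum(pa / pa.sum(), 1e-300)
        pb = np.maximum(pb / pb.sum(), 1e-300)
        kls.append(float(np.sum(pb * np.log(pb / pa))))
    if not kls:
        raise ValueError("all marginals degenerate; KL undefined")
    return float(np.mean(kls))


def coverage_bound(n_obs: int, n_gen_samples: int, n_batch: int,
                   log: bool = False):
    """Probability that a generation never samples a given observation.

    Returns ``(exact, bound)`` with exact = (1 - 1/n_obs)^(n_gen * n_batch)
    and bound = exp(-n_gen * n_batch / n_obs) >= exact.  With ``log=True``
    the natural logs are returned instead (the probabilities underflow at
    realistic settings).
    """
    if min(n_obs, n_gen_samples, n_batch) < 1:
        raise ValueError("all arguments must be >= 1")
    k = n_gen_samples * n_batch
    log_exact = k * np.log1p(-1.0 / n_obs) if n_obs > 1 else -np.inf
    log_bound = -k / n_obs
    if log:
        return log_exact, log_bound
    return float(np.exp(log_exact)), float(np.exp(log_bound))
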