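"""Sequential ABC: importance-weighted particle populations with a shrinking
acceptance threshold.

The engine approximates the posterior ``pi(theta | y_obs) ~ pi(theta) *
P(d(s(M(theta)), s(y_obs)) <= eps)`` of a stochastic simulator M without
likelihood evaluations. Generation 1 accepts prior draws as-is (eps = inf);
each later generation resamples the previous population by weight, perturbs
with a Gaussian kernel whose covariance is a scaled weighted empirical
covariance, simulates, and accepts while the distance does not exceed the
current eps — the alpha-quantile of the previous generation's accepted
distances. Importance weights ``w ~ pi(theta') / sum_j w_j K(theta' |
theta_j)`` correct for the proposal mixture.

Early rejection: each simulation carries a work budget (lattice update
steps by default); a proposal whose simulation exhausts it is discarded at
that point with distance +inf, without finishing the simulation.

All randomness flows through per-task substreams derived from the run seed,
so a run is reproducible bit-for-bit for a fixed (problem, config, seed,
single worker).
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import parallel
from .lattice import BudgetExceeded, simulate_model
from .problem import ProblemSpec, map_parameters
from .summaries import (
    DistanceSpec,
    StatisticVector,
    adapt_weights,
    compute_summaries,
    distance,
    fit_regression_statistics,
    observed_summaries,
)
from .weighted import type1_quantile

logger = logging.getLogger(__name__)

__all__ = [
    "Particle",
    "Population",
    "ABCConfig",
    "Prior",
    "build_priors",
    "sample_prior",
    "prior_logpdf",
    "PerturbationKernel",
    "perturb",
    "importance_weights",
    "next_epsilon",
    "evaluate_particle",
    "run_abc",
    "DegenerateKernelError",
    "REJECTED_EARLY",
]

REJECTED_EARLY = float("inf")


class DegenerateKernelError(RuntimeError):
    """Perturbation failed to produce an in-support draw within the retry cap."""


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class Prior:
    """One parameter's prior on its sampling scale.

    uniform and log10-uniform priors are both uniform on the sampling scale
    (the latter after a log10 transform of its bounds); normal priors are
    Gaussian on the declared scale.
    """

    parameter_id: str
    kind: str  # "uniform" | "normal" (on sampling scale)
    a: float  # lower bound / mean
    b: float  # upper bound / sd
    scale: str  # "lin" | "log10"

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "uniform":
            return float(rng.uniform(self.a, self.b))
        return float(rng.normal(self.a, self.b))

    def logpdf(self, x: float) -> float:
        if self.kind == "uniform":
            if self.a <= x <= self.b:
                return -math.log(self.b - self.a)
            return -math.inf
        z = (x - self.a) / self.b
        return -0.5 * z * z - math.log(self.b * math.sqrt(2 * math.pi))

    def in_support(self, x: float) -> bool:
        if self.kind == "uniform":
            return self.a <= x <= self.b
        return True


def build_priors(p: ProblemSpec) -> list[Prior]:
    priors = []
    for par in p.estimated:
        if par.prior_kind == "uniform":
            priors.append(Prior(par.parameter_id, "uniform", par.prior_arg1, par.prior_arg2, par.scale))
        elif par.prior_kind == "log10-uniform":
            priors.append(
                Prior(
                    par.parameter_id,
                    "uniform",
                    math.log10(par.prior_arg1),
                    math.log10(par.prior_arg2),
                    "log10",
                )
            )
        elif par.prior_kind == "normal":
            priors.append(Prior(par.parameter_id, "normal", par.prior_arg1, par.prior_arg2, par.scale))
        else:
            raise ValueError(f"unsupported prior kind {par.prior_kind!r}")
    return priors


def sample_prior(p: ProblemSpec | Sequence[Prior], rng: np.random.Generator) -> np.ndarray:
    priors = p if isinstance(p, (list, tuple)) else build_priors(p)
    return np.array([pr.sample(rng) for pr in priors])


def prior_logpdf(priors: Sequence[Prior], theta: np.ndarray) -> float:
    return float(sum(pr.logpdf(x) for pr, x in zip(priors, theta)))


# ---------------------------------------------------------------------------
# particles and populations


@dataclass
class Particle:
    theta: np.ndarray  # on sampling scale
    weight: float
    distance: float
    summaries: Optional[StatisticVector] = None
    n_attempts: int = 1


@dataclass
class Population:
    generation_index: int
    particles: list[Particle]
    epsilon: float
    total_proposals: int

    # arrays are cached because the engine reads them once per proposal
    @property
    def thetas(self) -> np.ndarray:
        if "_thetas" not in self.__dict__:
            self.__dict__["_thetas"] = np.stack([pt.theta for pt in self.particles])
        return self.__dict__["_thetas"]

    @property
    def weights(self) -> np.ndarray:
        if "_weights" not in self.__dict__:
            self.__dict__["_weights"] = np.array([pt.weight for pt in self.particles])
        return self.__dict__["_weights"]

    @property
    def distances(self) -> np.ndarray:
        return np.array([pt.distance for pt in self.particles])

    def normalize_weights(self) -> None:
        w = np.array([pt.weight for pt in self.particles])
        total = w.sum()
        if total <= 0:
            raise ValueError("population weights sum to zero")
        for pt, wi in zip(self.particles, w / total):
            pt.weight = float(wi)
        self.__dict__.pop("_weights", None)


@dataclass
class ABCConfig:
    population_size: int = 500
    max_generations: int = 10
    min_epsilon: float = 0.0
    epsilon_quantile: float = 0.5  # alpha of the schedule
    kernel_scale_factor: float = 2.0
    max_walltime: Optional[float] = None  # seconds; generation finishes first
    sim_budget: Optional[int] = None  # work units per simulation (early rejection)
    initial_epsilon: float = math.inf
    pilot_size: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 < self.epsilon_quantile < 1.0:
            raise ValueError("epsilon_quantile must be in (0, 1)")


# ---------------------------------------------------------------------------
# perturbation kernel and weights


class PerturbationKernel:
    """Multivariate normal kernel with covariance factor * weighted cov."""

    def __init__(self, thetas: np.ndarray, weights: np.ndarray, scale_factor: float = 2.0):
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
        mean = weights @ thetas
        centered = thetas - mean
        cov = (centered * weights[:, None]).T @ centered
        # unbiased normalization for weighted samples
        denom = 1.0 - float(np.sum(weights**2))
        if denom > 0:
            cov = cov / denom
        self.cov = scale_factor * cov
        self.dim = thetas.shape[1]
        if np.allclose(self.cov, 0.0):
            self._chol = None  # degenerate: kernel is a point mass at zero
        else:
            jitter = 1e-12 * np.trace(self.cov) / self.dim
            self._chol = np.linalg.cholesky(self.cov + jitter * np.eye(self.dim))

    @property
    def degenerate(self) -> bool:
        return self._chol is None

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        if self._chol is None:
            return np.zeros(self.dim)
        return self._chol @ rng.standard_normal(self.dim)

    def logpdf(self, diff: np.ndarray) -> np.ndarray:
        """Log density of the kernel at displacement(s) diff (rows)."""
        if self._chol is None:
            raise ValueError("degenerate kernel has no density")
        diff = np.atleast_2d(diff)
        z = np.linalg.solve(self._chol, diff.T)
        logdet = 2.0 * np.sum(np.log(np.diag(self._chol)))
        return -0.5 * np.sum(z**2, axis=0) - 0.5 * (self.dim * math.log(2 * math.pi) + logdet)


MAX_PERTURB_RETRIES = 10_000


def perturb(
    theta: np.ndarray,
    population: Population,
    kernel: PerturbationKernel,
    priors: Sequence[Prior],
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturb theta; out-of-support draws trigger a resample-and-retry.

    With a degenerate kernel (zero covariance) theta is returned unchanged.
    After 10^4 consecutive out-of-support draws a
    :class:`DegenerateKernelError` is raised.
    """
    theta = np.asarray(theta, dtype=float)
    if kernel.degenerate:
        return theta.copy()
    w = population.weights
    thetas = population.thetas
    current = theta
    for _ in range(MAX_PERTURB_RETRIES):
        cand = current + kernel.draw(rng)
        if all(pr.in_support(x) for pr, x in zip(priors, cand)):
            return cand
        current = thetas[rng.choice(len(w), p=w / w.sum())]
    raise DegenerateKernelError(
        f"no in-support draw after {MAX_PERTURB_RETRIES} attempts; kernel too wide for prior support"
    )


def importance_weights(
    thetas: np.ndarray,
    priors: Sequence[Prior],
    previous: Population,
    kernel: PerturbationKernel,
) -> np.ndarray:
    """Unnormalized SMC weights pi(theta') / sum_j w_j K(theta' | theta_j)."""
    thetas = np.atleast_2d(thetas)
    prev_thetas = previous.thetas
    prev_w = previous.weights
    log_prior = np.array([prior_logpdf(priors, th) for th in thetas])
    out = np.empty(len(thetas))
    for i, th in enumerate(thetas):
        logk = kernel.logpdf(th - prev_thetas)
        m = logk.max()
        denom = float(prev_w @ np.exp(logk - m))
        if denom <= 0:
            raise FloatingPointError("zero proposal density; cannot happen for Gaussian kernels")
        out[i] = math.exp(log_prior[i] - m - math.log(denom)) if np.isfinite(log_prior[i]) else 0.0
    return out


def next_epsilon(distances_of_accepted, alpha: float, previous: float = math.inf) -> float:
    """alpha-quantile (type 1) of the accepted distances, clamped below previous."""
    q = type1_quantile(np.asarray(distances_of_accepted, dtype=float), alpha)
    return min(q, previous)


# ---------------------------------------------------------------------------
# particle evaluation


def _sim_request(p: ProblemSpec):
    """Record/snapshot times the statistic table requires from the simulator."""
    record, snaps = set(), set()
    for s in p.statistic_table:
        if "times" in s.args:
            record.update(float(t) for t in s.args["times"])
        if s.function_id == "radial_profile":
            snaps.add(float(s.args["time"]))
        if s.function_id == "final_fraction":
            pass  # last recorded time is used
    return sorted(record), sorted(snaps)


def _condition_ids(p: ProblemSpec) -> list[str]:
    seen = []
    for m in p.measurement_table:
        if m.condition_id not in seen:
            seen.append(m.condition_id)
    return seen


def _n_replicates(p: ProblemSpec, condition_id: str) -> int:
    reps = {
        m.replicate_id
        for m in p.measurement_table
        if m.condition_id == condition_id and m.replicate_id is not None
    }
    return max(1, len(reps))


def assemble_observed(p: ProblemSpec) -> StatisticVector:
    """Observed statistic vector, concatenated over measurement conditions."""
    conds = _condition_ids(p)
    parts = [observed_summaries(p, c) for c in conds]
    if len(parts) == 1:
        return parts[0]
    values = np.concatenate([s.values for s in parts])
    names = [f"{c}:{n}" for c, s in zip(conds, parts) for n in s.names]
    return StatisticVector(values, names)


def simulate_summaries(
    p: ProblemSpec,
    theta: np.ndarray,
    seed_seq: np.random.SeedSequence,
    budget: Optional[int] = None,
) -> tuple[StatisticVector, int]:
    """Simulate all conditions/replicates for theta; returns (summaries, work).

    Replicate simulations run independently and their statistic vectors are
    averaged before any distance is taken. Raises
    :class:`~cellabc.lattice.BudgetExceeded` if the cumulative work budget
    runs out mid-simulation.
    """
    record, snaps = _sim_request(p)
    conds = _condition_ids(p)
    n_children = sum(_n_replicates(p, c) for c in conds)
    children = iter(seed_seq.spawn(n_children))
    work = 0
    parts, names = [], []
    for cond in conds:
        doc = map_parameters(p, theta, cond)
        reps = []
        for _ in range(_n_replicates(p, cond)):
            remaining = None if budget is None else budget - work
            traj = simulate_model(
                doc, next(children), record_times=record or None, snapshot_times=snaps,
                budget=remaining,
            )
            work += traj.work
            reps.append(compute_summaries(traj, p.statistic_table))
        mean_vals = np.mean([r.values for r in reps], axis=0)
        parts.append(mean_vals)
        if len(conds) == 1:
            names = reps[0].names
        else:
            names.extend(f"{cond}:{n}" for n in reps[0].names)
    return StatisticVector(np.concatenate(parts), names), work


def evaluate_particle(
    theta: np.ndarray,
    p: ProblemSpec,
    d: DistanceSpec,
    obs: StatisticVector,
    epsilon: float,
    sim_budget: Optional[int],
    seed_seq: np.random.SeedSequence,
) -> tuple[float, Optional[StatisticVector], int]:
    """Simulate theta and return (distance, summaries, work).

    A simulation that exhausts the work budget is rejected early: the
    distance is +inf and no summaries are produced. Simulator exceptions
    reject the particle with a logged error; the pipeline continues.
    """
    try:
        sim, work = simulate_summaries(p, theta, seed_seq, budget=sim_budget)
    except BudgetExceeded as e:
        return REJECTED_EARLY, None, e.work_done
    except Exception:  # noqa: BLE001 - deliberate containment per contract
        logger.exception("simulation failed for theta=%s; particle rejected", theta)
        return REJECTED_EARLY, None, 0
    return distance(sim, obs, d), sim, work


# ---------------------------------------------------------------------------
# the engine


@dataclass
class GenerationLog:
    t: int
    epsilon: float
    n_accepted: int
    total_proposals: int
    ess: float
    wall_seconds: float


def run_abc(
    p: ProblemSpec,
    cfg: ABCConfig,
    dspec: Optional[DistanceSpec] = None,
    sampler=None,
    fit_regression: bool = False,
    store=None,
):
    """Run ABC-SMC on a problem; returns a ResultStore.

    ``sampler`` is any object with the scheduler contract
    (``sample_until_n_accepted``); default is a single sequential worker.
    ``fit_regression`` fits the inverse-regression summary projection on the
    pilot sample and freezes it for the whole run.
    """
    from .store import ResultStore

    sampler = sampler or parallel.SequentialSampler()
    dspec = dspec or DistanceSpec()
    priors = build_priors(p)
    obs = assemble_observed(p)
    N = cfg.population_size
    t_start = time.monotonic()

    # pilot sample: initial adaptive weights and (optionally) the frozen
    # regression projection
    if dspec.adapt != "none" or fit_regression:
        pilot_thetas, pilot_summaries = [], []
        i = 0
        while len(pilot_summaries) < cfg.pilot_size:
            task = parallel.Task(index=i, generation=0, seed=cfg.seed)
            rng = task.rng()
            theta = sample_prior(priors, rng)
            try:
                sim, _ = simulate_summaries(p, theta, task.seed_seq.spawn(1)[0], budget=cfg.sim_budget)
            except BudgetExceeded:
                i += 1
                continue
            pilot_thetas.append(theta)
            pilot_summaries.append(sim)
            i += 1
        if fit_regression:
            dspec.regression_map = fit_regression_statistics(pilot_thetas, pilot_summaries)
        if dspec.adapt != "none":
            dspec.weights = adapt_weights(pilot_summaries, dspec.adapt, normalize=True)

    if store is None:
        store = ResultStore(
            problem_fingerprint=p.fingerprint(),
            config=_config_dict(cfg),
            parameter_names=[pr.parameter_id for pr in priors],
            statistic_names=list(obs.names),
        )

    populations: list[Population] = []
    epsilon = cfg.initial_epsilon
    for t in range(1, cfg.max_generations + 1):
        gen_start = time.monotonic()
        if populations:
            prev = populations[-1]
            epsilon = next_epsilon(prev.distances, cfg.epsilon_quantile, previous=prev.epsilon)
            if dspec.adapt != "none":
                # refit the relative weighting from the previous generation's
                # accepted summaries, then rescale the whole weight vector so
                # that the alpha-quantile of those accepted distances is
                # unchanged: the distance scale (and hence the epsilon
                # trajectory) stays comparable across generations while the
                # per-statistic weighting adapts
                w_new = adapt_weights(
                    [pt.summaries for pt in prev.particles], dspec.adapt
                )
                dspec.weights = w_new
                recomputed = [distance(pt.summaries, obs, dspec) for pt in prev.particles]
                q_new = type1_quantile(recomputed, cfg.epsilon_quantile)
                if q_new > 0 and np.isfinite(epsilon):
                    dspec.weights = w_new * (epsilon / q_new) ** dspec.p
            kernel = PerturbationKernel(prev.thetas, prev.weights, cfg.kernel_scale_factor)
        else:
            prev = None
            kernel = None

        def task_fn(task: parallel.Task) -> parallel.TaskResult:
            rng = task.rng()
            if kernel is None:
                theta = sample_prior(priors, rng)
            else:
                idx = rng.choice(N, p=prev.weights)
                theta = perturb(prev.thetas[idx], prev, kernel, priors, rng)
            d_val, sim, work = evaluate_particle(
                theta, p, dspec, obs, epsilon, cfg.sim_budget, task.seed_seq.spawn(2)[1]
            )
            accepted = d_val <= epsilon
            return parallel.TaskResult(
                task=task,
                accepted=accepted,
                payload=Particle(theta=theta, weight=0.0, distance=d_val, summaries=sim),
                cost=float(work),
            )

        accepted, total = sampler.sample_until_n_accepted(N, task_fn, t, cfg.seed)
        particles = [r.payload for r in accepted]
        pop = Population(t, particles, epsilon=epsilon, total_proposals=total)
        if kernel is None or kernel.degenerate:
            for pt in particles:
                pt.weight = 1.0 / N
        else:
            w = importance_weights(pop.thetas, priors, populations[-1], kernel)
            for pt, wi in zip(particles, w):
                pt.weight = float(wi)
        pop.normalize_weights()
        populations.append(pop)

        wall = time.monotonic() - gen_start
        from .weighted import ess as _ess

        gen_ess = _ess(pop.weights)
        store.append_generation(pop, wall_seconds=wall)
        logger.info(
            "generation %d: eps=%.6g accepted=%d/%d (rate %.3f) ESS=%.1f wall=%.2fs",
            t, epsilon, N, total, N / total, gen_ess, wall,
        )

        if pop.epsilon <= cfg.min_epsilon:
            logger.info(
                "stopping: epsilon %.6g <= min_epsilon %.6g", pop.epsilon, cfg.min_epsilon
            )
            break
        if cfg.max_walltime is not None and time.monotonic() - t_start > cfg.max_walltime:
            logger.info("stopping: wall-time limit reached after finishing generation %d", t)
            break
    return store


def _config_dict(cfg: ABCConfig) -> dict:
    return {
        "population_size": cfg.population_size,
        "max_generations": cfg.max_generations,
        "min_epsilon": cfg.min_epsilon,
        "epsilon_quantile": cfg.epsilon_quantile,
        "kernel_scale_factor": cfg.kernel_scale_factor,
        "max_walltime": cfg.max_walltime,
        "sim_budget": cfg.sim_budget,
        "initial_epsilon": cfg.initial_epsilon,
        "pilot_size": cfg.pilot_size,
        "seed": cfg.seed,
    }
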