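"""The (mu, lambda) generational loop of ISRES / ISRES+.

Each generation: the population is stochastically ranked, the top mu parents
are selected, and a fresh population of lambda offspring is assembled from

* mu - 1 recombination offspring (each parent moves toward the top-ranked
  parent by a fraction gamma),
* lambda - mu + 1 mutation offspring (parents repeated rank-wise, perturbed
  by self-adaptive log-normal step sizes), and
* when active, n_lin Linstep and n_newt Newton-step offspring that replace
  the mutation offspring of the lowest-ranked parents, keeping the
  population size at exactly lambda.

Parents are discarded (comma selection); the incumbent best over all
generations is tracked separately and never reinserted.  All randomness
flows through named substreams spawned from a single seed, so that toggling
the landscape operators perturbs only their own offspring slots — paired-seed
A/B comparisons between ISRES and ISRES+ are exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .lls import (
    Archive,
    NotEnoughPoints,
    OperatorSkip,
    StagnationGuard,
    cluster_diameter,
    fit_hyperplane,
    fit_quadric,
    linstep_offspring,
    newton_offspring,
    normalized_diameter,
    quadric_min_points,
    select_cluster,
    update_archive,
)
from .problem import BoundsBox, FAILED_OBJECTIVE, Individual, ProblemDefinition
from .ranking import RankingConfig, stochastic_rank

__all__ = [
    "ESConfig",
    "GenerationStats",
    "RunResult",
    "initialize_population",
    "recombine",
    "mutate",
    "smooth_eta",
    "repair_bounds",
    "default_mu",
    "run",
    "ISRESPlus",
]

logger = logging.getLogger(__name__)

_REPAIR_RETRIES = 10


def default_mu(lam: int) -> int:
    """Parent count whose recombination/mutation offspring ratio is closest to 1/7.

    The ratio (mu-1)/(lambda-mu+1) is kept near 1/7 so the two offspring
    routes have roughly equal success probability; lambda = 150 gives mu = 20.
    """
    best, best_err = 2, np.inf
    for mu in range(2, lam):
        err = abs((mu - 1) / (lam - mu + 1) - 1 / 7)
        if err < best_err:
            best, best_err = mu, err
    return best


@dataclass
class ESConfig:
    """All hyperparameters of a run.

    lam/mu: population and parent counts; gamma: recombination fraction;
    alpha: exponential-smoothing factor for step sizes; phi_rate: expected
    convergence rate setting the self-adaptation learning rates; n_lin /
    n_newt / beta_lin / beta_newt_mode: landscape-operator settings;
    *_window: generation intervals (1-based, inclusive; None = open end)
    during which each operator may act.
    """

    lam: int = 150
    mu: Optional[int] = None  # default: ratio (mu-1)/(lam-mu+1) closest to 1/7
    gamma: float = 0.85
    alpha: float = 0.2
    phi_rate: float = 1.0
    max_generations: int = 200
    n_lin: int = 2
    n_newt: int = 1
    beta_lin: float = 2.0
    beta_newt_mode: str = "full_step"
    linstep_window: tuple[int, Optional[int]] = (2, None)
    newton_window: tuple[int, Optional[int]] = (2, None)
    seed: int = 0
    ranking: RankingConfig = field(default_factory=RankingConfig)
    stagnation_eps: float = 1e-6
    archive_capacity: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lam < 2:
            raise ValueError("population size lam must be >= 2")
        if self.mu is None:
            self.mu = default_mu(self.lam)
        if not 1 <= self.mu < self.lam:
            raise ValueError("require 1 <= mu < lam")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.beta_lin < 1.0:
            raise ValueError("beta_lin must be >= 1")
        if self.n_lin < 0 or self.n_newt < 0:
            raise ValueError("operator counts must be non-negative")
        if self.n_lin + self.n_newt > self.lam - self.mu + 1:
            raise ValueError("n_lin + n_newt must not exceed the mutation slot count lam - mu + 1")
        if self.beta_newt_mode not in ("full_step", "uniform_random"):
            raise ValueError("beta_newt_mode must be 'full_step' or 'uniform_random'")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass
class GenerationStats:
    """Per-generation record supporting percentile/histogram summaries."""

    generation: int
    best_f: float
    best_phi: float
    median_f: float
    feasible_count: int
    contributions: dict[str, int]
    best_so_far_f: float


@dataclass
class RunResult:
    best: Individual
    stats: list[GenerationStats]
    n_evaluations: int
    feasible_found: bool
    populations: Optional[list[list[Individual]]] = None


def repair_bounds(
    x: np.ndarray,
    eta: np.ndarray,
    bounds: BoundsBox,
    rng: np.random.Generator,
    center: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Restore out-of-bounds coordinates using the strategy parameters.

    In-bounds coordinates are untouched.  A violating coordinate is redrawn
    from a Gaussian centered on the parent with standard deviation eta[j]
    (up to 10 retries), then reflected across the violated bound, then
    clamped if the reflection still violates.
    """
    x = np.asarray(x, dtype=float).copy()
    center = x if center is None else np.asarray(center, dtype=float)
    lo, hi = bounds.lower, bounds.upper
    for j in np.nonzero((x < lo) | (x > hi))[0]:
        fixed = False
        for _ in range(_REPAIR_RETRIES):
            cand = rng.normal(center[j], eta[j])
            if lo[j] <= cand <= hi[j]:
                x[j] = cand
                fixed = True
                break
        if not fixed:
            if x[j] > hi[j]:
                x[j] = 2 * hi[j] - x[j]
            elif x[j] < lo[j]:
                x[j] = 2 * lo[j] - x[j]
            x[j] = min(max(x[j], lo[j]), hi[j])
    return x


def initialize_population(
    bounds: BoundsBox, cfg: ESConfig, rng: np.random.Generator
) -> list[Individual]:
    """lambda individuals uniform over the box; eta0 = span / sqrt(n)."""
    n = bounds.n
    eta0 = bounds.span / math.sqrt(n)
    pop = []
    for _ in range(cfg.lam):
        x = bounds.lower + bounds.span * rng.random(n)
        pop.append(Individual(x=x, eta=eta0.copy(), origin="init", generation_born=0))
    return pop


def recombine(
    parents: Sequence[Individual],
    gamma: float,
    bounds: BoundsBox,
    rng: np.random.Generator,
    generation: int = 0,
) -> list[Individual]:
    """The top-ranked parent mates with each other parent: x_i + gamma*(x_1 - x_i).

    Each offspring keeps its own parent's strategy parameters unchanged:
    blending eta toward the top parent's would collapse the elite's step-size
    diversity and stall self-adaptation (positions may converge; step sizes
    must stay heritable).  Returns mu - 1 offspring (none when mu < 2).
    """
    if len(parents) < 2:
        return []
    top = parents[0]
    out = []
    for p in parents[1:]:
        x = p.x + gamma * (top.x - p.x)
        eta = p.eta.copy()
        x = repair_bounds(x, eta, bounds, rng, center=p.x)
        out.append(
            Individual(x=x, eta=eta, origin="recombination", generation_born=generation)
        )
    return out


def mutate(
    parent: Individual,
    cfg: ESConfig,
    rng: np.random.Generator,
    bounds: BoundsBox,
    generation: int = 0,
) -> Individual:
    """Self-adaptive log-normal mutation.

    Step sizes update first, eta' = eta * exp(tau' N + tau N_j), with one
    shared N(0,1) per individual (learning rate tau' = phi/sqrt(2n)) and an
    independent N_j per coordinate (tau = phi/sqrt(2 sqrt(n))); the position
    then takes a Gaussian step x' = x + eta' * N_j with fresh draws.
    """
    n = parent.x.size
    tau_prime = cfg.phi_rate / math.sqrt(2.0 * n)
    tau = cfg.phi_rate / math.sqrt(2.0 * math.sqrt(n))
    shared = rng.standard_normal()
    eta_new = parent.eta * np.exp(tau_prime * shared + tau * rng.standard_normal(n))
    x = parent.x + eta_new * rng.standard_normal(n)
    x = repair_bounds(x, eta_new, bounds, rng, center=parent.x)
    return Individual(x=x, eta=eta_new, origin="mutation", generation_born=generation)


def smooth_eta(eta_old: np.ndarray, eta_proposed: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential smoothing of step sizes: eta_old + alpha*(eta_proposed - eta_old)."""
    eta_old = np.asarray(eta_old, dtype=float)
    eta_proposed = np.asarray(eta_proposed, dtype=float)
    return eta_old + alpha * (eta_proposed - eta_old)


class ISRESPlus:
    """Stateful runner; ``run()`` is the one-call interface most users need.

    With ``n_lin = n_newt = 0`` this is baseline ISRES.  Random substreams:
    init / ranking / mutation / operators are spawned separately from the
    seed, so baseline and ISRES+ runs under the same seed share every draw
    outside the operator slots.
    """

    def __init__(self, problem: ProblemDefinition, cfg: ESConfig):
        self.problem = problem
        self.cfg = cfg
        ss = np.random.SeedSequence(cfg.seed)
        s_init, s_rank, s_mut, s_ops = ss.spawn(4)
        self.rng_init = np.random.Generator(np.random.PCG64(s_init))
        self.rng_rank = np.random.Generator(np.random.PCG64(s_rank))
        self.rng_mut = np.random.Generator(np.random.PCG64(s_mut))
        self.rng_ops = np.random.Generator(np.random.PCG64(s_ops))
        self.archive = Archive(problem.bounds.n, capacity=cfg.archive_capacity)
        self.guard = StagnationGuard(eps=cfg.stagnation_eps)
        self.n_evaluations = 0
        self.incumbent: Optional[Individual] = None
        self.incumbent_improved = False
        self.feasible_found = False
        self.generation = 0
        self.population: list[Individual] = []

    # -- bookkeeping ---------------------------------------------------------

    def _evaluate(self, individuals: Sequence[Individual]) -> None:
        for ind in individuals:
            self.problem.evaluate_individual(ind)
            self.n_evaluations += 1

    def _update_incumbent(self, individuals: Sequence[Individual]) -> None:
        improved = False
        for ind in individuals:
            if self.incumbent is None:
                self.incumbent = ind.copy()
                improved = True
                continue
            better = False
            if ind.feasible and not self.incumbent.feasible:
                better = True
            elif ind.feasible and self.incumbent.feasible:
                better = ind.f < self.incumbent.f
            elif not ind.feasible and not self.incumbent.feasible:
                better = ind.phi < self.incumbent.phi
            if better:
                self.incumbent = ind.copy()
                improved = True
        if any(ind.feasible for ind in individuals):
            self.feasible_found = True
        self.incumbent_improved = improved

    def _stats(self) -> GenerationStats:
        f = np.array([ind.f for ind in self.population])
        phi = np.array([ind.phi for ind in self.population])
        feas = np.array([bool(ind.feasible) for ind in self.population])
        if feas.any():
            ff = f[feas]
            i = int(np.argmin(ff))
            best_f, best_phi = float(ff[i]), float(phi[feas][i])
        else:
            i = int(np.argmin(phi))
            best_f, best_phi = float(f[i]), float(phi[i])
        contributions: dict[str, int] = {}
        for ind in self.population:
            contributions[ind.origin] = contributions.get(ind.origin, 0) + 1
        finite = f[np.isfinite(f)]
        return GenerationStats(
            generation=self.generation,
            best_f=best_f,
            best_phi=best_phi,
            median_f=float(np.median(finite)) if finite.size else FAILED_OBJECTIVE,
            feasible_count=int(feas.sum()),
            contributions=contributions,
            best_so_far_f=float(self.incumbent.f) if self.feasible_found else FAILED_OBJECTIVE,
        )

    # -- operators -----------------------------------------------------------

    def _window_contains(self, window: tuple[int, Optional[int]], g: int) -> bool:
        lo, hi = window
        return g >= lo and (hi is None or g <= hi)

    def _fit_with_enlargement(self, order: int):
        """Fit at the minimal cluster size, enlarging 25% on ill-conditioning."""
        n = self.problem.bounds.n
        k = n if order == 1 else quadric_min_points(n)
        min_members = k
        while True:
            cluster = select_cluster(self.archive, self.incumbent, k, self.problem.bounds)
            if cluster.k < min_members:
                logger.debug("order-%d fit skipped: only %d feasible cluster members", order, cluster.k)
                return None, None
            try:
                fit = fit_hyperplane(cluster) if order == 1 else fit_quadric(cluster)
            except NotEnoughPoints:
                return None, None
            if fit.condition_ok:
                return fit, cluster
            if cluster.complete:
                k = max(k + 1, math.ceil(k * 1.25))
                continue
            logger.debug("order-%d fit skipped: ill-conditioned at full archive (cond=%.2e)", order, fit.cond)
            return None, None

    def _operator_offspring(self, g: int) -> tuple[list[Individual], list[Individual]]:
        cfg = self.cfg
        want_lin = cfg.n_lin > 0 and self._window_contains(cfg.linstep_window, g)
        want_newt = cfg.n_newt > 0 and self._window_contains(cfg.newton_window, g)
        if not (want_lin or want_newt):
            return [], []
        if self.incumbent is None or not self.incumbent.feasible:
            logger.debug("operators skipped: no feasible incumbent")
            return [], []
        n = self.problem.bounds.n
        base = select_cluster(self.archive, self.incumbent, n, self.problem.bounds)
        if base.k == 0:
            return [], []
        active = self.guard.decide(
            normalized_diameter(base, self.problem.bounds), self.incumbent_improved
        )
        if not active:
            logger.debug("operators silenced: stagnated cluster bubble")
            return [], []
        lin: list[Individual] = []
        newt: list[Individual] = []
        if want_lin:
            fit, cluster = self._fit_with_enlargement(order=1)
            if fit is not None:
                try:
                    lin = linstep_offspring(
                        cluster, fit, cfg.beta_lin, cfg.n_lin,
                        self.problem.bounds, self.rng_ops, generation=g,
                    )
                except OperatorSkip as exc:
                    logger.debug("linstep skipped: %s", exc)
        if want_newt:
            fit, cluster = self._fit_with_enlargement(order=2)
            if fit is not None:
                try:
                    newt = newton_offspring(
                        self.incumbent, fit, cfg.n_newt, cfg.beta_newt_mode,
                        self.rng_ops, self.problem.bounds, generation=g,
                    )
                except OperatorSkip as exc:
                    logger.debug("newton skipped: %s", exc)
        return lin, newt

    # -- generational loop ---------------------------------------------------

    def initialize(self) -> None:
        self.generation = 0
        self.population = initialize_population(self.problem.bounds, self.cfg, self.rng_init)
        self._evaluate(self.population)
        if all(ind.f == FAILED_OBJECTIVE for ind in self.population):
            raise RuntimeError(
                "objective failed on every individual of the initial population; "
                "check the problem definition"
            )
        self._update_incumbent(self.population)
        update_archive(self.archive, self.population)

    def step_generation(self) -> GenerationStats:
        """Advance one generation; returns the stats of the new population."""
        cfg = self.cfg
        g = self.generation + 1
        order = stochastic_rank(
            self.population, replace(cfg.ranking, n_sweeps=cfg.ranking.n_sweeps or cfg.lam),
            self.rng_rank, tol=self.problem.feasibility_tolerance,
        )
        parents = [self.population[i] for i in order[: cfg.mu]]

        offspring = recombine(parents, cfg.gamma, self.problem.bounds, self.rng_mut, generation=g)
        recomb_srcs = parents[1:]
        mut_srcs = []
        for s in range(cfg.lam - cfg.mu + 1):
            p = parents[s % cfg.mu]
            offspring.append(mutate(p, cfg, self.rng_mut, self.problem.bounds, generation=g))
            mut_srcs.append(p)
        sources = recomb_srcs + mut_srcs

        # landscape operators replace the mutation offspring of the
        # lowest-ranked parents: newton slots just before the linstep slots
        lin, newt = self._operator_offspring(g)
        if lin:
            offspring[cfg.lam - len(lin):] = lin
            sources[cfg.lam - len(lin):] = [None] * len(lin)
        if newt:
            start = cfg.lam - cfg.n_lin - len(newt)
            offspring[start : start + len(newt)] = newt
            sources[start : start + len(newt)] = [None] * len(newt)

        # exponential smoothing of step sizes for all evolutionary offspring
        for child, src in zip(offspring, sources):
            if src is not None:
                child.eta = smooth_eta(src.eta, child.eta, cfg.alpha)

        self._evaluate(offspring)
        self._update_incumbent(offspring)
        update_archive(self.archive, offspring)
        self.population = offspring
        self.generation = g
        stats = self._stats()
        logger.info(
            "gen %d best_f=%.6g feasible=%d origins=%s",
            g, stats.best_so_far_f, stats.feasible_count, stats.contributions,
        )
        return stats

    def run(self, record_populations: bool = False) -> RunResult:
        self.initialize()
        stats = [self._stats()]
        populations = [[ind.copy() for ind in self.population]] if record_populations else None
        for _ in range(self.cfg.max_generations):
            stats.append(self.step_generation())
            if record_populations:
                populations.append([ind.copy() for ind in self.population])
        return RunResult(
            best=self.incumbent.copy(),
            stats=stats,
            n_evaluations=self.n_evaluations,
            feasible_found=self.feasible_found,
            populations=populations,
        )


def run(
    problem: ProblemDefinition, cfg: ESConfig, record_populations: bool = False
) -> RunResult:
    """Run ISRES+ (or baseline ISRES when n_lin = n_newt = 0) on a problem.

    Returns the feasible individual with the lowest objective found in any
    generation; if no feasible individual was ever found, the lowest-penalty
    individual with ``feasible_found=False``.  Deterministic given cfg.seed.
    """
    return ISRESPlus(problem, cfg).run(record_populations=record_populations)
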