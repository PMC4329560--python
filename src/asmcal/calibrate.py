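"""Weighted least-squares objective, fitting goodness, and GA parameter estimation.

The objective is the sigma-normalised sum of squared residuals over all
observables and sampling times,

    J(theta) = sum_i w_i sum_t ((y_obs,i(t) - y_sim,i(t; theta)) / sigma_i)^2,

minimised over box bounds by a real-coded genetic algorithm (tournament
selection, simulated-binary crossover, polynomial mutation, elitism) with
decision variables scaled to [0, 1].  Per-observable fitting goodness is the
Nash-Sutcliffe efficiency R^2 = 1 - SSE/SStot (1 for a perfect fit, 0 for
predicting the observation mean, negative for worse-than-mean predictions).

An optional deterministic local polish (L-BFGS-B inside the bounds, started
from the GA incumbent) sharpens the estimate; it never worsens the
best-so-far objective and preserves seeded reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .datasets import Dataset

__all__ = [
    "GAConfig",
    "GAResult",
    "CalibrationProblem",
    "objective",
    "fitting_goodness",
    "ga_estimate",
]

PENALTY = 1e12


@dataclass(frozen=True)
class GAConfig:
    population: int = 50
    generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float | None = None     # default 1/n_decision
    elitism: int = 2
    seed: int = 0
    stall_generations: int = 40
    stall_tol: float = 1e-10
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    polish: bool = True

    def __post_init__(self):
        if self.population < 10:
            raise ValueError("population must be >= 10")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for r in (self.crossover_rate, self.mutation_rate):
            if r is not None and not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class CalibrationProblem:
    """Decision vector -> simulated observables, judged against a dataset.

    ``predict(x)`` maps the decision vector (parameter subset values, plus
    optional initial observables) to a dict of simulated series aligned with
    the dataset sampling times per observable.  ``names`` labels the
    decision variables; bounds are boxes.
    """

    predict: Callable[[np.ndarray], Mapping[str, np.ndarray]]
    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    dataset: Dataset
    weights: Mapping[str, float] | None = None

    def __post_init__(self):
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        if len(self.dataset) == 0:
            raise ValueError("dataset is empty")
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names/bounds length mismatch")

    def weight(self, observable: str) -> float:
        if self.weights is None:
            return 1.0
        return float(self.weights.get(observable, 1.0))


def objective(x: np.ndarray, problem: CalibrationProblem) -> float:
    """Weighted least-squares objective; simulation failures earn a penalty."""
    try:
        sim = problem.predict(np.asarray(x, float))
    except Exception:
        return PENALTY
    J = 0.0
    for name in problem.dataset.observables:
        y_obs = problem.dataset.values(name)
        y_sim = np.asarray(sim[name], float)
        if y_sim.shape != y_obs.shape or not np.all(np.isfinite(y_sim)):
            return PENALTY
        sigma = problem.dataset.sigmas(name)
        J += problem.weight(name) * float(np.sum(((y_obs - y_sim) / sigma) ** 2))
    return J


def fitting_goodness(sim: np.ndarray, obs: np.ndarray) -> float:
    """Nash-Sutcliffe R^2 = 1 - SSE/SStot; NaN if the observations are constant."""
    sim = np.asarray(sim, float)
    obs = np.asarray(obs, float)
    if obs.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return np.nan
    return 1.0 - float(np.sum((obs - sim) ** 2)) / ss_tot


def per_observable_r2(x: np.ndarray, problem: CalibrationProblem) -> dict[str, float]:
    try:
        sim = problem.predict(np.asarray(x, float))
    except Exception:
        return {name: -np.inf for name in problem.dataset.observables}
    out = {}
    for name in problem.dataset.observables:
        y_sim = np.asarray(sim[name], float)
        if not np.all(np.isfinite(y_sim)):
            out[name] = -np.inf
        else:
            out[name] = fitting_goodness(y_sim, problem.dataset.values(name))
    return out


@dataclass
class GAResult:
    x: np.ndarray
    estimates: dict[str, float]
    objective: float
    trace: np.ndarray               # best-so-far objective per generation
    r2: dict[str, float]
    n_evaluations: int
    penalized_fraction: float
    seed: int
    config: GAConfig

    @property
    def min_r2(self) -> float:
        vals = [v if np.isfinite(v) else -np.inf for v in self.r2.values()]
        # a NaN goodness (constant observable) cannot certify a fit
        vals = [-np.inf if isinstance(v, float) and np.isnan(v) else v
                for v in vals]
        return float(min(vals)) if vals else -np.inf


def _sbx(parents: np.ndarray, rng, rate: float, eta: float) -> np.ndarray:
    """Simulated binary crossover on [0,1] genomes, pairwise."""
    children = parents.copy()
    n, d = parents.shape
    for k in range(0, n - 1, 2):
        if rng.random() >= rate:
            continue
        u = rng.random(d)
        beta = np.where(u <= 0.5,
                        (2 * u) ** (1.0 / (eta + 1)),
                        (1.0 / (2 * (1 - u))) ** (1.0 / (eta + 1)))
        p1, p2 = parents[k], parents[k + 1]
        children[k] = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
        children[k + 1] = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return np.clip(children, 0.0, 1.0)


def _poly_mutation(pop: np.ndarray, rng, rate: float, eta: float) -> np.ndarray:
    """Polynomial mutation, per-gene probability ``rate``."""
    n, d = pop.shape
    mask = rng.random((n, d)) < rate
    u = rng.random((n, d))
    delta = np.where(u < 0.5,
                     (2 * u) ** (1.0 / (eta + 1)) - 1.0,
                     1.0 - (2 * (1 - u)) ** (1.0 / (eta + 1)))
    out = np.where(mask, pop + delta, pop)
    return np.clip(out, 0.0, 1.0)


def ga_estimate(problem: CalibrationProblem, config: GAConfig = GAConfig(),
                fun: Callable[[np.ndarray, CalibrationProblem], float] = objective
                ) -> GAResult:
    """Genetic-algorithm minimisation of the calibration objective over bounds.

    Returns the best decision vector, the per-generation best-so-far trace
    (non-increasing by construction), per-observable fitting goodness at the
    optimum, and bookkeeping for reproducibility.  Aborts with a bounds
    diagnostic if more than half of the initial evaluations are penalised
    simulation failures.
    """
    d = len(problem.names)
    if d == 0:
        raise ValueError("no decision variables")
    rng = np.random.default_rng(config.seed)
    span = problem.upper - problem.lower
    to_x = lambda u: problem.lower + u * span
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / d

    pop = rng.random((config.population, d))
    pop[0] = 0.5                        # include the box centre
    n_eval = 0
    n_penalized = 0

    def evaluate(u_pop):
        nonlocal n_eval, n_penalized
        vals = np.empty(len(u_pop))
        for i, u in enumerate(u_pop):
            vals[i] = fun(to_x(u), problem)
            n_eval += 1
            if vals[i] >= PENALTY:
                n_penalized += 1
        return vals

    fitness = evaluate(pop)
    if np.mean(fitness >= PENALTY) > 0.5:
        raise RuntimeError(
            "more than half of the initial population failed to simulate: "
            "parameter bounds or scenario are likely improper")

    best_i = int(np.argmin(fitness))
    best_u, best_f = pop[best_i].copy(), float(fitness[best_i])
    trace = [best_f]
    stall = 0
    for _ in range(config.generations):
        # tournament selection (size 2)
        a = rng.integers(0, config.population, config.population)
        b = rng.integers(0, config.population, config.population)
        winners = np.where((fitness[a] <= fitness[b])[:, None], pop[a], pop[b])
        children = _sbx(winners, rng, config.crossover_rate, config.eta_crossover)
        children = _poly_mutation(children, rng, mut_rate, config.eta_mutation)
        # elitism: carry the current best individuals through unchanged
        elite_ix = np.argsort(fitness, kind="stable")[:config.elitism]
        children[:config.elitism] = pop[elite_ix]
        child_fit = evaluate(children)
        child_fit[:config.elitism] = fitness[elite_ix]
        pop, fitness = children, child_fit
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_f - config.stall_tol:
            best_f = float(fitness[gen_best])
            best_u = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1
        trace.append(best_f)
        if stall >= config.stall_generations:
            break

    x_best = to_x(best_u)
    if config.polish and best_f < PENALTY:
        res = minimize(lambda x: fun(x, problem), x_best, method="L-BFGS-B",
                       bounds=list(zip(problem.lower, problem.upper)),
                       options={"maxiter": 200})
        n_eval += res.nfev * (d + 1)
        if np.isfinite(res.fun) and res.fun < best_f:
            x_best, best_f = np.clip(res.x, problem.lower, problem.upper), float(res.fun)
            trace.append(best_f)

    return GAResult(
        x=x_best,
        estimates=dict(zip(problem.names, x_best.tolist())),
        objective=best_f,
        trace=np.asarray(trace),
        r2=per_observable_r2(x_best, problem),
        n_evaluations=n_eval,
        penalized_fraction=n_penalized / max(n_eval, 1),
        seed=config.seed,
        config=config,
    )
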