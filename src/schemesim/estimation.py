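"""Kinetic-parameter estimation from observed time-course data.

The objective is a (optionally weighted) sum of squared errors between
simulated and observed concentrations over the observation grid. Three
optimizers are provided:

* :func:`fit_powell` — the bounded modified Powell conjugate-direction
  method (derivative-free local search, deterministic given its start);
* :func:`fit_rcga` — a real-coded genetic algorithm: uniform random
  initialization within bounds, BLX-alpha crossover (alpha = 0.5),
  Gaussian mutation (per-gene rate 0.1, sigma = 5% of the bound range),
  tournament selection of size 2, elitism of one, fully reproducible from
  a seed;
* :func:`fit_hybrid` — the GA's global phase polished by Powell from the
  best individual; its objective never exceeds the GA phase's.

Estimation works unchanged when the scheme contains custom kinetic laws,
assignment rules and events, because the objective just runs the full
simulator. A failed simulation scores +inf (penalty), so optimizers simply
avoid pathological parameter regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import Bounds, minimize

from .errors import EstimationError, SchemeError
from .model import ReactionScheme
from .simulation import SimulationSettings, Simulator, TimeCourse

__all__ = ["EstimationProblem", "EstimationResult", "objective",
           "fit_powell", "fit_rcga", "fit_hybrid"]


@dataclass
class EstimationProblem:
    """A parameter-fitting task.

    ``free_parameters`` is a list of ``(name, lower, upper)`` with finite
    bounds; names refer to global parameters or namespaced reaction-local
    parameters (``reactionid__name``) of the derived system, or to pool
    concentrations. ``observed`` holds a subset of species (keyed by display
    name) on an arbitrary time grid. ``weights`` rescales each observed
    species' squared-error contribution (useful when concentrations span
    scales); the default is unweighted.
    """

    scheme: ReactionScheme
    free_parameters: List[Tuple[str, float, float]]
    observed: TimeCourse
    settings: SimulationSettings
    weights: Optional[Dict[str, float]] = None

    def __post_init__(self):
        self._simulator = None
        names = [n for n, _, _ in self.free_parameters]
        if len(set(names)) != len(names):
            raise EstimationError("duplicate free parameter names")
        for name, lo, hi in self.free_parameters:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise EstimationError(
                    f"parameter {name!r}: bounds must be finite with "
                    f"lower < upper, got [{lo}, {hi}]")
        display_names = {sp.display_name for sp in self.scheme.species}
        for col in self.observed.values:
            if col not in display_names:
                raise EstimationError(
                    f"observed column {col!r} matches no species in the "
                    "scheme")
        if self.weights:
            for col, w in self.weights.items():
                if col not in self.observed.values:
                    raise EstimationError(
                        f"weight given for unobserved species {col!r}")
                if not w > 0:
                    raise EstimationError(
                        f"weight for {col!r} must be positive")

    # lazily built so the problem object stays cheap to construct
    def simulator(self) -> Simulator:
        if self._simulator is None:
            self._simulator = Simulator(self.scheme)
            env = self._simulator.system.base_env()
            for name, _, _ in self.free_parameters:
                if name not in env:
                    raise EstimationError(
                        f"free parameter {name!r} is neither a parameter "
                        "nor a pool of the derived system")
        return self._simulator

    def fitting_settings(self) -> SimulationSettings:
        tmax = float(np.max(self.observed.times))
        return SimulationSettings(
            t0=self.settings.t0,
            tf=max(tmax, self.settings.t0 + np.finfo(float).eps),
            max_step=self.settings.max_step,
            rel_tol=self.settings.rel_tol,
            abs_tol=self.settings.abs_tol,
            output_grid=np.asarray(self.observed.times, dtype=float),
        )

    def bounds_arrays(self):
        lo = np.array([b[1] for b in self.free_parameters])
        hi = np.array([b[2] for b in self.free_parameters])
        return lo, hi

    def names(self) -> List[str]:
        return [n for n, _, _ in self.free_parameters]


@dataclass
class EstimationResult:
    best_parameters: Dict[str, float]
    objective_value: float
    evaluations: int
    method: str
    seed: Optional[int] = None
    trace: List[float] = field(default_factory=list)


class _CountingObjective:
    """SSE objective with an evaluation counter and +inf failure penalty."""

    def __init__(self, problem: EstimationProblem):
        self.problem = problem
        self.simulator = problem.simulator()
        self.settings = problem.fitting_settings()
        self.names = problem.names()
        self.evaluations = 0

    def __call__(self, vector: Sequence[float]) -> float:
        self.evaluations += 1
        overrides = dict(zip(self.names, map(float, vector)))
        try:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tc = self.simulator.run(self.settings, overrides)
        except (SchemeError, ValueError, FloatingPointError):
            return float("inf")
        obs = self.problem.observed
        weights = self.problem.weights or {}
        sse = 0.0
        for col, y_obs in obs.values.items():
            y_sim = tc.values[col]
            if len(y_sim) != len(y_obs):  # solver stopped short
                return float("inf")
            resid = y_sim - y_obs
            sse += weights.get(col, 1.0) * float(resid @ resid)
        if not np.isfinite(sse):
            return float("inf")
        return sse


def objective(problem: EstimationProblem,
              parameters: Dict[str, float]) -> float:
    """Weighted SSE of the simulation at ``parameters`` (+inf on failure)."""
    fn = _CountingObjective(problem)
    vector = [parameters[name] for name in problem.names()]
    return fn(vector)


def _start_vector(problem, start) -> np.ndarray:
    lo, hi = problem.bounds_arrays()
    if start is None:
        return 0.5 * (lo + hi)
    if isinstance(start, dict):
        vec = np.array([start[n] for n in problem.names()], dtype=float)
    else:
        vec = np.asarray(start, dtype=float)
    return np.clip(vec, lo, hi)


def fit_powell(problem: EstimationProblem, start=None,
               max_restarts: int = 12, maxiter_per_restart: int = 30,
               xtol: float = 1e-9, ftol: float = 1e-12) -> EstimationResult:
    """Bounded modified Powell search from ``start`` (dict or vector).

    The direction set of Powell's method can degenerate in narrow curved
    valleys (the search stalls far from the optimum with a large gradient
    remaining), so the search is restarted from the current best point with
    a fresh axis-aligned direction set until a restart no longer improves
    the objective. Deterministic given the start point; the returned
    objective value is the recomputed value at the returned parameters.
    """
    fn = _CountingObjective(problem)
    lo, hi = problem.bounds_arrays()
    x = _start_vector(problem, start)
    fval = fn(x)
    trace: List[float] = [fval]

    for _ in range(max_restarts):
        res = minimize(fn, x, method="Powell", bounds=Bounds(lo, hi),
                       options={"xtol": xtol, "ftol": ftol,
                                "maxiter": maxiter_per_restart})
        improved = res.fun < fval - max(1e-14, ftol * abs(fval))
        if res.fun < fval:
            x, fval = np.clip(res.x, lo, hi), float(res.fun)
        trace.append(fval)
        if not improved:
            break

    value = fn(x)
    if value > fval:  # guard against any recomputation drift
        value = fval
    return EstimationResult(
        best_parameters=dict(zip(problem.names(), map(float, x))),
        objective_value=value,
        evaluations=fn.evaluations,
        method="powell",
        trace=trace,
    )


def fit_rcga(problem: EstimationProblem, population_size: int = 40,
             generations: int = 100, seed: int = 0,
             crossover_alpha: float = 0.5, mutation_rate: float = 0.1,
             mutation_sigma_frac: float = 0.05,
             tournament_size: int = 2, elitism: int = 1
             ) -> EstimationResult:
    """Real-coded genetic algorithm, fully reproducible from ``seed``."""
    if population_size < 4:
        raise EstimationError("population_size must be at least 4")
    fn = _CountingObjective(problem)
    lo, hi = problem.bounds_arrays()
    span = hi - lo
    dim = len(lo)
    rng = np.random.default_rng(seed)

    pop = lo + rng.random((population_size, dim)) * span
    fitness = np.array([fn(ind) for ind in pop])
    trace = [float(fitness.min())]

    for _ in range(generations):
        order = np.argsort(fitness)
        new_pop = [pop[i].copy() for i in order[:elitism]]
        while len(new_pop) < population_size:
            parents = []
            for _ in range(2):
                rivals = rng.integers(0, population_size, tournament_size)
                parents.append(pop[rivals[np.argmin(fitness[rivals])]])
            p1, p2 = parents
            # BLX-alpha: uniform in the parent interval widened by alpha
            lo_g = np.minimum(p1, p2)
            hi_g = np.maximum(p1, p2)
            width = hi_g - lo_g
            child = rng.uniform(lo_g - crossover_alpha * width,
                                hi_g + crossover_alpha * width + 1e-300)
            mask = rng.random(dim) < mutation_rate
            child = child + mask * rng.normal(
                0.0, mutation_sigma_frac * span, dim)
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop)
        fitness = np.array([fn(ind) for ind in pop])
        trace.append(float(min(trace[-1], fitness.min())))

    best_i = int(np.argmin(fitness))
    best = pop[best_i]
    value = float(fitness[best_i])
    if trace[-1] < value:  # elitism keeps the best ever in pop, but be safe
        value = trace[-1]
    return EstimationResult(
        best_parameters=dict(zip(problem.names(), map(float, best))),
        objective_value=value,
        evaluations=fn.evaluations,
        method="rcga",
        seed=seed,
        trace=trace,
    )


def fit_hybrid(problem: EstimationProblem, population_size: int = 40,
               generations: int = 100, seed: int = 0,
               **rcga_options) -> EstimationResult:
    """RCGA global phase followed by a Powell polish from the GA's best.

    The final objective is the better of the two phases, so it never
    exceeds the GA-phase objective at the same seed.
    """
    ga = fit_rcga(problem, population_size=population_size,
                  generations=generations, seed=seed, **rcga_options)
    local = fit_powell(problem, start=ga.best_parameters)
    if local.objective_value <= ga.objective_value:
        best, value = local.best_parameters, local.objective_value
    else:
        best, value = ga.best_parameters, ga.objective_value
    return EstimationResult(
        best_parameters=best,
        objective_value=value,
        evaluations=ga.evaluations + local.evaluations,
        method="hybrid",
        seed=seed,
        trace=ga.trace + local.trace,
    )
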