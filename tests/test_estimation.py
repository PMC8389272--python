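"""Parameter estimation: SSE objective, Powell, RCGA and the hybrid."""

import numpy as np
import pytest

import schemesim as ss
from schemesim import fixtures as fx
from schemesim.errors import EstimationError
from schemesim.estimation import (EstimationProblem, fit_hybrid, fit_powell,
                                  fit_rcga, objective)


def _observe(scheme, species, tf=20.0, n=11, max_step=1.0, noise=0.0,
             rng=None):
    settings = ss.SimulationSettings(tf=tf, max_step=max_step, output_grid=n)
    tc = ss.simulate(scheme, settings)
    values = {k: tc.values[k].copy() for k in species}
    if noise:
        for k in values:
            values[k] = values[k] + rng.normal(
                0.0, noise * max(1.0, np.max(np.abs(values[k]))), n)
    observed = ss.TimeCourse(times=tc.times, values=values)
    return observed, settings


def _chain_problem(n=2, species=("X2",), bounds=(0.01, 1.0), **kw):
    scheme = fx.make_linear_chain(n=n)
    observed, settings = _observe(scheme, species, **kw)
    n_params = n  # k1..kn (terminal outflow)
    free = [(f"k{j}", bounds[0], bounds[1]) for j in range(1, n_params + 1)]
    return EstimationProblem(scheme=scheme, free_parameters=free,
                             observed=observed, settings=settings)


# ---------------------------------------------------------------------------
# Objective


def test_objective_is_zero_at_generating_parameters():
    prob = _chain_problem()
    assert objective(prob, {"k1": 0.1, "k2": 0.1}) <= 1e-10


def test_objective_positive_for_wrong_parameters():
    prob = _chain_problem()
    assert objective(prob, {"k1": 0.3, "k2": 0.1}) > 1.0


def test_objective_matches_hand_computed_sse(ab_toy):
    # 2 observation points, 1 species: SSE computable by hand
    observed = ss.TimeCourse(times=np.array([0.0, 1.0]),
                             values={"B": np.array([0.0, 0.5])})
    settings = ss.SimulationSettings(tf=1.0, output_grid=2)
    prob = EstimationProblem(scheme=ab_toy,
                             free_parameters=[("k1", 0.01, 2.0)],
                             observed=observed, settings=settings)
    k = 0.5
    b1 = 1.0 - np.exp(-k)   # B(1) for A(0)=1
    expected = (0.0 - 0.0) ** 2 + (b1 - 0.5) ** 2
    assert objective(prob, {"k1": k}) == pytest.approx(expected, abs=1e-6)


def test_objective_respects_weights(ab_toy):
    observed = ss.TimeCourse(times=np.array([1.0]),
                             values={"A": np.array([0.0]),
                                     "B": np.array([0.0])})
    settings = ss.SimulationSettings(tf=1.0, output_grid=2)
    base = EstimationProblem(scheme=ab_toy,
                             free_parameters=[("k1", 0.01, 2.0)],
                             observed=observed, settings=settings)
    weighted = EstimationProblem(scheme=ab_toy,
                                 free_parameters=[("k1", 0.01, 2.0)],
                                 observed=observed, settings=settings,
                                 weights={"A": 2.0, "B": 1.0})
    a = np.exp(-0.5)
    b = 1.0 - a
    assert objective(base, {"k1": 0.5}) == pytest.approx(a * a + b * b,
                                                         abs=1e-6)
    assert objective(weighted, {"k1": 0.5}) == pytest.approx(
        2 * a * a + b * b, abs=1e-6)


def test_problem_validation():
    scheme = fx.make_linear_chain(n=2)
    observed = ss.TimeCourse(times=np.array([1.0]),
                             values={"nope": np.array([1.0])})
    with pytest.raises(EstimationError, match="nope"):
        EstimationProblem(scheme=scheme,
                          free_parameters=[("k1", 0.01, 1.0)],
                          observed=observed,
                          settings=ss.SimulationSettings(tf=1.0))
    good = ss.TimeCourse(times=np.array([1.0]),
                         values={"X2": np.array([1.0])})
    with pytest.raises(EstimationError, match="bounds"):
        EstimationProblem(scheme=scheme,
                          free_parameters=[("k1", 1.0, 0.5)],
                          observed=good,
                          settings=ss.SimulationSettings(tf=1.0))


# ---------------------------------------------------------------------------
# Powell


def test_powell_converges_to_quadratic_minimum():
    """Zero-order inflow: X2(t) = 100 k t, so the SSE is a parabola in k
    with an analytically known minimum."""
    scheme = fx.make_linear_chain(n=2, terminal_outflow=False)
    observed = ss.TimeCourse(times=np.array([1.0]),
                             values={"X2": np.array([7.0])})
    prob = EstimationProblem(
        scheme=scheme, free_parameters=[("k1", 0.001, 1.0)],
        observed=observed,
        settings=ss.SimulationSettings(tf=1.0, max_step=1.0))
    res = fit_powell(prob, start={"k1": 0.5})
    assert res.best_parameters["k1"] == pytest.approx(0.07, abs=1e-8)


def test_powell_recovers_chain_rates():
    prob = _chain_problem(species=("X2",))
    res = fit_powell(prob, start={"k1": 0.05, "k2": 0.05},
                     xtol=1e-7, max_restarts=8)
    for v in res.best_parameters.values():
        assert v == pytest.approx(0.1, abs=1e-3)
    assert res.method == "powell"


def test_powell_from_truth_stays_at_truth():
    prob = _chain_problem()
    res = fit_powell(prob, start={"k1": 0.1, "k2": 0.1})
    assert res.objective_value <= 1e-10
    for v in res.best_parameters.values():
        assert v == pytest.approx(0.1, abs=1e-6)


# ---------------------------------------------------------------------------
# RCGA


def test_rcga_is_deterministic_given_seed():
    prob = _chain_problem()
    a = fit_rcga(prob, population_size=8, generations=5, seed=123)
    b = fit_rcga(prob, population_size=8, generations=5, seed=123)
    assert a.best_parameters == b.best_parameters
    assert a.objective_value == b.objective_value
    assert a.trace == b.trace
    c = fit_rcga(prob, population_size=8, generations=5, seed=124)
    assert c.best_parameters != a.best_parameters


def test_rcga_improves_over_random_initialization():
    prob = _chain_problem()
    improved = 0
    for seed in range(5):
        res = fit_rcga(prob, population_size=12, generations=15, seed=seed)
        if res.objective_value < res.trace[0]:
            improved += 1
        assert res.objective_value <= res.trace[0]
    assert improved >= 3


def test_rcga_tight_bounds_recovery():
    prob = _chain_problem(bounds=(0.09, 0.11))
    res = fit_rcga(prob, population_size=20, generations=30, seed=2)
    for v in res.best_parameters.values():
        assert v == pytest.approx(0.1, abs=5e-3)


# ---------------------------------------------------------------------------
# Hybrid


def test_hybrid_never_worse_than_rcga():
    prob = _chain_problem()
    for seed in (0, 1, 2):
        ga = fit_rcga(prob, population_size=10, generations=8, seed=seed)
        hy = fit_hybrid(prob, population_size=10, generations=8, seed=seed)
        assert hy.objective_value <= ga.objective_value
        assert hy.method == "hybrid" and hy.seed == seed


def test_hybrid_recovers_chain_rates():
    prob = _chain_problem()
    res = fit_hybrid(prob, population_size=16, generations=12, seed=3)
    for v in res.best_parameters.values():
        assert v == pytest.approx(0.1, rel=1e-3)


def test_hybrid_escapes_local_basin_where_powell_does_not():
    """Two-basin landscape: a narrow global basin at k = 0.2 and a broad
    spurious one at k = 1.5; Powell started at k = 1.9 settles in the
    spurious basin, the hybrid's population sampling finds the true one."""
    scheme = ss.ReactionScheme(layers=["main"], name="two_basin")
    scheme.species.append(ss.SpeciesSymbol(
        id="A", initial_concentration=1.0, reactant_type="pool"))
    scheme.species.append(ss.SpeciesSymbol(id="C"))
    scheme.global_parameters["k"] = 0.2
    scheme.reactions.append(ss.ReactionStep(
        id="r2", substrates=[ss.Participant("A")],
        products=[ss.Participant("C")],
        kinetic_law=ss.KineticLaw(
            kind="custom",
            expression="min(8*abs(k-0.2), 0.8+0.1*abs(k-1.5))*A")))
    observed, settings = _observe(scheme, ("C",), tf=10, n=6)
    prob = EstimationProblem(scheme=scheme,
                             free_parameters=[("k", 0.01, 2.0)],
                             observed=observed, settings=settings)
    stuck = fit_powell(prob, start={"k": 1.9})
    assert abs(stuck.best_parameters["k"] - 1.5) < 0.1   # trapped
    wins = 0
    for seed in range(10):
        hy = fit_hybrid(prob, population_size=20, generations=15, seed=seed)
        if hy.objective_value < stuck.objective_value \
                and abs(hy.best_parameters["k"] - 0.2) < 0.05:
            wins += 1
    assert wins >= 8


def test_estimation_with_rules_and_events(rule_event_toy):
    """The objective runs the full simulator, so schemes with rules and
    events are estimable unchanged."""
    observed, settings = _observe(rule_event_toy, ("A", "total"), tf=20,
                                  n=21, max_step=0.5)
    prob = EstimationProblem(scheme=rule_event_toy,
                             free_parameters=[("k_dec", 0.01, 1.0)],
                             observed=observed, settings=settings)
    res = fit_powell(prob, start={"k_dec": 0.5})
    assert res.best_parameters["k_dec"] == pytest.approx(0.2, rel=1e-3)


def test_noise_error_shrinks_with_more_observations():
    """Median recovery error over 10 seeds decreases monotonically as the
    observation grid densifies (5% Gaussian noise)."""
    medians = []
    for n_obs in (5, 20, 80):
        errors = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            scheme = fx.make_linear_chain(n=2)
            observed, settings = _observe(scheme, ("X2",), tf=20, n=n_obs,
                                          noise=0.05, rng=rng)
            prob = EstimationProblem(
                scheme=scheme,
                free_parameters=[("k2", 0.01, 1.0)],
                observed=observed, settings=settings)
            res = fit_powell(prob, start={"k2": 0.05},
                             xtol=1e-6, max_restarts=4,
                             maxiter_per_restart=20)
            errors.append(abs(res.best_parameters["k2"] - 0.1))
        medians.append(float(np.median(errors)))
    assert medians[0] > medians[1] > medians[2], medians
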