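"""Simulation: closed forms, linear-system oracle, rules, events, CSV I/O."""

import io

import numpy as np
import pytest
from scipy.linalg import expm

import schemesim as ss
from schemesim import fixtures as fx
from schemesim.errors import TimeCourseFormatError


def test_pool_fed_chain_matches_closed_form():
    """X2' = k*100 - k*X2  =>  X2(t) = 100 (1 - e^{-0.1 t})."""
    scheme = fx.make_linear_chain(n=2, k=0.1)
    tc = ss.simulate(scheme, ss.SimulationSettings(tf=20, output_grid=41))
    expected = 100.0 * (1.0 - np.exp(-0.1 * tc.times))
    assert np.max(np.abs(tc.values["X2"] - expected)) < 1e-3
    assert tc.values["X2"][-1] == pytest.approx(86.466, abs=1e-3)


def test_chain_without_outflow_grows_linearly():
    scheme = fx.make_linear_chain(n=2, k=0.1, terminal_outflow=False)
    tc = ss.simulate(scheme, ss.SimulationSettings(tf=10, output_grid=11))
    assert np.max(np.abs(tc.values["X2"] - 10.0 * tc.times)) < 1e-3


def test_chain_with_empty_pool_stays_at_zero():
    scheme = fx.make_linear_chain(n=2, x1_constant=0.0)
    tc = ss.simulate(scheme, ss.SimulationSettings(tf=10, output_grid=11))
    assert np.all(tc.values["X2"] == 0.0)


def test_no_reactions_means_constant_columns():
    scheme = ss.ReactionScheme(layers=["main"])
    scheme.species.append(ss.SpeciesSymbol(id="A", initial_concentration=2.5))
    scheme.species.append(ss.SpeciesSymbol(
        id="P", initial_concentration=7.0, reactant_type="pool"))
    tc = ss.simulate(scheme, ss.SimulationSettings(tf=5, output_grid=11))
    assert np.all(tc.values["A"] == 2.5)
    assert np.all(tc.values["P"] == 7.0)


def test_pool_columns_are_constant(chain3):
    tc = ss.simulate(chain3, ss.SimulationSettings(tf=10, output_grid=21))
    assert np.all(tc.values["X1"] == 100.0)
    assert np.all(np.diff(tc.times) > 0)


# ---------------------------------------------------------------------------
# Matrix-exponential oracle for first-order schemes


def _random_linear_scheme(rng, n):
    """First-order mass-action scheme: unimolecular conversions and decays,
    plus a pool-fed inflow, all with coefficient 1 (a linear ODE system)."""
    scheme = ss.ReactionScheme(layers=["main"], name="linear")
    scheme.species.append(ss.SpeciesSymbol(
        id="F", initial_concentration=float(rng.uniform(1, 5)),
        reactant_type="pool"))
    for i in range(n):
        scheme.species.append(ss.SpeciesSymbol(
            id=f"Y{i}", initial_concentration=float(rng.uniform(0, 3))))
    count = 0

    def add(sub, prods):
        nonlocal count
        count += 1
        k = f"k{count}"
        scheme.global_parameters[k] = float(rng.uniform(0.05, 0.6))
        scheme.reactions.append(ss.ReactionStep(
            id=f"r{count}", substrates=[ss.Participant(sub)],
            products=[ss.Participant(p) for p in prods],
            kinetic_law=ss.KineticLaw(kind="mass_action", rate_constant=k)))

    add("F", [f"Y{rng.integers(n)}"])                 # constant inflow
    for _ in range(2 * n):
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        if i == j:
            add(f"Y{i}", [])                          # decay
        else:
            add(f"Y{i}", [f"Y{j}"])                   # conversion
    return scheme


def _linear_oracle(scheme, system, times):
    """x(t) via the augmented matrix exponential of x' = A x + b."""
    n = system.n_states
    A = np.zeros((n, n))
    b = np.zeros(n)
    env = system.base_env()
    for rxn in scheme.reactions:
        k = env[rxn.kinetic_law.rate_constant]
        sub, _ = scheme.resolve_participant(rxn.substrates[0])
        prods = [scheme.resolve_participant(p)[0] for p in rxn.products]
        if sub.id in system.pool_values:
            flux = k * system.pool_values[sub.id]
            for p in prods:
                b[system.state_index[p.id]] += flux
        else:
            i = system.state_index[sub.id]
            A[i, i] -= k
            for p in prods:
                A[system.state_index[p.id], i] += k
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = b
    x0 = np.append(system.initial_state(), 1.0)
    return np.stack([(expm(M * t) @ x0)[:n] for t in times])


def test_linear_schemes_match_matrix_exponential():
    rng = np.random.default_rng(5)
    for _ in range(5):
        scheme = _random_linear_scheme(rng, int(rng.integers(2, 5)))
        system = ss.derive(scheme)
        tc = ss.simulate(scheme, ss.SimulationSettings(
            tf=10, output_grid=21, rel_tol=1e-10, abs_tol=1e-13))
        expected = _linear_oracle(scheme, system, tc.times)
        scale = max(1.0, np.max(np.abs(expected)))
        for sid, i in system.state_index.items():
            err = np.max(np.abs(tc.values[sid] - expected[:, i]))
            assert err / scale < 1e-6, sid


def test_tightening_tolerances_is_self_consistent(chain3):
    coarse = ss.simulate(chain3, ss.SimulationSettings(
        tf=30, output_grid=16, rel_tol=1e-6, abs_tol=1e-9))
    fine = ss.simulate(chain3, ss.SimulationSettings(
        tf=30, output_grid=16, rel_tol=1e-7, abs_tol=1e-10))
    for k in coarse.values:
        scale = max(1.0, np.max(np.abs(fine.values[k])))
        assert np.max(np.abs(coarse.values[k] - fine.values[k])) / scale \
            < 1e-6


# ---------------------------------------------------------------------------
# Rules and events


def test_rule_output_equals_sum_of_inputs(rule_event_toy):
    tc = ss.simulate(rule_event_toy,
                     ss.SimulationSettings(tf=20, output_grid=41))
    recomputed = (tc.values["c1"] + tc.values["c2"] + tc.values["c3"]
                  + tc.values["c4"])
    assert np.array_equal(tc.values["total"], recomputed)


def test_event_matches_piecewise_closed_form(rule_event_toy):
    tc = ss.simulate(rule_event_toy,
                     ss.SimulationSettings(tf=20, output_grid=81))
    expected = np.exp(-0.2 * np.minimum(tc.times, 10.0))
    assert np.max(np.abs(tc.values["A"] - expected)) < 1e-6
    assert [eid for _, eid in tc.event_log] == ["stop_decay"]
    assert tc.event_log[0][0] == pytest.approx(10.0, abs=1e-6)


def test_event_fires_only_on_false_to_true(ab_toy):
    """A trigger already true at t0 must not fire at t0."""
    s = ss.scheme_from_dict(ss.scheme_to_dict(ab_toy))
    s.events.append(ss.EventSpec(id="at_start", trigger="t >= 0",
                                 assignments=[("k1", "0")]))
    tc = ss.simulate(s, ss.SimulationSettings(tf=5, output_grid=11))
    assert tc.event_log == []
    assert tc.values["A"][-1] < 0.2  # decay still happened


def test_event_state_assignment(ab_toy):
    s = ss.scheme_from_dict(ss.scheme_to_dict(ab_toy))
    s.events.append(ss.EventSpec(id="refill", trigger="A < 0.5",
                                 assignments=[("A", "2")]))
    tc = ss.simulate(s, ss.SimulationSettings(tf=6, output_grid=121))
    assert len(tc.event_log) >= 2          # refires after re-arming
    assert np.max(tc.values["A"]) <= 2.0 + 1e-9
    after = tc.values["A"][tc.times > tc.event_log[0][0] + 0.1]
    assert np.max(after) > 1.0             # the refill is visible


def test_negative_concentration_warns():
    s = ss.ReactionScheme(layers=["main"])
    s.species.append(ss.SpeciesSymbol(id="A", initial_concentration=1.0))
    s.global_parameters["k"] = 1.0
    s.reactions.append(ss.ReactionStep(
        id="drain", substrates=[ss.Participant("A")], products=[],
        kinetic_law=ss.KineticLaw(
            kind="custom", expression="k")))  # zero-order: goes negative
    with pytest.warns(UserWarning, match="negative concentration"):
        ss.simulate(s, ss.SimulationSettings(tf=3, output_grid=7))


# ---------------------------------------------------------------------------
# CSV round trip


def test_timecourse_round_trip(chain3):
    tc = ss.simulate(chain3, ss.SimulationSettings(tf=10, output_grid=21))
    buf = io.StringIO()
    ss.write_timecourse(tc, buf)
    buf.seek(0)
    back = ss.read_timecourse(buf)
    assert list(back.values) == list(tc.values)
    assert np.allclose(back.times, tc.times, rtol=1e-11, atol=0)
    for k in tc.values:
        assert np.allclose(back.values[k], tc.values[k], rtol=1e-11,
                           atol=1e-300)


def test_quoted_display_names_survive_csv(butanol):
    tc = ss.simulate(butanol, ss.SimulationSettings(tf=1, output_grid=3))
    buf = io.StringIO()
    ss.write_timecourse(tc, buf)
    buf.seek(0)
    back = ss.read_timecourse(buf)
    assert "1,3-diphosphoglycerate" in back.values


def test_empty_timecourse_writes_header_only():
    tc = ss.TimeCourse(times=np.array([]), values={"A": np.array([])})
    buf = io.StringIO()
    ss.write_timecourse(tc, buf)
    assert buf.getvalue().strip() == "time,A"


def test_malformed_csv_is_reported():
    with pytest.raises(TimeCourseFormatError, match="time"):
        ss.read_timecourse(io.StringIO("wrong,A\n1,2\n"))
    with pytest.raises(TimeCourseFormatError, match="increasing"):
        ss.read_timecourse(io.StringIO("time,A\n1,2\n1,3\n"))
    with pytest.raises(TimeCourseFormatError):
        ss.read_timecourse(io.StringIO(""))


# ---------------------------------------------------------------------------
# Layer invisibility (shared with acceptance, exercised per fixture here)


def test_simulation_identical_after_flatten(all_fixture_schemes):
    for name, scheme in all_fixture_schemes.items():
        settings = ss.SimulationSettings(tf=5.0, output_grid=11)
        a = ss.simulate(scheme, settings)
        b = ss.simulate(ss.flatten(scheme), settings)
        for k in a.values:
            assert np.allclose(a.values[k], b.values[k],
                               rtol=0, atol=1e-12), (name, k)
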