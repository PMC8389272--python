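"""Stiff time-course simulation with pools, assignment rules and events.

Integration uses scipy's variable-order BDF implementation (the Gear family
of multistep methods for stiff systems), honoring an explicit maximum step
size. Event triggers are monitored continuously: each boolean trigger is
turned into a signed margin (positive iff true) whose zero crossing the
solver localizes by root finding; at a false->true crossing the integration
stops, the event's assignments are applied, and integration restarts from
the event time. Triggers already true at t0 do not fire at t0, and an event
re-arms only after its trigger has gone false again. Simultaneous events
fire in declaration order.

Assignment-rule targets and constant pools are not states; they are
evaluated at every reported time and included in the output table.
Negative concentrations are reported (with a warning), never clamped —
clamping would silently change the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import expressions as ex
from .derivation import DerivedSystem, derive, make_evaluator
from .errors import IntegrationError, TimeCourseFormatError
from .model import ReactionScheme

__all__ = ["SimulationSettings", "TimeCourse", "Simulator", "simulate",
           "write_timecourse", "read_timecourse"]

_EVENT_TIME_RTOL = 1e-9


@dataclass
class SimulationSettings:
    """Integration settings.

    ``max_step`` defaults to 0.1, the simulator's standard maximum step size
    for the Gear/BDF integrator; ``output_grid`` is either an explicit array
    of report times or a point count for a uniform grid over [t0, tf].
    """

    t0: float = 0.0
    tf: float = 100.0
    max_step: float = 0.1
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    output_grid: Union[int, np.ndarray, None] = None

    def __post_init__(self):
        if not self.tf > self.t0:
            raise ValueError(f"tf ({self.tf}) must exceed t0 ({self.t0})")
        if not self.max_step > 0:
            raise ValueError("max_step must be positive")

    def grid(self) -> np.ndarray:
        if self.output_grid is None:
            return np.linspace(self.t0, self.tf, 501)
        if isinstance(self.output_grid, int):
            return np.linspace(self.t0, self.tf, self.output_grid)
        g = np.asarray(self.output_grid, dtype=float)
        if g.ndim != 1 or len(g) < 1 or np.any(np.diff(g) <= 0):
            raise ValueError("output_grid must be strictly increasing")
        if g[0] < self.t0 or g[-1] > self.tf:
            raise ValueError("output_grid must lie within [t0, tf]")
        return g


@dataclass
class TimeCourse:
    """Simulated or observed trajectories keyed by species display name."""

    times: np.ndarray
    values: Dict[str, np.ndarray]
    event_log: List[Tuple[float, str]] = field(default_factory=list)

    def species(self) -> List[str]:
        return list(self.values)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, **self.values})


class Simulator:
    """Compiled simulator for one scheme; reusable across parameter sets.

    Compiling the right-hand side, rule evaluators and event machinery once
    and re-running with ``parameter_overrides`` is what makes repeated
    estimation objective evaluations cheap.
    """

    def __init__(self, scheme: ReactionScheme,
                 system: Optional[DerivedSystem] = None):
        self.scheme = scheme
        self.system = system if system is not None else derive(scheme)
        sys_ = self.system

        self._rule_values = make_evaluator(
            sys_, [ex.Sym(t) for t, _ in sys_.rule_order])

        self._events = []
        for ev in scheme.events:
            trig = ex.parse(ev.trigger)
            margin = make_evaluator(sys_, [ex.margin_ast(trig.ast)])
            assigns = [(target, make_evaluator(sys_, [ex.parse(value).ast]))
                       for target, value in ev.assignments]
            self._events.append((ev, margin, assigns))

    # -- helpers -----------------------------------------------------------
    def _apply_assignments(self, ev, assigns, t, x, env):
        sys_ = self.system
        values = [(target, float(fn(t, x, env)[0])) for target, fn in assigns]
        for target, value in values:  # evaluate all, then assign (SBML-style)
            if target in sys_.state_index:
                x[sys_.state_index[target]] = value
            elif target in env:
                env[target] = value
            else:
                raise IntegrationError(
                    f"event {ev.id!r}: assignment target {target!r} is "
                    f"neither a state nor in the environment", last_time=t)

    def run(self, settings: SimulationSettings,
            parameter_overrides: Optional[Dict[str, float]] = None
            ) -> TimeCourse:
        sys_ = self.system
        env = sys_.base_env()
        if parameter_overrides:
            unknown = set(parameter_overrides) - set(env)
            if unknown:
                raise KeyError(
                    f"unknown parameter override(s): {sorted(unknown)}")
            env.update(parameter_overrides)

        grid = settings.grid()
        x = sys_.initial_state()
        t = settings.t0

        if sys_.n_states == 0:
            # nothing to integrate: report pools/rule targets on the grid
            snaps = [dict(env)] * len(grid)
            return self._assemble(grid, [x] * len(grid), list(range(len(grid))),
                                  snaps, [], settings)

        times: List[float] = []
        states: List[np.ndarray] = []
        seg_of_point: List[int] = []
        env_snapshots: List[Dict[str, float]] = []
        event_log: List[Tuple[float, str]] = []

        def snapshot():
            env_snapshots.append(dict(env))
            return len(env_snapshots) - 1

        seg = snapshot()
        if grid[0] == settings.t0:
            times.append(t)
            states.append(x.copy())
            seg_of_point.append(seg)

        armed = [float(margin(t, x, env)[0]) < 0
                 for _, margin, _ in self._events]

        def rhs(tt, xx):
            return sys_.rhs(tt, xx, env)

        while t < settings.tf:
            ev_funcs = []
            for idx, (ev, margin, _) in enumerate(self._events):
                def g(tt, xx, _margin=margin):
                    return float(_margin(tt, xx, env)[0])
                g.terminal = True
                g.direction = 1.0 if armed[idx] else -1.0
                ev_funcs.append(g)

            t_eval = grid[(grid > t) & (grid <= settings.tf)]
            sol = solve_ivp(
                rhs, (t, settings.tf), x, method="BDF",
                t_eval=t_eval if len(t_eval) else None,
                max_step=settings.max_step,
                rtol=settings.rel_tol, atol=settings.abs_tol,
                events=ev_funcs if ev_funcs else None,
                jac_sparsity=(sys_.jac_sparsity
                              if sys_.n_states > 8 else None),
            )
            if sol.status == -1:
                last = times[-1] if times else t
                raise IntegrationError(
                    f"stiff solver failed: {sol.message}", last_time=last)

            hit_time = None
            if sol.status == 1:
                hit_time = min(te[0] for te in sol.t_events if len(te))

            for k, tk in enumerate(sol.t):
                if len(t_eval) and (hit_time is None or tk <= hit_time):
                    times.append(tk)
                    states.append(sol.y[:, k].copy())
                    seg_of_point.append(seg)

            if sol.status == 0:
                break

            # event segment boundary
            tol = _EVENT_TIME_RTOL * max(1.0, abs(hit_time))
            x_hit = None
            fired_any = False
            for idx, (ev, margin, assigns) in enumerate(self._events):
                te = sol.t_events[idx]
                if len(te) == 0 or abs(te[0] - hit_time) > tol:
                    continue
                if x_hit is None:
                    x_hit = sol.y_events[idx][0].copy()
                if armed[idx]:
                    self._apply_assignments(ev, assigns, hit_time, x_hit, env)
                    event_log.append((hit_time, ev.id))
                    armed[idx] = False
                    fired_any = True
                else:
                    armed[idx] = True  # trigger fell back to false: re-arm
            t = hit_time
            x = x_hit if x_hit is not None else x
            if fired_any:
                seg = snapshot()
            # assignments may flip their own trigger (e.g. a refill event
            # resetting the species it watches): recompute arming from the
            # post-assignment margin, keeping the crossing-direction value
            # only when the margin is too close to zero to tell
            for idx, (_, margin, _) in enumerate(self._events):
                m = float(margin(t, x, env)[0])
                if m > 1e-8:
                    armed[idx] = False
                elif m < -1e-8:
                    armed[idx] = True

        return self._assemble(np.array(times), states, seg_of_point,
                              env_snapshots, event_log, settings)

    def _assemble(self, times, states, seg_of_point, env_snapshots,
                  event_log, settings):
        sys_ = self.system
        n = len(times)
        columns: Dict[str, np.ndarray] = {}
        for sid in sys_.species_order:
            columns[sid] = np.empty(n)
        for k in range(n):
            x = states[k]
            env = env_snapshots[seg_of_point[k]]
            for sid, i in sys_.state_index.items():
                columns[sid][k] = x[i]
            for pid in sys_.pool_values:
                columns[pid][k] = env[pid]
            if sys_.rule_order:
                vals = self._rule_values(times[k], x, env)
                for (target, _), v in zip(sys_.rule_order, vals):
                    columns[target][k] = v

        if n and sys_.state_index:
            lowest = min(columns[sid].min() for sid in sys_.state_index)
            if lowest < -10 * settings.abs_tol:
                warnings.warn(
                    f"negative concentration reached (min {lowest:.3g}); "
                    "values are reported, not clamped", stacklevel=3)

        values = {sys_.display_names[sid]: columns[sid]
                  for sid in sys_.species_order}
        return TimeCourse(times=times, values=values, event_log=event_log)


def simulate(scheme: ReactionScheme, settings: SimulationSettings,
             parameter_overrides: Optional[Dict[str, float]] = None
             ) -> TimeCourse:
    """Derive, compile and integrate ``scheme`` over ``settings``."""
    return Simulator(scheme).run(settings, parameter_overrides)


# ---------------------------------------------------------------------------
# CSV I/O


def write_timecourse(tc: TimeCourse, destination) -> None:
    """Write a time course as CSV: ``time,<species display names...>``.

    Values carry 12 significant digits, enough for a lossless round trip at
    the 1e-12 level; display names containing commas are quoted.
    """
    tc.as_frame().to_csv(destination, index=False, float_format="%.12g")


def read_timecourse(source) -> TimeCourse:
    """Read a time-course CSV written by :func:`write_timecourse`.

    Also accepts observed-data files: any CSV whose first column is
    ``time`` (strictly increasing) and whose remaining columns are species
    display names.
    """
    try:
        frame = pd.read_csv(source)
    except pd.errors.ParserError as e:
        raise TimeCourseFormatError(f"malformed time-course CSV: {e}") from e
    except pd.errors.EmptyDataError as e:
        raise TimeCourseFormatError("empty time-course CSV") from e
    if frame.columns[0] != "time":
        raise TimeCourseFormatError(
            f"first column must be 'time', got {frame.columns[0]!r}")
    times = frame["time"].to_numpy(dtype=float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise TimeCourseFormatError("time column must be strictly increasing")
    values = {c: frame[c].to_numpy(dtype=float)
              for c in frame.columns if c != "time"}
    return TimeCourse(times=times, values=values)
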