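"""Automatic derivation of mass-balance ODEs from a reaction scheme.

For every state variable the mass balance is

    d[S]/dt = sum_r (net coefficient of S in r) * rate_r

where the net coefficient sums each edge's own stoichiometric coefficient
(shortcut edges contribute against their *target* species using the
*shortcut's* coefficient). Under mass action the edge coefficient also sets
the kinetic order of the substrate, which is why a coefficient-2 edge shows
up as ``S^2`` inside the rate. Pool species are held constant and never
receive a state index; species determined by assignment rules are computed
outputs, not states, and must have zero net stoichiometry.

The assembled right-hand side is compiled to plain Python once per scheme
(a generated function evaluating every rate, fed through the stoichiometry
matrix), which keeps large schemes fast without any external code
generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Tuple

import numpy as np

from . import expressions as ex
from .errors import DerivationError, SchemeValidationError
from .model import (CUSTOM, MASS_ACTION, MICHAELIS_MENTEN, POOL,
                    ReactionScheme, topological_rule_order, validate)

__all__ = ["DerivedSystem", "derive", "render_equations", "make_evaluator"]


@dataclass
class DerivedSystem:
    """The assembled ODE system for one scheme."""

    scheme: ReactionScheme
    state_index: Dict[str, int]                 # variable species id -> index
    species_order: List[str]                    # all species ids, output order
    pool_values: Dict[str, float]               # pool id -> constant value
    parameters: Dict[str, float]                # globals + namespaced locals
    reaction_ids: List[str]
    rate_expressions: List[ex.Expression]       # one per reaction
    rule_order: List[Tuple[str, ex.Expression]]  # (target id, expr), topo order
    stoichiometry_matrix: np.ndarray            # variables x reactions (net)
    equations_text: Dict[str, str]              # variable id -> RHS text
    display_names: Dict[str, str]
    rhs: Callable = field(repr=False, default=None)    # (t, x, env) -> dx/dt
    rates: Callable = field(repr=False, default=None)  # (t, x, env) -> rates
    jac_sparsity: np.ndarray = field(repr=False, default=None)

    @property
    def n_states(self) -> int:
        return len(self.state_index)

    def initial_state(self) -> np.ndarray:
        spmap = self.scheme.species_by_id()
        x0 = np.zeros(self.n_states)
        for sid, i in self.state_index.items():
            x0[i] = spmap[sid].initial_concentration
        return x0

    def base_env(self) -> Dict[str, float]:
        """Mutable evaluation environment: parameters and pool levels."""
        env = dict(self.parameters)
        env.update(self.pool_values)
        return env


def _rate_ast(scheme, rxn, local_rename):
    """Build the rate expression AST for one reaction."""
    law = rxn.kinetic_law

    def pname(name):
        return local_rename.get(name, name)

    if law.kind == MASS_ACTION:
        node = ex.Sym(pname(law.rate_constant))
        # aggregate kinetic order per substrate species across its edges
        orders: Dict[str, float] = {}
        seen: List[str] = []
        for p in rxn.substrates:
            sp, coeff = scheme.resolve_participant(p)
            if sp.id not in orders:
                seen.append(sp.id)
            orders[sp.id] = orders.get(sp.id, 0.0) + coeff
        for sid in seen:
            c = orders[sid]
            factor = ex.Sym(sid) if c == 1 else \
                ex.BinOp("^", ex.Sym(sid), ex.Num(c))
            node = ex.BinOp("*", node, factor)
        return node
    if law.kind == MICHAELIS_MENTEN:
        sub, _ = scheme.resolve_participant(rxn.substrates[0])
        s = ex.Sym(sub.id)
        return ex.BinOp("/", ex.BinOp("*", ex.Sym(pname("Vmax")), s),
                        ex.BinOp("+", ex.Sym(pname("Km")), s))
    if law.kind == CUSTOM:
        ast = ex.parse(law.expression).ast
        mapping = {old: ex.Sym(new) for old, new in local_rename.items()}
        return ex.substitute(ast, mapping)
    raise DerivationError(f"reaction {rxn.id!r}: unknown law {law.kind!r}")


def derive(scheme: ReactionScheme) -> DerivedSystem:
    """Assemble the mass-balance ODE system from a validated scheme.

    ``derive(scheme)`` and ``derive(flatten(scheme))`` produce the same
    system (layers are invisible to the numerics).
    """
    diags = validate(scheme)
    if diags:
        raise SchemeValidationError(diags)

    ordered = scheme.ordered_species()
    rule_targets = scheme.rule_target_ids()
    display = {sp.id: sp.display_name for sp in ordered}

    state_index: Dict[str, int] = {}
    pool_values: Dict[str, float] = {}
    for sp in ordered:
        if sp.reactant_type == POOL:
            pool_values[sp.id] = sp.initial_concentration
        elif sp.id not in rule_targets:
            state_index[sp.id] = len(state_index)

    parameters = dict(scheme.global_parameters)
    rate_asts: List[ex.Node] = []
    for rxn in scheme.reactions:
        rename = {}
        for name, value in rxn.kinetic_law.parameters.items():
            qualified = f"{rxn.id}__{name}"
            rename[name] = qualified
            parameters[qualified] = value
        rate_asts.append(_rate_ast(scheme, rxn, rename))

    known = set(display) | set(parameters) | {ex.TIME_SYMBOL}
    for rxn, ast in zip(scheme.reactions, rate_asts):
        unknown = ex.free_symbols(ast) - known
        if unknown:
            raise DerivationError(
                f"reaction {rxn.id!r}: rate references unknown symbol(s) "
                f"{sorted(unknown)}")

    # net stoichiometry per (species, reaction), from per-edge coefficients
    n_rxn = len(scheme.reactions)
    net: Dict[str, np.ndarray] = {sp.id: np.zeros(n_rxn) for sp in ordered}
    for j, rxn in enumerate(scheme.reactions):
        for p in rxn.substrates:
            sp, coeff = scheme.resolve_participant(p)
            net[sp.id][j] -= coeff
        for p in rxn.products:
            sp, coeff = scheme.resolve_participant(p)
            net[sp.id][j] += coeff

    for tid in rule_targets:
        if tid in net and np.any(net[tid] != 0):
            raise DerivationError(
                f"rule target {tid!r} is produced/consumed with nonzero net "
                "stoichiometry; a rule-determined species cannot also be a "
                "state")

    matrix = np.zeros((len(state_index), n_rxn))
    for sid, i in state_index.items():
        matrix[i] = net[sid]

    rule_order = [(r.target_id, ex.parse(r.expression))
                  for r in topological_rule_order(scheme)]

    equations_text = {
        sid: _equation_text(net[sid], rate_asts)
        for sid in state_index
    }

    system = DerivedSystem(
        scheme=scheme,
        state_index=state_index,
        species_order=[sp.id for sp in ordered],
        pool_values=pool_values,
        parameters=parameters,
        reaction_ids=[r.id for r in scheme.reactions],
        rate_expressions=[ex.Expression(ex.render(a), a,
                                        frozenset(ex.free_symbols(a)))
                          for a in rate_asts],
        rule_order=rule_order,
        stoichiometry_matrix=matrix,
        equations_text=equations_text,
        display_names=display,
    )
    system.rates = make_evaluator(system, rate_asts)
    N = matrix

    def rhs(t, x, env):
        return N.dot(system.rates(t, x, env))

    system.rhs = rhs
    system.jac_sparsity = _jac_sparsity(system, rate_asts)
    return system


def _maybe_paren(text: str, ast: ex.Node) -> str:
    if isinstance(ast, ex.BinOp) and ast.op in ("+", "-"):
        return f"({text})"
    if isinstance(ast, ex.Unary):
        return f"({text})"
    return text


def _equation_text(net_row: np.ndarray, rate_asts) -> str:
    parts = []
    for j, c in enumerate(net_row):
        if c == 0:
            continue
        rate_text = _maybe_paren(ex.render(rate_asts[j]), rate_asts[j])
        mag = abs(c)
        term = rate_text if mag == 1 else \
            f"{ex.format_number(mag)}*{rate_text}"
        if not parts:
            parts.append(("-" if c < 0 else "") + term)
        else:
            parts.append(("- " if c < 0 else "+ ") + term)
    return " ".join(parts) if parts else "0"


def render_equations(system: DerivedSystem) -> str:
    """Human-readable mass balance equations, one line per state variable.

    Exponentiation is printed with ``^``; terms follow reaction declaration
    order, so the output is deterministic.
    """
    lines = []
    for sid in system.state_index:
        lines.append(f"d[{system.display_names[sid]}]/dt = "
                     f"{system.equations_text[sid]}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Compilation


def make_evaluator(system: DerivedSystem, asts) -> Callable:
    """Compile ASTs into one fast function ``f(t, x, env) -> ndarray``.

    The generated code unpacks the state vector, reads pools and parameters
    from ``env`` (a mutable dict, so events can retarget values between
    segments), computes assignment-rule targets in dependency order, and
    returns the evaluated expressions as a float array.
    """
    name_map: Dict[str, str] = {ex.TIME_SYMBOL: "t"}
    lines = ["def _f(t, x, env):"]
    for sid, i in system.state_index.items():
        name_map[sid] = f"_v{i}"
        lines.append(f"    _v{i} = x[{i}]")
    for k, pid in enumerate(system.pool_values):
        name_map[pid] = f"_p{k}"
        lines.append(f"    _p{k} = env[{pid!r}]")
    for k, pname in enumerate(system.parameters):
        name_map[pname] = f"_k{k}"
        lines.append(f"    _k{k} = env[{pname!r}]")
    for k, (target, expr) in enumerate(system.rule_order):
        name_map[target] = f"_r{k}"
        lines.append(f"    _r{k} = {ex.to_python(expr.ast, name_map)}")
    body = ", ".join(ex.to_python(a, name_map) for a in asts)
    lines.append(f"    return np.array([{body}], dtype=float)")
    namespace = {"np": np, "math": math}
    exec(compile("\n".join(lines), "<schemesim-generated>", "exec"), namespace)
    return namespace["_f"]


def _jac_sparsity(system: DerivedSystem, rate_asts) -> np.ndarray:
    """Conservative Jacobian sparsity pattern for the BDF solver.

    Rate j depends on state i directly or through assignment rules; the
    pattern is |N| . D with D the rate-on-state dependency matrix.
    """
    # expand rule targets to the states they transitively depend on
    rule_deps: Dict[str, set] = {}
    for target, expr in system.rule_order:  # topological order
        deps = set()
        for s in expr.free_symbols:
            if s in system.state_index:
                deps.add(s)
            elif s in rule_deps:
                deps |= rule_deps[s]
        rule_deps[target] = deps

    n_states = system.n_states
    n_rxn = len(rate_asts)
    D = np.zeros((n_rxn, n_states), dtype=bool)
    for j, ast in enumerate(rate_asts):
        for s in ex.free_symbols(ast):
            if s in system.state_index:
                D[j, system.state_index[s]] = True
            elif s in rule_deps:
                for dep in rule_deps[s]:
                    D[j, system.state_index[dep]] = True
    S = (np.abs(system.stoichiometry_matrix) > 0) @ D
    return S.astype(float)
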