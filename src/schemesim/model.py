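"""Domain types for multi-layered reaction schemes and structural validation.

A :class:`ReactionScheme` is the diagram-level model: named layers, species
(state variables or constant pools), shortcut symbols that alias a species
defined elsewhere while carrying their own stoichiometric coefficient,
reaction steps with kinetic laws, assignment rules, and events. Everything
downstream (ODE derivation, simulation, estimation, SBML I/O) consumes this
object graph.

Layers are unordered labels with no hierarchy: they organize large pathways
the way textbooks split metabolism by role, and simulation always merges
them into one flat scheme. A shortcut symbol reads its name, concentration
and reactant type through its target species (edits to the target are
immediately visible through every shortcut), but its stoichiometric
coefficient is local to the reaction edge it sits on — that is what lets the
same coenzyme appear with coefficient 2 in one reaction and 1 in another.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from . import expressions as ex
from .errors import ExpressionError, SchemeValidationError

__all__ = [
    "SpeciesSymbol", "ShortcutSymbol", "Participant", "KineticLaw",
    "ReactionStep", "AssignmentRule", "EventSpec", "ReactionScheme",
    "Diagnostic", "validate", "flatten", "connectors", "sanitize_id",
]

VARIABLE = "variable"
POOL = "pool"

MASS_ACTION = "mass_action"
MICHAELIS_MENTEN = "michaelis_menten"
CUSTOM = "custom"

_RESERVED = {ex.TIME_SYMBOL, "and", "or", "not", *ex.FUNCTIONS}


def sanitize_id(name: str, taken=()) -> str:
    """Derive a machine identifier from a display name.

    Display names may contain anything ("NAD+", "p-cyclin_cdc2-p",
    "1,3-diphosphoglycerate"); identifiers used in expressions and SBML must
    match ``[A-Za-z_][A-Za-z0-9_]*``. Non-alphanumeric characters become
    underscores, a leading digit gets a leading underscore, reserved words
    get a trailing underscore, and collisions with ``taken`` are resolved
    with numeric suffixes.
    """
    base = re.sub(r"[^0-9A-Za-z_]", "_", name)
    if not base:
        base = "_"
    if base[0].isdigit():
        base = "_" + base
    if base in _RESERVED:
        base = base + "_"
    candidate = base
    i = 2
    while candidate in taken:
        candidate = f"{base}_{i}"
        i += 1
    return candidate


# ---------------------------------------------------------------------------
# Symbols and reactions


@dataclass
class SpeciesSymbol:
    """A reactant symbol: one pool or state variable of the scheme."""

    id: str
    display_name: str = ""
    initial_concentration: float = 0.0
    reactant_type: str = VARIABLE          # "variable" | "pool"
    layer: str = "main"
    stoichiometric_coefficient: float = 1.0  # default for direct edges

    def __post_init__(self):
        if not self.display_name:
            self.display_name = self.id


@dataclass
class ShortcutSymbol:
    """An alias of a species (possibly in another layer).

    Name/concentration/reactant type are read through the target and never
    stored here; only the stoichiometric coefficient is local.
    """

    id: str
    target_id: str
    layer: str = "main"
    stoichiometric_coefficient: float = 1.0


@dataclass
class Participant:
    """A reaction edge endpoint: a species or shortcut reference.

    ``coefficient`` overrides the referenced symbol's stoichiometric
    coefficient for this edge; ``None`` means "use the symbol's own".
    """

    ref: str
    coefficient: Optional[float] = None


@dataclass
class KineticLaw:
    """Rate law of one reaction step.

    * ``mass_action``: rate = k * prod(substrate ^ its edge coefficient);
      the rate-constant parameter is named by ``rate_constant`` and resolved
      against the law's local ``parameters`` first, then the scheme's
      global parameters.
    * ``michaelis_menten``: rate = Vmax * S / (Km + S) with S the first
      substrate; ``Vmax``/``Km`` resolved the same way.
    * ``custom``: ``expression`` is used verbatim (stoichiometry then only
      enters the mass balance, not the rate).
    """

    kind: str = MASS_ACTION
    parameters: Dict[str, float] = field(default_factory=dict)
    expression: Optional[str] = None
    rate_constant: str = "k"


@dataclass
class ReactionStep:
    id: str
    layer: str = "main"
    substrates: List[Participant] = field(default_factory=list)
    products: List[Participant] = field(default_factory=list)
    modifiers: List[Participant] = field(default_factory=list)
    kinetic_law: KineticLaw = field(default_factory=KineticLaw)


@dataclass
class AssignmentRule:
    """Algebraic equation continuously defining ``target_id`` (a species)."""

    id: str
    target_id: str
    expression: str
    layer: str = "main"


@dataclass
class EventSpec:
    """Discrete change fired when ``trigger`` flips from false to true."""

    id: str
    trigger: str
    assignments: List[Tuple[str, str]] = field(default_factory=list)
    layer: str = "main"


# ---------------------------------------------------------------------------
# Scheme


@dataclass
class ReactionScheme:
    layers: List[str] = field(default_factory=lambda: ["main"])
    species: List[SpeciesSymbol] = field(default_factory=list)
    shortcuts: List[ShortcutSymbol] = field(default_factory=list)
    reactions: List[ReactionStep] = field(default_factory=list)
    rules: List[AssignmentRule] = field(default_factory=list)
    events: List[EventSpec] = field(default_factory=list)
    global_parameters: Dict[str, float] = field(default_factory=dict)
    name: str = "scheme"

    # -- lookups -----------------------------------------------------------
    def species_by_id(self) -> Dict[str, SpeciesSymbol]:
        return {sp.id: sp for sp in self.species}

    def shortcuts_by_id(self) -> Dict[str, ShortcutSymbol]:
        return {sc.id: sc for sc in self.shortcuts}

    def resolve_shortcut(self, shortcut: ShortcutSymbol) -> SpeciesSymbol:
        """Target species of a shortcut (read-through for name/conc/type)."""
        return self.species_by_id()[shortcut.target_id]

    def resolve_participant(self, p: Participant):
        """Resolve an edge endpoint to ``(species, coefficient)``.

        The edge coefficient is the participant's explicit override if set,
        otherwise the wired symbol's own coefficient (shortcut or species).
        """
        spmap = self.species_by_id()
        if p.ref in spmap:
            sp = spmap[p.ref]
            coeff = p.coefficient if p.coefficient is not None \
                else sp.stoichiometric_coefficient
            return sp, coeff
        sc = self.shortcuts_by_id().get(p.ref)
        if sc is None:
            raise KeyError(f"unresolved participant reference {p.ref!r}")
        sp = spmap[sc.target_id]
        coeff = p.coefficient if p.coefficient is not None \
            else sc.stoichiometric_coefficient
        return sp, coeff

    def rule_target_ids(self) -> set:
        return {r.target_id for r in self.rules}

    def edges(self):
        """Multiset of (reaction id, species id, role, coefficient) edges."""
        out = []
        for rxn in self.reactions:
            for role, plist in (("substrate", rxn.substrates),
                                ("product", rxn.products),
                                ("modifier", rxn.modifiers)):
                for p in plist:
                    sp, coeff = self.resolve_participant(p)
                    out.append((rxn.id, sp.id, role, coeff))
        return out

    def ordered_species(self) -> List[SpeciesSymbol]:
        """Species in declaration order across layers, in layer order."""
        index = {name: i for i, name in enumerate(self.layers)}
        return sorted(self.species,
                      key=lambda sp: index.get(sp.layer, len(index)))

    def layer_species_ids(self, layer: str) -> set:
        """Species (resolved through shortcuts) wired into a layer's
        reactions, rules or events."""
        out = set()
        spids = {sp.id for sp in self.species}
        for rxn in self.reactions:
            if rxn.layer != layer:
                continue
            for plist in (rxn.substrates, rxn.products, rxn.modifiers):
                for p in plist:
                    sp, _ = self.resolve_participant(p)
                    out.add(sp.id)
        for rule in self.rules:
            if rule.layer != layer:
                continue
            out.add(rule.target_id)
            try:
                out |= ex.parse(rule.expression).free_symbols & spids
            except ExpressionError:
                pass
        for ev in self.events:
            if ev.layer != layer:
                continue
            try:
                out |= ex.parse(ev.trigger).free_symbols & spids
            except ExpressionError:
                pass
            for target, value in ev.assignments:
                if target in spids:
                    out.add(target)
                try:
                    out |= ex.parse(value).free_symbols & spids
                except ExpressionError:
                    pass
        return out


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Diagnostic:
    element: str
    rule: str
    message: str

    def __str__(self):
        return f"[{self.element}] {self.rule}: {self.message}"


def _known_symbols(scheme: ReactionScheme) -> set:
    known = {sp.id for sp in scheme.species}
    known |= set(scheme.global_parameters)
    known.add(ex.TIME_SYMBOL)
    return known


def validate(scheme: ReactionScheme) -> List[Diagnostic]:
    """Check every structural invariant; returns diagnostics, never raises."""
    diags: List[Diagnostic] = []
    add = lambda el, rule, msg: diags.append(Diagnostic(el, rule, msg))

    if not scheme.layers:
        add("scheme", "layers", "a scheme needs at least one layer")
    if len(set(scheme.layers)) != len(scheme.layers):
        add("scheme", "duplicate layer", "layer names must be unique")
    layerset = set(scheme.layers)

    # global id uniqueness across every element kind
    seen = {}
    for kind, elems in (("species", scheme.species),
                        ("shortcut", scheme.shortcuts),
                        ("reaction", scheme.reactions),
                        ("rule", scheme.rules),
                        ("event", scheme.events)):
        for el in elems:
            if el.id in seen:
                add(el.id, "duplicate id",
                    f"id also used by {seen[el.id]}")
            else:
                seen[el.id] = kind

    spmap = {sp.id: sp for sp in scheme.species}
    scmap = {sc.id: sc for sc in scheme.shortcuts}

    for sp in scheme.species:
        if sp.layer not in layerset:
            add(sp.id, "unknown layer", f"layer {sp.layer!r} not declared")
        if sp.reactant_type not in (VARIABLE, POOL):
            add(sp.id, "reactant type",
                f"must be 'variable' or 'pool', got {sp.reactant_type!r}")
        if sp.initial_concentration < 0:
            add(sp.id, "negative concentration",
                f"initial concentration {sp.initial_concentration} < 0")
        if not sp.stoichiometric_coefficient > 0:
            add(sp.id, "non-positive coefficient",
                f"stoichiometric coefficient must be > 0, "
                f"got {sp.stoichiometric_coefficient}")
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", sp.id) \
                or sp.id in _RESERVED:
            add(sp.id, "bad id",
                "ids must match [A-Za-z_][A-Za-z0-9_]* and avoid "
                "reserved words (use sanitize_id on the display name)")

    for sc in scheme.shortcuts:
        if sc.layer not in layerset:
            add(sc.id, "unknown layer", f"layer {sc.layer!r} not declared")
        if sc.target_id not in spmap:
            kind = "shortcut chain" if sc.target_id in scmap \
                else "unresolved shortcut target"
            add(sc.id, kind,
                f"target {sc.target_id!r} is not a species symbol")
        if not sc.stoichiometric_coefficient > 0:
            add(sc.id, "non-positive coefficient",
                f"stoichiometric coefficient must be > 0, "
                f"got {sc.stoichiometric_coefficient}")

    rule_targets = scheme.rule_target_ids()
    known = _known_symbols(scheme)

    for rxn in scheme.reactions:
        if rxn.layer not in layerset:
            add(rxn.id, "unknown layer", f"layer {rxn.layer!r} not declared")
        if not rxn.substrates and not rxn.products:
            add(rxn.id, "empty reaction",
                "substrates and products cannot both be empty")
        for p in rxn.substrates + rxn.products + rxn.modifiers:
            if p.ref not in spmap and p.ref not in scmap:
                add(rxn.id, "unresolved participant",
                    f"reference {p.ref!r} matches no species or shortcut")
            elif p.coefficient is not None and not p.coefficient > 0:
                add(rxn.id, "non-positive coefficient",
                    f"edge coefficient for {p.ref!r} must be > 0")
        diags.extend(_check_law(scheme, rxn, known))

    seen_targets = set()
    for rule in scheme.rules:
        if rule.layer not in layerset:
            add(rule.id, "unknown layer", f"layer {rule.layer!r} not declared")
        if rule.target_id not in spmap:
            add(rule.id, "unresolved rule target",
                f"target {rule.target_id!r} is not a species symbol")
        elif spmap[rule.target_id].reactant_type == POOL:
            add(rule.id, "rule targets pool",
                f"{rule.target_id!r} is a constant pool; a rule cannot "
                "also determine it")
        if rule.target_id in seen_targets:
            add(rule.id, "duplicate rule target",
                f"{rule.target_id!r} already determined by another rule")
        seen_targets.add(rule.target_id)
        try:
            expr = ex.parse(rule.expression)
            for name in sorted(expr.free_symbols - known):
                add(rule.id, "unknown symbol",
                    f"expression references undeclared {name!r}")
        except ExpressionError as e:
            add(rule.id, "expression syntax", str(e))

    diags.extend(_check_rule_cycles(scheme))

    for ev in scheme.events:
        if ev.layer not in layerset:
            add(ev.id, "unknown layer", f"layer {ev.layer!r} not declared")
        try:
            trig = ex.parse(ev.trigger)
            if not ex.is_boolean(trig.ast):
                add(ev.id, "trigger not boolean",
                    f"trigger {ev.trigger!r} must be a comparison or "
                    "logical expression")
            for name in sorted(trig.free_symbols - known):
                add(ev.id, "unknown symbol",
                    f"trigger references undeclared {name!r}")
        except ExpressionError as e:
            add(ev.id, "trigger syntax", str(e))
        for target, value in ev.assignments:
            if target not in spmap and target not in scheme.global_parameters:
                add(ev.id, "unknown assignment target",
                    f"{target!r} is neither a species nor a parameter")
            try:
                vexpr = ex.parse(value)
                for name in sorted(vexpr.free_symbols - known):
                    add(ev.id, "unknown symbol",
                        f"assignment references undeclared {name!r}")
            except ExpressionError as e:
                add(ev.id, "assignment syntax", str(e))

    for name in scheme.global_parameters:
        if name in spmap:
            add(name, "parameter shadows species",
                "a global parameter and a species share this id")

    return diags


def _check_law(scheme, rxn, known):
    diags = []
    law = rxn.kinetic_law
    local = {f"{rxn.id}__{p}" for p in law.parameters}
    visible = known | set(law.parameters) | local

    def resolvable(pname):
        return pname in law.parameters or pname in scheme.global_parameters

    if law.kind == MASS_ACTION:
        if not resolvable(law.rate_constant):
            diags.append(Diagnostic(
                rxn.id, "missing rate constant",
                f"parameter {law.rate_constant!r} is neither a local law "
                "parameter nor a global parameter"))
    elif law.kind == MICHAELIS_MENTEN:
        for pname in ("Vmax", "Km"):
            if not resolvable(pname):
                diags.append(Diagnostic(
                    rxn.id, "missing parameter",
                    f"Michaelis-Menten law needs parameter {pname!r}"))
        if not rxn.substrates:
            diags.append(Diagnostic(
                rxn.id, "missing substrate",
                "Michaelis-Menten law needs at least one substrate"))
    elif law.kind == CUSTOM:
        if not law.expression:
            diags.append(Diagnostic(
                rxn.id, "missing expression",
                "custom kinetic law needs an expression"))
        else:
            try:
                expr = ex.parse(law.expression)
                for name in sorted(expr.free_symbols - visible):
                    diags.append(Diagnostic(
                        rxn.id, "unknown symbol",
                        f"rate expression references undeclared {name!r}"))
            except ExpressionError as e:
                diags.append(Diagnostic(rxn.id, "expression syntax", str(e)))
    else:
        diags.append(Diagnostic(
            rxn.id, "unknown kinetic law kind",
            f"got {law.kind!r}, expected mass_action, michaelis_menten "
            "or custom"))
    return diags


def _check_rule_cycles(scheme):
    """Rules must form an acyclic dependency graph (target <- free symbols)."""
    targets = {r.target_id: r for r in scheme.rules}
    deps = {}
    for r in scheme.rules:
        try:
            syms = ex.parse(r.expression).free_symbols
        except ExpressionError:
            syms = frozenset()
        deps[r.target_id] = {s for s in syms if s in targets}
    state = {}  # 0=visiting, 1=done
    diags = []

    def visit(node, stack):
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            cycle = stack[stack.index(node):] + [node]
            diags.append(Diagnostic(
                targets[node].id, "circular rules",
                "rule dependency cycle: " + " -> ".join(cycle)))
            return
        state[node] = 0
        for d in deps.get(node, ()):
            visit(d, stack + [node])
        state[node] = 1

    for t in deps:
        visit(t, [])
    return diags


def topological_rule_order(scheme: ReactionScheme) -> List[AssignmentRule]:
    """Rules ordered so every dependency is computed before its dependents."""
    targets = {r.target_id: r for r in scheme.rules}
    deps = {r.target_id: {s for s in ex.parse(r.expression).free_symbols
                          if s in targets}
            for r in scheme.rules}
    out, done = [], set()
    pending = [r.target_id for r in scheme.rules]
    while pending:
        progressed = False
        for t in list(pending):
            if deps[t] <= done:
                out.append(targets[t])
                done.add(t)
                pending.remove(t)
                progressed = True
        if not progressed:  # cycle: validate() reports it; keep stable order
            out.extend(targets[t] for t in pending)
            break
    return out


# ---------------------------------------------------------------------------
# Flatten & connectors


def flatten(scheme: ReactionScheme) -> ReactionScheme:
    """Merge all layers into one and inline every shortcut.

    Each shortcut participant becomes a direct reference to its target
    species carrying the shortcut's (or the edge's explicit) coefficient;
    the species set is unchanged. Idempotent, and preserves the multiset of
    (reaction, species, role, coefficient) edges.
    """
    diags = validate(scheme)
    if diags:
        raise SchemeValidationError(diags)
    layer = scheme.layers[0] if len(scheme.layers) == 1 else "merged"

    def resolve(plist):
        out = []
        for p in plist:
            sp, coeff = scheme.resolve_participant(p)
            out.append(Participant(ref=sp.id, coefficient=coeff))
        return out

    return ReactionScheme(
        layers=[layer],
        species=[replace(sp, layer=layer) for sp in scheme.ordered_species()],
        shortcuts=[],
        reactions=[replace(rxn, layer=layer,
                           substrates=resolve(rxn.substrates),
                           products=resolve(rxn.products),
                           modifiers=resolve(rxn.modifiers))
                   for rxn in scheme.reactions],
        rules=[replace(r, layer=layer) for r in scheme.rules],
        events=[replace(e, layer=layer) for e in scheme.events],
        global_parameters=dict(scheme.global_parameters),
        name=scheme.name,
    )


def connectors(scheme: ReactionScheme):
    """Species shared between the reactions of each pair of layers.

    Returns ``{(layerA, layerB): set of species ids}`` for every unordered
    layer pair (pairs in declaration order); layers sharing no species map
    to an empty set. A species connects two layers when it is wired —
    directly or through a shortcut — into reactions (or rules/events) of
    both.
    """
    per_layer = {name: scheme.layer_species_ids(name)
                 for name in scheme.layers}
    out = {}
    for i, a in enumerate(scheme.layers):
        for b in scheme.layers[i + 1:]:
            out[(a, b)] = per_layer[a] & per_layer[b]
    return out
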