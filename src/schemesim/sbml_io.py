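"""SBML Level 3 Version 1 Core interchange.

Import maps an SBML document onto a single-layer :class:`ReactionScheme`:
species become reactant symbols (boundary/constant species become pools,
assignment-rule targets become rule-determined outputs), kinetic-law MathML
becomes custom rate expressions, assignmentRules and events map directly,
and compartment sizes are imported as inert named parameters (their sizes
stay folded into the rate expressions exactly as written in the source —
compartments play a different role than layers and are preserved without
interpretation). Constructs outside the supported subset — fast reactions,
csymbol delay, dynamic stoichiometry, multi-piece piecewise, rate/algebraic
rules, event delays and priorities — raise an error naming the feature
rather than being silently skipped.

Export flattens first (SBML cannot represent layers or shortcut symbols):
each shortcut edge becomes a plain speciesReference carrying the shortcut's
stoichiometry, reaction-local parameters are published globally under their
``reactionid__name`` qualified names, display names land in ``name``
attributes and sanitized identifiers in ``id``.

:func:`partition` is the inverse convenience: it re-layers a flat
(typically imported) scheme from an explicit assignment config, wiring
every cross-layer participation through a shortcut, without changing the
simulated dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from lxml import etree

from . import expressions as ex
from .derivation import derive
from .errors import (SBMLImportError, SchemeValidationError,
                     UnsupportedSBMLError)
from .mathml import MATHML_NS, ast_to_mathml, mathml_to_ast
from .model import (AssignmentRule, EventSpec, KineticLaw, Participant,
                    POOL, ReactionScheme, ReactionStep, ShortcutSymbol,
                    SpeciesSymbol, VARIABLE, flatten, validate)

__all__ = ["import_sbml", "export_sbml", "partition", "ImportReport"]

SBML_L3V1_NS = "http://www.sbml.org/sbml/level3/version1/core"


@dataclass
class ImportReport:
    """What an SBML import mapped, plus free-form notes."""

    mapped: List[str] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)


def _ln(el) -> str:
    return etree.QName(el).localname


def _find_all(parent, ns, *path):
    cur = [parent]
    for name in path:
        nxt = []
        for el in cur:
            nxt.extend(el.findall(f"{{{ns}}}{name}"))
        cur = nxt
    return cur


def _math_of(el, ns):
    m = el.find(f"{{{MATHML_NS}}}math")
    return m


# ---------------------------------------------------------------------------
# Import


def import_sbml(source) -> Tuple[ReactionScheme, ImportReport]:
    """Read an SBML document into a single-layer scheme.

    ``source`` is a path, file object, or XML bytes/string. Returns the
    scheme and an :class:`ImportReport`; raises
    :class:`UnsupportedSBMLError` when the document uses constructs outside
    the supported subset (every offending feature is named).
    """
    try:
        if isinstance(source, (bytes, str)) and \
                (isinstance(source, bytes) or source.lstrip().startswith("<")):
            data = source.encode() if isinstance(source, str) else source
            root = etree.fromstring(data)
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as e:
        raise SBMLImportError(f"not well-formed XML: {e}") from e

    if _ln(root) != "sbml":
        raise SBMLImportError(f"root element is <{_ln(root)}>, not <sbml>")
    ns = etree.QName(root).namespace
    model = root.find(f"{{{ns}}}model")
    if model is None:
        raise SBMLImportError("document has no <model>")

    unsupported: List[str] = []
    report = ImportReport()
    layer = model.get("id") or model.get("name") or "model"
    scheme = ReactionScheme(layers=[layer], name=layer)

    # unsupported structural features first
    for rxn_el in _find_all(model, ns, "listOfReactions", "reaction"):
        if rxn_el.get("fast") == "true":
            unsupported.append("fast reaction")
            break
    for tag, feature in (("rateRule", "rate rule"),
                         ("algebraicRule", "algebraic rule")):
        if _find_all(model, ns, "listOfRules", tag):
            unsupported.append(feature)
    if _find_all(model, ns, "listOfInitialAssignments", "initialAssignment"):
        unsupported.append("initial assignment")
    if model.get("conversionFactor"):
        unsupported.append("model conversion factor")

    sref_ids = set()
    for tag in ("listOfReactants", "listOfProducts"):
        for el in model.iter(f"{{{ns}}}speciesReference"):
            if el.get("id"):
                sref_ids.add(el.get("id"))
    math_targets = [r.get("variable")
                    for r in _find_all(model, ns, "listOfRules",
                                       "assignmentRule")]
    math_targets += [a.get("variable")
                     for a in model.iter(f"{{{ns}}}eventAssignment")]
    if sref_ids & set(filter(None, math_targets)):
        unsupported.append("dynamic change in stoichiometry")

    # function definitions (inlined during math translation)
    functions: Dict[str, tuple] = {}
    for fd in _find_all(model, ns, "listOfFunctionDefinitions",
                        "functionDefinition"):
        math = _math_of(fd, ns)
        lam = math.find(f"{{{MATHML_NS}}}lambda") if math is not None else None
        if lam is None:
            raise SBMLImportError(
                f"functionDefinition {fd.get('id')!r} has no lambda")
        argnames = []
        body = None
        for child in lam:
            if not isinstance(child.tag, str):
                continue
            if _ln(child) == "bvar":
                ci = child.find(f"{{{MATHML_NS}}}ci")
                argnames.append(ci.text.strip())
            else:
                body = _translate(child, functions, unsupported)
        functions[fd.get("id")] = (argnames, body)
        report.mapped.append(f"functionDefinition {fd.get('id')} (inlined)")

    for comp in _find_all(model, ns, "listOfCompartments", "compartment"):
        cid = comp.get("id")
        size = comp.get("size") or comp.get("volume") or "1"
        scheme.global_parameters[cid] = float(size)
        report.mapped.append(f"compartment {cid} -> parameter (size {size})")

    rule_targets = {r.get("variable")
                    for r in _find_all(model, ns, "listOfRules",
                                       "assignmentRule")}

    for sp in _find_all(model, ns, "listOfSpecies", "species"):
        sid = sp.get("id")
        boundary = sp.get("boundaryCondition") == "true"
        constant = sp.get("constant") == "true"
        conc = sp.get("initialConcentration")
        if conc is None:
            conc = sp.get("initialAmount")
            if conc is not None and sp.get("hasOnlySubstanceUnits") != "true":
                report.notes.append(
                    f"species {sid}: initialAmount read as concentration")
        value = float(conc) if conc is not None else 0.0
        if sid in rule_targets:
            rtype = VARIABLE  # rule-determined output, not a state
        elif boundary or constant:
            rtype = POOL
        else:
            rtype = VARIABLE
        scheme.species.append(SpeciesSymbol(
            id=sid, display_name=sp.get("name") or sid,
            initial_concentration=value, reactant_type=rtype, layer=layer))
        report.mapped.append(f"species {sid} ({rtype})")

    for par in _find_all(model, ns, "listOfParameters", "parameter"):
        pid = par.get("id")
        scheme.global_parameters[pid] = float(par.get("value") or 0.0)
        report.mapped.append(f"parameter {pid}")

    for rxn_el in _find_all(model, ns, "listOfReactions", "reaction"):
        rid = rxn_el.get("id")

        def participants(list_tag, ref_tag="speciesReference"):
            out = []
            for ref in _find_all(rxn_el, ns, list_tag, ref_tag):
                stoich = ref.get("stoichiometry")
                out.append(Participant(
                    ref=ref.get("species"),
                    coefficient=float(stoich) if stoich is not None else 1.0))
            return out

        law_el = rxn_el.find(f"{{{ns}}}kineticLaw")
        law = KineticLaw(kind="custom", expression="0")
        if law_el is not None:
            locals_: Dict[str, float] = {}
            for lp in _find_all(law_el, ns, "listOfLocalParameters",
                                "localParameter") + \
                    _find_all(law_el, ns, "listOfParameters", "parameter"):
                locals_[lp.get("id")] = float(lp.get("value") or 0.0)
            math = _math_of(law_el, ns)
            if math is None:
                raise SBMLImportError(f"reaction {rid} kineticLaw lacks math")
            ast = _translate(math, functions, unsupported)
            law = KineticLaw(kind="custom", parameters=locals_,
                             expression=ex.render(ast) if ast is not None
                             else "0")
        scheme.reactions.append(ReactionStep(
            id=rid, layer=layer,
            substrates=participants("listOfReactants"),
            products=participants("listOfProducts"),
            modifiers=participants("listOfModifiers",
                                   "modifierSpeciesReference"),
            kinetic_law=law))
        report.mapped.append(f"reaction {rid}")

    for i, rule in enumerate(_find_all(model, ns, "listOfRules",
                                       "assignmentRule")):
        ast = _translate(_math_of(rule, ns), functions, unsupported)
        scheme.rules.append(AssignmentRule(
            id=rule.get("id") or f"rule{i + 1}", layer=layer,
            target_id=rule.get("variable"),
            expression=ex.render(ast) if ast is not None else "0"))
        report.mapped.append(f"assignmentRule -> {rule.get('variable')}")

    for i, ev in enumerate(_find_all(model, ns, "listOfEvents", "event")):
        eid = ev.get("id") or f"event{i + 1}"
        if ev.find(f"{{{ns}}}delay") is not None:
            unsupported.append("event delay")
        if ev.find(f"{{{ns}}}priority") is not None:
            unsupported.append("event priority")
        trig_el = ev.find(f"{{{ns}}}trigger")
        trig_ast = _translate(_math_of(trig_el, ns), functions, unsupported) \
            if trig_el is not None else None
        assignments = []
        for ea in _find_all(ev, ns, "listOfEventAssignments",
                            "eventAssignment"):
            val = _translate(_math_of(ea, ns), functions, unsupported)
            assignments.append((ea.get("variable"),
                                ex.render(val) if val is not None else "0"))
        scheme.events.append(EventSpec(
            id=eid, layer=layer,
            trigger=ex.render(trig_ast) if trig_ast is not None else "1 == 0",
            assignments=assignments))
        report.mapped.append(f"event {eid}")

    if unsupported:
        seen = []
        for f in unsupported:
            if f not in seen:
                seen.append(f)
        raise UnsupportedSBMLError(seen)

    diags = validate(scheme)
    if diags:
        raise SBMLImportError(
            "imported model is not internally consistent: "
            + "; ".join(str(d) for d in diags))
    return scheme, report


def _translate(math, functions, unsupported) -> Optional[ex.Node]:
    if math is None:
        return None
    try:
        return mathml_to_ast(math, functions)
    except UnsupportedSBMLError as e:
        unsupported.extend(e.features)
        return None


# ---------------------------------------------------------------------------
# Export


def export_sbml(scheme: ReactionScheme) -> bytes:
    """Serialize a scheme as an SBML L3V1 Core document (UTF-8 bytes).

    The scheme is flattened first; layer and shortcut information is not
    representable in SBML, so multi-layered models are stored non-layered.
    """
    diags = validate(scheme)
    if diags:
        raise SchemeValidationError(diags)
    flat = flatten(scheme)
    system = derive(flat)  # qualified local-parameter names + rate ASTs

    S = f"{{{SBML_L3V1_NS}}}"
    nsmap = {None: SBML_L3V1_NS}
    root = etree.Element(S + "sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "1")
    model = etree.SubElement(root, S + "model")
    model.set("id", _sbml_id(scheme.name))
    model.set("name", scheme.name)

    comps = etree.SubElement(model, S + "listOfCompartments")
    comp = etree.SubElement(comps, S + "compartment")
    comp.set("id", "default")
    comp.set("size", "1")
    comp.set("constant", "true")

    rule_targets = flat.rule_target_ids()
    species_list = etree.SubElement(model, S + "listOfSpecies")
    for sp in flat.species:
        el = etree.SubElement(species_list, S + "species")
        el.set("id", sp.id)
        el.set("name", sp.display_name)
        el.set("compartment", "default")
        el.set("initialConcentration", repr(sp.initial_concentration))
        is_pool = sp.reactant_type == POOL
        el.set("boundaryCondition",
               "true" if is_pool or sp.id in rule_targets else "false")
        el.set("constant", "false")
        el.set("hasOnlySubstanceUnits", "false")

    event_targets = {t for ev in flat.events for t, _ in ev.assignments}
    if system.parameters:
        params = etree.SubElement(model, S + "listOfParameters")
        for name, value in system.parameters.items():
            el = etree.SubElement(params, S + "parameter")
            el.set("id", name)
            el.set("value", repr(value))
            el.set("constant",
                   "false" if name in event_targets else "true")

    if flat.reactions:
        rxns = etree.SubElement(model, S + "listOfReactions")
        for rxn, rate in zip(flat.reactions, system.rate_expressions):
            el = etree.SubElement(rxns, S + "reaction")
            el.set("id", rxn.id)
            el.set("reversible", "false")
            el.set("fast", "false")
            for tag, plist in (("listOfReactants", rxn.substrates),
                               ("listOfProducts", rxn.products)):
                if not plist:
                    continue
                lst = etree.SubElement(el, S + tag)
                for p in plist:
                    sp, coeff = flat.resolve_participant(p)
                    ref = etree.SubElement(lst, S + "speciesReference")
                    ref.set("species", sp.id)
                    ref.set("stoichiometry", repr(float(coeff)))
                    ref.set("constant", "true")
            if rxn.modifiers:
                lst = etree.SubElement(el, S + "listOfModifiers")
                for p in rxn.modifiers:
                    sp, _ = flat.resolve_participant(p)
                    ref = etree.SubElement(
                        lst, S + "modifierSpeciesReference")
                    ref.set("species", sp.id)
            law_el = etree.SubElement(el, S + "kineticLaw")
            law_el.append(ast_to_mathml(rate.ast))

    if flat.rules:
        rules = etree.SubElement(model, S + "listOfRules")
        for rule in flat.rules:
            el = etree.SubElement(rules, S + "assignmentRule")
            el.set("variable", rule.target_id)
            el.append(ast_to_mathml(ex.parse(rule.expression).ast))

    if flat.events:
        events = etree.SubElement(model, S + "listOfEvents")
        for ev in flat.events:
            el = etree.SubElement(events, S + "event")
            el.set("id", ev.id)
            el.set("useValuesFromTriggerTime", "true")
            trig = etree.SubElement(el, S + "trigger")
            trig.set("initialValue", "true")
            trig.set("persistent", "true")
            trig.append(ast_to_mathml(ex.parse(ev.trigger).ast))
            lst = etree.SubElement(el, S + "listOfEventAssignments")
            for target, value in ev.assignments:
                ea = etree.SubElement(lst, S + "eventAssignment")
                ea.set("variable", target)
                ea.append(ast_to_mathml(ex.parse(value).ast))

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def _sbml_id(name: str) -> str:
    from .model import sanitize_id
    return sanitize_id(name)


# ---------------------------------------------------------------------------
# Partition


def partition(scheme: ReactionScheme, config: dict) -> ReactionScheme:
    """Re-layer a scheme from an explicit assignment config.

    ``config`` keys:

    * ``layers``: ordered list of layer names;
    * ``assign``: map from element id (species, reaction, rule, event) to
      its layer — every element must be assigned;
    * ``shortcuts`` (optional): explicit shortcut creations, each
      ``{"id", "target", "layer", "coefficient"?}``; cross-layer
      participations matching a listed shortcut's (layer, target) are wired
      through it. Remaining cross-layer participations get an
      auto-generated shortcut carrying the original edge coefficient.

    The partitioned scheme simulates identically to the original, and
    flattening it recovers the original flat scheme (up to ordering).
    """
    flat = flatten(scheme)
    layers = list(config.get("layers", []))
    if not layers:
        raise ValueError("partition config needs a non-empty 'layers' list")
    assign: Dict[str, str] = dict(config.get("assign", {}))
    known_ids = {el.id for group in
                 (flat.species, flat.reactions, flat.rules, flat.events)
                 for el in group}
    unknown = set(assign) - known_ids
    if unknown:
        raise KeyError(f"partition config references unknown ids: "
                       f"{sorted(unknown)}")
    missing = known_ids - set(assign)
    if missing:
        raise KeyError(f"partition config must assign every element; "
                       f"missing: {sorted(missing)}")
    bad = {e: l for e, l in assign.items() if l not in layers}
    if bad:
        raise KeyError(f"assignments to undeclared layers: {bad}")

    out = ReactionScheme(layers=layers, name=scheme.name,
                         global_parameters=dict(flat.global_parameters))
    from dataclasses import replace
    for sp in flat.species:
        out.species.append(replace(sp, layer=assign[sp.id]))
    sp_layer = {sp.id: assign[sp.id] for sp in flat.species}

    shortcut_for: Dict[Tuple[str, str], str] = {}
    for d in config.get("shortcuts", []):
        sc = ShortcutSymbol(
            id=d["id"], target_id=d["target"], layer=d["layer"],
            stoichiometric_coefficient=float(d.get("coefficient", 1.0)))
        out.shortcuts.append(sc)
        shortcut_for[(sc.layer, sc.target_id)] = sc.id

    def rewire(plist, rxn_layer):
        new = []
        for p in plist:
            sp, coeff = flat.resolve_participant(p)
            if sp_layer[sp.id] == rxn_layer:
                new.append(Participant(sp.id, coefficient=coeff))
                continue
            key = (rxn_layer, sp.id)
            if key not in shortcut_for:
                sc_id = f"sc_{sp.id}_{len(out.shortcuts) + 1}"
                out.shortcuts.append(ShortcutSymbol(
                    id=sc_id, target_id=sp.id, layer=rxn_layer,
                    stoichiometric_coefficient=coeff))
                shortcut_for[key] = sc_id
            new.append(Participant(shortcut_for[key], coefficient=coeff))
        return new

    for rxn in flat.reactions:
        layer = assign[rxn.id]
        out.reactions.append(replace(
            rxn, layer=layer,
            substrates=rewire(rxn.substrates, layer),
            products=rewire(rxn.products, layer),
            modifiers=rewire(rxn.modifiers, layer)))
    for rule in flat.rules:
        out.rules.append(replace(rule, layer=assign[rule.id]))
    for ev in flat.events:
        out.events.append(replace(ev, layer=assign[ev.id]))

    diags = validate(out)
    if diags:
        raise SchemeValidationError(diags)
    return out
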