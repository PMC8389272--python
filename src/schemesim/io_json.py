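"""Native JSON model format: lossless round trip including layers.

One document with top-level keys ``layers, species, shortcuts, reactions,
rules, events, parameters``. Unlike SBML, the format carries layer
assignments and shortcut symbols, so a multi-layered scheme survives a
save/load cycle unchanged. ``SCHEMA`` documents the structure.
"""

from __future__ import annotations

import json
from typing import Union

from .errors import ModelFormatError
from .model import (AssignmentRule, EventSpec, KineticLaw, Participant,
                    ReactionScheme, ReactionStep, ShortcutSymbol,
                    SpeciesSymbol)

__all__ = ["scheme_to_dict", "scheme_from_dict", "save_scheme",
           "load_scheme", "SCHEMA"]

FORMAT_NAME = "schemesim-model"
FORMAT_VERSION = 1

#: JSON-schema style description of the document (shipped for reference).
SCHEMA = {
    "$comment": f"{FORMAT_NAME} v{FORMAT_VERSION}",
    "type": "object",
    "required": ["layers", "species", "reactions"],
    "properties": {
        "format": {"const": FORMAT_NAME},
        "version": {"const": FORMAT_VERSION},
        "name": {"type": "string"},
        "layers": {"type": "array", "items": {"type": "string"}},
        "species": {"type": "array", "items": {
            "type": "object", "required": ["id"],
            "properties": {
                "id": {"type": "string"},
                "name": {"type": "string"},
                "initial_concentration": {"type": "number", "minimum": 0},
                "reactant_type": {"enum": ["variable", "pool"]},
                "layer": {"type": "string"},
                "stoichiometric_coefficient":
                    {"type": "number", "exclusiveMinimum": 0},
            }}},
        "shortcuts": {"type": "array", "items": {
            "type": "object", "required": ["id", "target"],
            "properties": {
                "id": {"type": "string"},
                "target": {"type": "string"},
                "layer": {"type": "string"},
                "stoichiometric_coefficient":
                    {"type": "number", "exclusiveMinimum": 0},
            }}},
        "reactions": {"type": "array", "items": {
            "type": "object", "required": ["id"],
            "properties": {
                "id": {"type": "string"},
                "layer": {"type": "string"},
                "substrates": {"type": "array"},
                "products": {"type": "array"},
                "modifiers": {"type": "array"},
                "kinetic_law": {"type": "object", "properties": {
                    "kind": {"enum": ["mass_action", "michaelis_menten",
                                      "custom"]},
                    "parameters": {"type": "object"},
                    "rate_constant": {"type": "string"},
                    "expression": {"type": "string"},
                }},
            }}},
        "rules": {"type": "array", "items": {
            "type": "object",
            "required": ["id", "target", "expression"]}},
        "events": {"type": "array", "items": {
            "type": "object", "required": ["id", "trigger", "assignments"]}},
        "parameters": {"type": "object"},
    },
}


def _participant_to_dict(p: Participant) -> dict:
    d = {"ref": p.ref}
    if p.coefficient is not None:
        d["coefficient"] = p.coefficient
    return d


def scheme_to_dict(scheme: ReactionScheme) -> dict:
    return {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "name": scheme.name,
        "layers": list(scheme.layers),
        "species": [
            {"id": sp.id, "name": sp.display_name,
             "initial_concentration": sp.initial_concentration,
             "reactant_type": sp.reactant_type, "layer": sp.layer,
             "stoichiometric_coefficient": sp.stoichiometric_coefficient}
            for sp in scheme.species],
        "shortcuts": [
            {"id": sc.id, "target": sc.target_id, "layer": sc.layer,
             "stoichiometric_coefficient": sc.stoichiometric_coefficient}
            for sc in scheme.shortcuts],
        "reactions": [
            {"id": rxn.id, "layer": rxn.layer,
             "substrates": [_participant_to_dict(p) for p in rxn.substrates],
             "products": [_participant_to_dict(p) for p in rxn.products],
             "modifiers": [_participant_to_dict(p) for p in rxn.modifiers],
             "kinetic_law": _law_to_dict(rxn.kinetic_law)}
            for rxn in scheme.reactions],
        "rules": [
            {"id": r.id, "layer": r.layer, "target": r.target_id,
             "expression": r.expression}
            for r in scheme.rules],
        "events": [
            {"id": e.id, "layer": e.layer, "trigger": e.trigger,
             "assignments": [{"target": t, "expression": v}
                             for t, v in e.assignments]}
            for e in scheme.events],
        "parameters": dict(scheme.global_parameters),
    }


def _law_to_dict(law: KineticLaw) -> dict:
    d = {"kind": law.kind, "parameters": dict(law.parameters)}
    if law.kind == "mass_action":
        d["rate_constant"] = law.rate_constant
    if law.expression is not None:
        d["expression"] = law.expression
    return d


def _require(d: dict, key: str, where: str):
    try:
        return d[key]
    except KeyError:
        raise ModelFormatError(f"missing key {key!r} in {where}") from None
    except TypeError:
        raise ModelFormatError(f"{where} must be an object") from None


def _participant_from_dict(d, where) -> Participant:
    if isinstance(d, str):  # shorthand: bare reference
        return Participant(ref=d)
    return Participant(ref=_require(d, "ref", where),
                       coefficient=d.get("coefficient"))


def scheme_from_dict(doc: dict) -> ReactionScheme:
    if not isinstance(doc, dict):
        raise ModelFormatError("model document must be a JSON object")
    if doc.get("format", FORMAT_NAME) != FORMAT_NAME:
        raise ModelFormatError(
            f"not a {FORMAT_NAME} document (format={doc.get('format')!r})")
    scheme = ReactionScheme(
        layers=list(_require(doc, "layers", "document")),
        name=doc.get("name", "scheme"),
        global_parameters={str(k): float(v)
                           for k, v in doc.get("parameters", {}).items()},
    )
    for d in _require(doc, "species", "document"):
        sid = _require(d, "id", "species entry")
        scheme.species.append(SpeciesSymbol(
            id=sid,
            display_name=d.get("name", sid),
            initial_concentration=float(d.get("initial_concentration", 0.0)),
            reactant_type=d.get("reactant_type", "variable"),
            layer=d.get("layer", scheme.layers[0]),
            stoichiometric_coefficient=float(
                d.get("stoichiometric_coefficient", 1.0)),
        ))
    for d in doc.get("shortcuts", []):
        scheme.shortcuts.append(ShortcutSymbol(
            id=_require(d, "id", "shortcut entry"),
            target_id=_require(d, "target", "shortcut entry"),
            layer=d.get("layer", scheme.layers[0]),
            stoichiometric_coefficient=float(
                d.get("stoichiometric_coefficient", 1.0)),
        ))
    for d in _require(doc, "reactions", "document"):
        rid = _require(d, "id", "reaction entry")
        law = d.get("kinetic_law", {})
        scheme.reactions.append(ReactionStep(
            id=rid,
            layer=d.get("layer", scheme.layers[0]),
            substrates=[_participant_from_dict(p, f"reaction {rid}")
                        for p in d.get("substrates", [])],
            products=[_participant_from_dict(p, f"reaction {rid}")
                      for p in d.get("products", [])],
            modifiers=[_participant_from_dict(p, f"reaction {rid}")
                       for p in d.get("modifiers", [])],
            kinetic_law=KineticLaw(
                kind=law.get("kind", "mass_action"),
                parameters={str(k): float(v)
                            for k, v in law.get("parameters", {}).items()},
                expression=law.get("expression"),
                rate_constant=law.get("rate_constant", "k"),
            ),
        ))
    for d in doc.get("rules", []):
        scheme.rules.append(AssignmentRule(
            id=_require(d, "id", "rule entry"),
            layer=d.get("layer", scheme.layers[0]),
            target_id=_require(d, "target", "rule entry"),
            expression=_require(d, "expression", "rule entry"),
        ))
    for d in doc.get("events", []):
        eid = _require(d, "id", "event entry")
        scheme.events.append(EventSpec(
            id=eid,
            layer=d.get("layer", scheme.layers[0]),
            trigger=_require(d, "trigger", "event entry"),
            assignments=[(_require(a, "target", f"event {eid} assignment"),
                          _require(a, "expression",
                                   f"event {eid} assignment"))
                         for a in d.get("assignments", [])],
        ))
    return scheme


def save_scheme(scheme: ReactionScheme, destination) -> None:
    doc = scheme_to_dict(scheme)
    if hasattr(destination, "write"):
        json.dump(doc, destination, indent=1)
    else:
        with open(destination, "w") as fh:
            json.dump(doc, fh, indent=1)


def load_scheme(source: Union[str, dict]) -> ReactionScheme:
    if isinstance(source, dict):
        return scheme_from_dict(source)
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as e:
                raise ModelFormatError(f"invalid JSON: {e}") from e
    return scheme_from_dict(doc)
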