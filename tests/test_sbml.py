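"""SBML L3V1 import/export, unsupported-feature detection, partitioning."""

import numpy as np
import pytest
from lxml import etree

import schemesim as ss
from schemesim import fixtures as fx
from schemesim.errors import UnsupportedSBMLError
from schemesim.sbml_io import SBML_L3V1_NS, partition

NS = {"s": SBML_L3V1_NS,
      "m": "http://www.w3.org/1998/Math/MathML"}

MINIMAL = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      level="3" version="1">
 <model id="mini">
  <listOfCompartments>
   <compartment id="cell" size="1" constant="true"/>
  </listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="cell" initialConcentration="2"
            boundaryCondition="false" constant="false"
            hasOnlySubstanceUnits="false"/>
   <species id="B" compartment="cell" initialConcentration="0"
            boundaryCondition="false" constant="false"
            hasOnlySubstanceUnits="false"/>
  </listOfSpecies>
  <listOfParameters>
   <parameter id="k1" value="0.4" constant="true"/>
  </listOfParameters>
  <listOfReactions>
   <reaction id="r1" reversible="false" fast="false">
    <listOfReactants>
     <speciesReference species="A" stoichiometry="1" constant="true"/>
    </listOfReactants>
    <listOfProducts>
     <speciesReference species="B" stoichiometry="1" constant="true"/>
    </listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>k1</ci><ci>A</ci></apply>
     </math>
    </kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


def test_import_minimal_model():
    scheme, report = ss.import_sbml(MINIMAL)
    assert len(scheme.species) == 2
    assert len(scheme.reactions) == 1
    assert scheme.reactions[0].kinetic_law.expression == "k1*A"
    assert scheme.layers == ["mini"]
    assert scheme.global_parameters["k1"] == 0.4
    assert any("reaction r1" in m for m in report.mapped)
    tc = ss.simulate(scheme, ss.SimulationSettings(tf=5, output_grid=11))
    expected = 2.0 * (1 - np.exp(-0.4 * tc.times))
    assert np.max(np.abs(tc.values["B"] - expected)) < 1e-5


def _with_math(math_xml):
    return MINIMAL.replace(
        "<apply><times/><ci>k1</ci><ci>A</ci></apply>", math_xml)


def test_csymbol_delay_is_rejected_by_name():
    doc = _with_math(
        '<apply><csymbol encoding="text" definitionURL='
        '"http://www.sbml.org/sbml/symbols/delay"> delay </csymbol>'
        "<ci>A</ci><cn>1</cn></apply>")
    with pytest.raises(UnsupportedSBMLError, match="csymbol delay"):
        ss.import_sbml(doc)


def test_multiple_piecewise_is_rejected():
    doc = _with_math(
        "<piecewise>"
        "<piece><cn>1</cn><apply><lt/><ci>A</ci><cn>1</cn></apply></piece>"
        "<piece><cn>2</cn><apply><lt/><ci>A</ci><cn>2</cn></apply></piece>"
        "<otherwise><cn>3</cn></otherwise></piecewise>")
    with pytest.raises(UnsupportedSBMLError, match="multiple piecewise"):
        ss.import_sbml(doc)


def test_single_piecewise_is_supported():
    doc = _with_math(
        "<piecewise>"
        "<piece><cn>1</cn><apply><lt/><ci>A</ci><cn>1</cn></apply></piece>"
        "<otherwise><cn>3</cn></otherwise></piecewise>")
    scheme, _ = ss.import_sbml(doc)
    assert scheme.reactions[0].kinetic_law.expression == \
        "piecewise(1, A < 1, 3)"


def test_fast_reaction_is_rejected():
    doc = MINIMAL.replace('fast="false"', 'fast="true"')
    with pytest.raises(UnsupportedSBMLError, match="fast reaction"):
        ss.import_sbml(doc)


def test_rate_rule_is_rejected():
    doc = MINIMAL.replace(
        "<listOfReactions>",
        '<listOfRules><rateRule variable="B">'
        '<math xmlns="http://www.w3.org/1998/Math/MathML"><cn>1</cn></math>'
        "</rateRule></listOfRules><listOfReactions>")
    with pytest.raises(UnsupportedSBMLError, match="rate rule"):
        ss.import_sbml(doc)


def test_event_delay_is_rejected():
    doc = MINIMAL.replace(
        "</model>",
        '<listOfEvents><event id="e1" useValuesFromTriggerTime="true">'
        '<trigger initialValue="true" persistent="true">'
        '<math xmlns="http://www.w3.org/1998/Math/MathML">'
        "<apply><geq/><csymbol definitionURL="
        '"http://www.sbml.org/sbml/symbols/time">t</csymbol><cn>1</cn>'
        "</apply></math></trigger>"
        "<delay><math xmlns=\"http://www.w3.org/1998/Math/MathML\">"
        "<cn>1</cn></math></delay>"
        '<listOfEventAssignments><eventAssignment variable="k1">'
        '<math xmlns="http://www.w3.org/1998/Math/MathML"><cn>0</cn></math>'
        "</eventAssignment></listOfEventAssignments>"
        "</event></listOfEvents></model>")
    with pytest.raises(UnsupportedSBMLError, match="event delay"):
        ss.import_sbml(doc)


def test_function_definitions_are_inlined():
    doc = MINIMAL.replace(
        "<listOfCompartments>",
        "<listOfFunctionDefinitions>"
        '<functionDefinition id="f">'
        '<math xmlns="http://www.w3.org/1998/Math/MathML"><lambda>'
        "<bvar><ci>x</ci></bvar><bvar><ci>y</ci></bvar>"
        "<apply><times/><ci>x</ci><ci>y</ci></apply>"
        "</lambda></math></functionDefinition>"
        "</listOfFunctionDefinitions><listOfCompartments>")
    doc = _with_math_doc(doc,
                         "<apply><ci>f</ci><ci>k1</ci><ci>A</ci></apply>")
    scheme, _ = ss.import_sbml(doc)
    assert scheme.reactions[0].kinetic_law.expression == "k1*A"


def _with_math_doc(doc, math_xml):
    return doc.replace(
        "<apply><times/><ci>k1</ci><ci>A</ci></apply>", math_xml)


# ---------------------------------------------------------------------------
# Export


def test_export_atp_toy_stoichiometry(atp_toy):
    xml = ss.export_sbml(atp_toy)
    root = etree.fromstring(xml)
    refs = root.xpath(
        "//s:reaction[@id='step3']/s:listOfReactants/"
        "s:speciesReference[@species='ATP']", namespaces=NS)
    assert len(refs) == 1
    assert float(refs[0].get("stoichiometry")) == 2.0
    refs1 = root.xpath(
        "//s:reaction[@id='step1']/s:listOfReactants/"
        "s:speciesReference[@species='ATP']", namespaces=NS)
    assert float(refs1[0].get("stoichiometry")) == 1.0


def test_export_preserves_display_names(butanol):
    root = etree.fromstring(ss.export_sbml(butanol))
    sp = root.xpath("//s:species[@id='NAD_']", namespaces=NS)
    assert sp and sp[0].get("name") == "NAD+"


def test_export_single_species_scheme():
    scheme = ss.ReactionScheme(layers=["main"])
    scheme.species.append(ss.SpeciesSymbol(id="A", initial_concentration=1.0))
    root = etree.fromstring(ss.export_sbml(scheme))
    assert root.get("level") == "3" and root.get("version") == "1"
    assert len(root.xpath("//s:species", namespaces=NS)) == 1
    assert not root.xpath("//s:reaction", namespaces=NS)
    back, _ = ss.import_sbml(ss.export_sbml(scheme))
    assert len(back.species) == 1


def test_round_trip_simulates_identically(all_fixture_schemes):
    for name, scheme in all_fixture_schemes.items():
        back, _ = ss.import_sbml(ss.export_sbml(scheme))
        settings = ss.SimulationSettings(tf=5.0, output_grid=11)
        a = ss.simulate(scheme, settings)
        b = ss.simulate(back, settings)
        for k in a.values:
            assert np.max(np.abs(a.values[k] - b.values[k])) < 1e-6, \
                (name, k)


def test_round_trip_preserves_counts(all_fixture_schemes):
    for name, scheme in all_fixture_schemes.items():
        back, _ = ss.import_sbml(ss.export_sbml(scheme))
        assert len(back.species) == len(scheme.species), name
        assert len(back.reactions) == len(scheme.reactions), name
        assert len(back.rules) == len(scheme.rules), name
        assert len(back.events) == len(scheme.events), name
        # and an import->export->import cycle is stable too
        again, _ = ss.import_sbml(ss.export_sbml(back))
        assert len(again.species) == len(back.species), name


# ---------------------------------------------------------------------------
# Partition


def _identity_config(scheme, layer):
    flat = ss.flatten(scheme)
    assign = {el.id: layer for group in (flat.species, flat.reactions,
                                         flat.rules, flat.events)
              for el in group}
    return flat, {"layers": [layer], "assign": assign}


def test_partition_identity_is_structurally_unchanged(atp_toy):
    flat, config = _identity_config(atp_toy, "pathway")
    out = partition(atp_toy, config)
    assert out.layers == ["pathway"]
    assert sorted(sp.id for sp in out.species) == \
        sorted(sp.id for sp in flat.species)
    assert out.shortcuts == []


def test_partition_then_flatten_recovers_original(butanol):
    flat = ss.flatten(butanol)
    assign = {}
    for sp in flat.species:
        assign[sp.id] = "left" if sp.id.startswith(("gl", "_1", "py")) \
            else "right"
    for rxn in flat.reactions:
        assign[rxn.id] = "left" if rxn.id.startswith("e") else "right"
    out = partition(butanol, {"layers": ["left", "right"], "assign": assign})
    back = ss.flatten(out)
    from collections import Counter
    assert Counter((r, sp, role, c) for r, sp, role, c in back.edges()) == \
        Counter((r, sp, role, c) for r, sp, role, c in flat.edges())


def test_partition_simulates_identically(rule_event_toy):
    """Moving the total rule to its own layer must not change dynamics."""
    flat = ss.flatten(rule_event_toy)
    assign = {el.id: "base" for group in (flat.species, flat.reactions,
                                          flat.rules, flat.events)
              for el in group}
    assign["rule_total"] = "Total"
    assign["total"] = "Total"
    out = partition(rule_event_toy,
                    {"layers": ["base", "Total"], "assign": assign})
    settings = ss.SimulationSettings(tf=20, output_grid=41)
    a = ss.simulate(rule_event_toy, settings)
    b = ss.simulate(out, settings)
    for k in a.values:
        assert np.max(np.abs(a.values[k] - b.values[k])) < 1e-6, k
    # the rule layer is connected to the base layer through its variables
    conn = ss.connectors(out)
    assert conn[("base", "Total")] >= {"c1", "c2", "c3", "c4"}


def test_partition_rejects_unknown_and_missing_ids(atp_toy):
    flat, config = _identity_config(atp_toy, "pathway")
    bad = dict(config["assign"])
    bad["ghost"] = "pathway"
    with pytest.raises(KeyError, match="unknown ids"):
        partition(atp_toy, {"layers": ["pathway"], "assign": bad})
    incomplete = dict(config["assign"])
    incomplete.pop("ATP")
    with pytest.raises(KeyError, match="missing"):
        partition(atp_toy, {"layers": ["pathway"], "assign": incomplete})
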