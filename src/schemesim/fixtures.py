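"""Programmatic model generators used throughout the test suite and docs.

Every generator returns a fully valid :class:`ReactionScheme`:

* :func:`make_linear_chain` — the n-species first-order chain
  X1 -> X2 -> ... -> Xn used for scaling studies (X1 a constant pool);
* :func:`make_atp_toy` — a three-step pathway where ATP/ADP participate
  with coefficient 1 at step 1 (direct symbols) and coefficient 2 at step 3
  (shortcut symbols), the canonical demonstration that one species can
  carry different stoichiometric coefficients on different edges;
* :func:`make_butanol` — a two-layer synthetic-butanol pathway (an
  E. coli glycolytic layer feeding a C. acetobutylicum reduction layer)
  coupled through acetoacetyl-CoA, NAD+ and NADH shortcuts, with 4 NADH
  produced on one side and 4 consumed on the other;
* :func:`make_three_layer_toy` — a small three-layer scheme whose layer
  connectors are exactly {B}, {S} and {K, M, N};
* :func:`make_rule_event_toy` — a decaying species, an assignment rule
  computing a four-species total, and an event zeroing a rate constant at
  t = 10;
* :func:`make_random_scheme` — seeded random mass-action schemes for
  oracle-based testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (KineticLaw, Participant, ReactionScheme, ReactionStep,
                    AssignmentRule, EventSpec, ShortcutSymbol, SpeciesSymbol,
                    POOL, VARIABLE, sanitize_id)

__all__ = ["ChainSpec", "make_linear_chain", "make_atp_toy", "make_butanol",
           "make_three_layer_toy", "make_rule_event_toy",
           "make_random_scheme", "FIXTURES", "make_fixture"]


@dataclass
class ChainSpec:
    """Linear chain X1 -> X2 -> ... -> Xn.

    X1 is a constant pool at ``x1_constant`` (default 100); the other
    species start at 0; every step is mass action with rate constant ``k``
    (default 0.1, named k1..kn as global parameters). With
    ``terminal_outflow`` (the default) Xn drains through an extra sink
    reaction, so every species approaches the pool level at steady state.
    """

    n: int = 10
    k: float = 0.1
    x1_constant: float = 100.0
    terminal_outflow: bool = True

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("chain needs at least 2 species")
        if not self.k > 0:
            raise ValueError("rate constant must be positive")


def make_linear_chain(spec: ChainSpec = None, **kwargs) -> ReactionScheme:
    if spec is None:
        spec = ChainSpec(**kwargs)
    scheme = ReactionScheme(layers=["chain"], name=f"linear_chain_n{spec.n}")
    scheme.species.append(SpeciesSymbol(
        id="X1", initial_concentration=spec.x1_constant,
        reactant_type=POOL, layer="chain"))
    for i in range(2, spec.n + 1):
        scheme.species.append(SpeciesSymbol(
            id=f"X{i}", initial_concentration=0.0, layer="chain"))
    n_rxn = spec.n if spec.terminal_outflow else spec.n - 1
    for j in range(1, n_rxn + 1):
        scheme.global_parameters[f"k{j}"] = spec.k
        products = [Participant(f"X{j + 1}")] if j < spec.n else []
        scheme.reactions.append(ReactionStep(
            id=f"r{j}", layer="chain",
            substrates=[Participant(f"X{j}")],
            products=products,
            kinetic_law=KineticLaw(kind="mass_action",
                                   rate_constant=f"k{j}"),
        ))
    return scheme


def make_atp_toy() -> ReactionScheme:
    """Three-step pathway with ATP/ADP at coefficients 1 (step 1, direct
    reactant symbols) and 2 (step 3, shortcut symbols)."""
    scheme = ReactionScheme(layers=["pathway"], name="atp_toy")
    specs = [("S1", 5.0), ("S2", 0.0), ("S3", 0.0), ("S4", 0.0),
             ("ATP", 3.0), ("ADP", 1.0)]
    for sid, conc in specs:
        scheme.species.append(SpeciesSymbol(
            id=sid, initial_concentration=conc, layer="pathway"))
    scheme.shortcuts.append(ShortcutSymbol(
        id="ATP_step3", target_id="ATP", layer="pathway",
        stoichiometric_coefficient=2.0))
    scheme.shortcuts.append(ShortcutSymbol(
        id="ADP_step3", target_id="ADP", layer="pathway",
        stoichiometric_coefficient=2.0))
    scheme.global_parameters.update({"k1": 1.0, "k2": 1.0, "k3": 1.0})
    scheme.reactions.append(ReactionStep(
        id="step1", layer="pathway",
        substrates=[Participant("S1"), Participant("ATP")],
        products=[Participant("S2"), Participant("ADP")],
        kinetic_law=KineticLaw(kind="mass_action", rate_constant="k1")))
    scheme.reactions.append(ReactionStep(
        id="step2", layer="pathway",
        substrates=[Participant("S2")],
        products=[Participant("S3")],
        kinetic_law=KineticLaw(kind="mass_action", rate_constant="k2")))
    scheme.reactions.append(ReactionStep(
        id="step3", layer="pathway",
        substrates=[Participant("S3"), Participant("ATP_step3")],
        products=[Participant("S4"), Participant("ADP_step3")],
        kinetic_law=KineticLaw(kind="mass_action", rate_constant="k3")))
    return scheme


_ECOLI = "E. coli"
_CLOSTRIDIUM = "C. acetobutylicum"


def make_butanol() -> ReactionScheme:
    """Two-organism butanol pathway connected through shared cofactors.

    The E. coli layer oxidizes glucose to acetoacetyl-CoA, producing 4 NADH
    (2 at the glyceraldehyde-3-phosphate oxidation step, 2 at pyruvate
    oxidation) and consuming 4 NAD+. The C. acetobutylicum layer reduces
    acetoacetyl-CoA to butanol through four NADH-consuming steps (1 NADH
    each, the first being the acetoacetyl-CoA -> 3-hydroxybutyryl-CoA
    step), regenerating 4 NAD+. Kinetics are unit-rate mass action
    placeholders; the structurally asserted content is the topology, the
    connector set and the coefficient balance.
    """
    scheme = ReactionScheme(layers=[_ECOLI, _CLOSTRIDIUM], name="butanol")
    taken = set()

    def species(name, conc, layer):
        sid = sanitize_id(name, taken)
        taken.add(sid)
        scheme.species.append(SpeciesSymbol(
            id=sid, display_name=name, initial_concentration=conc,
            layer=layer))
        return sid

    glucose = species("glucose", 10.0, _ECOLI)
    g3p = species("glyceraldehyde-3-phosphate", 0.0, _ECOLI)
    dpg = species("1,3-diphosphoglycerate", 0.0, _ECOLI)
    pyruvate = species("pyruvate", 0.0, _ECOLI)
    accoa = species("acetyl-CoA", 0.0, _ECOLI)
    acac = species("acetoacetyl-CoA", 0.0, _ECOLI)
    nad = species("NAD+", 2.0, _ECOLI)
    nadh = species("NADH", 0.5, _ECOLI)
    hbcoa = species("3-hydroxybutyryl-CoA", 0.0, _CLOSTRIDIUM)
    crotonyl = species("crotonyl-CoA", 0.0, _CLOSTRIDIUM)
    butyryl = species("butyryl-CoA", 0.0, _CLOSTRIDIUM)
    butyraldehyde = species("butyraldehyde", 0.0, _CLOSTRIDIUM)
    butanol = species("butanol", 0.0, _CLOSTRIDIUM)

    def shortcut(sid, target, coeff):
        scheme.shortcuts.append(ShortcutSymbol(
            id=sid, target_id=target, layer=_CLOSTRIDIUM,
            stoichiometric_coefficient=coeff))
        return sid

    sc_acac = shortcut("sc_acetoacetyl_CoA", acac, 1.0)
    sc = {}
    for step in ("c1", "c3", "c4", "c5"):
        sc[("nadh", step)] = shortcut(f"sc_NADH_{step}", nadh, 1.0)
        sc[("nad", step)] = shortcut(f"sc_NAD_{step}", nad, 1.0)

    def reaction(rid, layer, subs, prods):
        k = f"k_{rid}"
        scheme.global_parameters[k] = 1.0
        scheme.reactions.append(ReactionStep(
            id=rid, layer=layer,
            substrates=[Participant(r, c) for r, c in subs],
            products=[Participant(r, c) for r, c in prods],
            kinetic_law=KineticLaw(kind="mass_action", rate_constant=k)))

    # E. coli layer: glycolysis to acetoacetyl-CoA (per-glucose accounting)
    reaction("e1", _ECOLI, [(glucose, 1)], [(g3p, 2)])
    reaction("e2", _ECOLI, [(g3p, 2), (nad, 2)], [(dpg, 2), (nadh, 2)])
    reaction("e3", _ECOLI, [(dpg, 2)], [(pyruvate, 2)])
    reaction("e4", _ECOLI, [(pyruvate, 2), (nad, 2)], [(accoa, 2), (nadh, 2)])
    reaction("e5", _ECOLI, [(accoa, 2)], [(acac, 1)])

    # C. acetobutylicum layer: acetoacetyl-CoA to butanol, via shortcuts
    reaction("c1", _CLOSTRIDIUM,
             [(sc_acac, None), (sc[("nadh", "c1")], None)],
             [(hbcoa, 1), (sc[("nad", "c1")], None)])
    reaction("c2", _CLOSTRIDIUM, [(hbcoa, 1)], [(crotonyl, 1)])
    reaction("c3", _CLOSTRIDIUM,
             [(crotonyl, 1), (sc[("nadh", "c3")], None)],
             [(butyryl, 1), (sc[("nad", "c3")], None)])
    reaction("c4", _CLOSTRIDIUM,
             [(butyryl, 1), (sc[("nadh", "c4")], None)],
             [(butyraldehyde, 1), (sc[("nad", "c4")], None)])
    reaction("c5", _CLOSTRIDIUM,
             [(butyraldehyde, 1), (sc[("nadh", "c5")], None)],
             [(butanol, 1), (sc[("nad", "c5")], None)])
    return scheme


def make_three_layer_toy() -> ReactionScheme:
    """Three layers whose connectors are (1,2)->{B}, (1,3)->{S},
    (2,3)->{K, M, N}."""
    L1, L2, L3 = "layer1", "layer2", "layer3"
    scheme = ReactionScheme(layers=[L1, L2, L3], name="three_layer_toy")
    for sid, conc, layer in [("A", 10.0, L1), ("B", 0.0, L1),
                             ("C", 0.0, L2), ("K", 0.0, L2),
                             ("M", 0.0, L2), ("N", 0.0, L2),
                             ("S", 5.0, L3)]:
        scheme.species.append(SpeciesSymbol(
            id=sid, initial_concentration=conc, layer=layer))
    scheme.shortcuts.append(ShortcutSymbol(id="sc_S_l1", target_id="S",
                                           layer=L1))
    scheme.shortcuts.append(ShortcutSymbol(id="sc_B_l2", target_id="B",
                                           layer=L2))
    scheme.shortcuts.append(ShortcutSymbol(id="sc_K_l3", target_id="K",
                                           layer=L3))
    scheme.shortcuts.append(ShortcutSymbol(id="sc_M_l3", target_id="M",
                                           layer=L3))
    scheme.shortcuts.append(ShortcutSymbol(id="sc_N_l3", target_id="N",
                                           layer=L3))
    steps = [("l1r1", L1, ["A"], ["B"]),
             ("l1r2", L1, ["sc_S_l1"], ["A"]),
             ("l2r1", L2, ["sc_B_l2"], ["C"]),
             ("l2r2", L2, ["C"], ["K"]),
             ("l2r3", L2, ["K"], ["M"]),
             ("l2r4", L2, ["M"], ["N"]),
             ("l3r1", L3, ["sc_N_l3"], ["S"]),
             ("l3r2", L3, ["sc_K_l3", "sc_M_l3"], ["S"])]
    for i, (rid, layer, subs, prods) in enumerate(steps, start=1):
        scheme.global_parameters[f"k{i}"] = 1.0
        scheme.reactions.append(ReactionStep(
            id=rid, layer=layer,
            substrates=[Participant(r) for r in subs],
            products=[Participant(r) for r in prods],
            kinetic_law=KineticLaw(kind="mass_action",
                                   rate_constant=f"k{i}")))
    return scheme


def make_rule_event_toy() -> ReactionScheme:
    """Decaying species + four-species total rule + one rate-reset event.

    Species A decays at rate k_dec until the event at t = 10 sets
    k_dec := 0, so A(t) = A(0) * exp(-k_dec * min(t, 10)) in closed form.
    The rule-determined species ``total`` continuously equals
    c1 + c2 + c3 + c4 (a conserved chain, so the total also stays at its
    initial sum).
    """
    scheme = ReactionScheme(layers=["toy"], name="rule_event_toy")
    scheme.species.append(SpeciesSymbol(id="A", initial_concentration=1.0,
                                        layer="toy"))
    for sid, conc in [("c1", 4.0), ("c2", 3.0), ("c3", 2.0), ("c4", 1.0)]:
        scheme.species.append(SpeciesSymbol(
            id=sid, initial_concentration=conc, layer="toy"))
    scheme.species.append(SpeciesSymbol(id="total", layer="toy"))
    scheme.global_parameters.update(
        {"k_dec": 0.2, "kc1": 0.3, "kc2": 0.3, "kc3": 0.3})
    scheme.reactions.append(ReactionStep(
        id="decay", layer="toy", substrates=[Participant("A")], products=[],
        kinetic_law=KineticLaw(kind="mass_action", rate_constant="k_dec")))
    for j in range(1, 4):
        scheme.reactions.append(ReactionStep(
            id=f"chain{j}", layer="toy",
            substrates=[Participant(f"c{j}")],
            products=[Participant(f"c{j + 1}")],
            kinetic_law=KineticLaw(kind="mass_action",
                                   rate_constant=f"kc{j}")))
    scheme.rules.append(AssignmentRule(
        id="rule_total", layer="toy", target_id="total",
        expression="c1+c2+c3+c4"))
    scheme.events.append(EventSpec(
        id="stop_decay", layer="toy", trigger="t >= 10",
        assignments=[("k_dec", "0")]))
    return scheme


def make_random_scheme(n_species: int = 6, n_reactions: int = 6,
                       seed: int = 0, with_pools: bool = False,
                       two_layers: bool = False) -> ReactionScheme:
    """Seeded random mass-action scheme (integer coefficients 1-3).

    With ``two_layers`` the species are split over two layers and every
    cross-layer participation is wired through a shortcut carrying the
    edge's coefficient, so the result exercises the flatten/derive paths.
    Always validates cleanly; identical for identical arguments.
    """
    rng = np.random.default_rng(seed)
    layers = ["north", "south"] if two_layers else ["main"]
    scheme = ReactionScheme(layers=layers,
                            name=f"random_{n_species}x{n_reactions}_{seed}")
    for i in range(n_species):
        layer = layers[int(rng.integers(len(layers)))]
        rtype = POOL if (with_pools and i > 0 and rng.random() < 0.2) \
            else VARIABLE
        scheme.species.append(SpeciesSymbol(
            id=f"S{i}", initial_concentration=float(rng.uniform(0.5, 5.0)),
            reactant_type=rtype, layer=layer))
    spmap = {sp.id: sp for sp in scheme.species}
    sc_count = 0
    for j in range(n_reactions):
        ids = list(spmap)
        rng.shuffle(ids)
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        subs = ids[:n_sub]
        prods = ids[n_sub:n_sub + n_prod]
        layer = spmap[subs[0]].layer

        def edge(sid):
            nonlocal sc_count
            coeff = float(rng.integers(1, 4))
            if spmap[sid].layer != layer:
                sc_count += 1
                sc_id = f"sc{sc_count}_{sid}"
                scheme.shortcuts.append(ShortcutSymbol(
                    id=sc_id, target_id=sid, layer=layer,
                    stoichiometric_coefficient=coeff))
                return Participant(sc_id)
            return Participant(sid, coefficient=coeff)

        k = f"k{j + 1}"
        scheme.global_parameters[k] = float(rng.uniform(0.05, 0.5))
        scheme.reactions.append(ReactionStep(
            id=f"r{j + 1}", layer=layer,
            substrates=[edge(s) for s in subs],
            products=[edge(s) for s in prods],
            kinetic_law=KineticLaw(kind="mass_action", rate_constant=k)))
    return scheme


FIXTURES = {
    "linear-chain": make_linear_chain,
    "atp-toy": make_atp_toy,
    "butanol": make_butanol,
    "three-layer": make_three_layer_toy,
    "rule-event": make_rule_event_toy,
    "random": make_random_scheme,
}


def make_fixture(name: str, **kwargs) -> ReactionScheme:
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}"
        ) from None
    return factory(**kwargs)
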