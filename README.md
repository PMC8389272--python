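# schemesim

Multi-layered biochemical reaction schemes as code: build the diagram-level
model (species, reactions, kinetic laws, assignment rules, events), let the
package derive the mass-balance ODE system automatically, integrate it with
a stiff BDF (Gear-family) solver, fit kinetic parameters to time-course
data, and exchange models with SBML Level 3.

## Who this is for

Metabolic pathways are usually drawn the way textbooks draw them: split
into layers by role (glycolysis here, a fermentation pathway there), with
ubiquitous species — ATP, ADP, NAD+, NADH — repeated wherever they are
used, each occurrence carrying its own stoichiometric coefficient.
`schemesim` models exactly that structure:

* a **layer** is a named, non-hierarchical partition of the scheme;
* a **shortcut symbol** is an alias of a species defined elsewhere
  (possibly in another layer): it reads the species' name, concentration
  and type through the target, but carries its **own stoichiometric
  coefficient** for the reaction edge it sits on;
* species shared between layers (directly or via shortcuts) are the
  **connectors** that couple the layers into one system.

Simulation always flattens the layers away, so the layered layout is pure
organization: `simulate(scheme)` and `simulate(flatten(scheme))` are the
same system.

## The mathematics

For every state variable S the mass balance is assembled automatically:

    d[S]/dt = Σ_r ν_{S,r} · v_r(x, p, t)

where ν_{S,r} is the net stoichiometric coefficient of S in reaction r,
summed over the edges S (or a shortcut to S) is wired to — each edge
contributing its own coefficient — and v_r is the reaction's rate law.
Under mass action, v_r = k · Π_s [s]^{c_s} with the kinetic order c_s equal
to the substrate edge coefficient, so a coefficient-2 edge appears as
`[S]^2` in the rate. Species marked as *pools* are boundary conditions
(held constant); species set by *assignment rules* are computed outputs,
not states; *events* apply discrete assignments when a boolean trigger
flips from false to true (localized by root-finding on a continuous
trigger margin).

Parameter estimation minimizes the (optionally weighted) sum of squared
errors between simulated and observed trajectories, with a bounded modified
Powell search (restarted when its direction set degenerates), a real-coded
genetic algorithm (BLX-0.5 crossover, Gaussian mutation, tournament
selection, elitism), or their hybrid (GA global phase + Powell polish).

## Worked example

```python
import schemesim as ss
from schemesim import fixtures

scheme = fixtures.make_atp_toy()      # 3-step pathway; ATP/ADP with
                                      # coefficient 1 at step 1 (direct
                                      # symbols), 2 at step 3 (shortcuts)
print(ss.render_equations(ss.derive(scheme)))
```

prints the automatically derived mass balances:

```
d[S1]/dt = -k1*S1*ATP
d[S2]/dt = k1*S1*ATP - k2*S2
d[S3]/dt = k2*S2 - k3*S3*ATP^2
d[S4]/dt = k3*S3*ATP^2
d[ATP]/dt = -k1*S1*ATP - 2*k3*S3*ATP^2
d[ADP]/dt = k1*S1*ATP + 2*k3*S3*ATP^2
```

Note the shortcut coefficient 2 appearing both as the `-2*` balance factor
and as the kinetic order `ATP^2` in the third step — while the first step
uses coefficient 1. Simulating and fitting:

```python
settings = ss.SimulationSettings(tf=20, output_grid=41)
tc = ss.simulate(fixtures.make_linear_chain(n=3), settings)
print(round(tc.values["X2"][-1], 3))   # 86.466 — matches 100(1 - e^{-0.1 t})
```

The same works from the shell:

```sh
schemesim fixture linear-chain --n 10 --out chain.json
schemesim simulate chain.json --tf 1000 --max-step 0.1 --out traj.csv
schemesim derive chain.json
schemesim convert chain.json chain.xml     # SBML L3V1 export
schemesim connectors butanol.json
schemesim estimate chain.json traj.csv --params k1:0.01:1,k2:0.01:1 \
    --method hybrid --seed 42 --out fit.json
```

## Layout

| Module | Contents |
| --- | --- |
| `schemesim.model` | domain types, validation, `flatten`, `connectors` |
| `schemesim.expressions` | kinetic/trigger expression language |
| `schemesim.derivation` | mass-balance assembly, equation rendering |
| `schemesim.simulation` | BDF integration, rules, events, CSV I/O |
| `schemesim.estimation` | SSE objective, Powell / RCGA / hybrid |
| `schemesim.sbml_io` | SBML L3V1 import/export, `partition` |
| `schemesim.io_json` | native JSON model format (keeps layers) |
| `schemesim.fixtures` | programmatic example models |
| `schemesim.cli` | `schemesim` command-line tool |

See `docs/methods.md` for modeling assumptions, numerical choices and
limitations.
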