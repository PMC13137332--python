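# crossrange

Individual-based simulation of a cross-feeding bacterial consortium
expanding on a toxic substrate, with the spatial pattern metrics needed to
ask when the expansion becomes a *succession*.

## The problem

Two engineered strains degrade a toxic carbon source in series: a
**detoxifier** converts the substrate S (salicylate) into an intermediate I
(catechol), and a **consumer** converts I into a shared growth product P
(pyruvate/acetyl-CoA) that feeds both. Cooperation would normally favour
spatial intermixing during colony range expansion — but the substrate is
also toxic, and the detoxifier lowers the local substrate concentration
around itself. At high substrate concentrations this self-detoxification
lets the detoxifier colonise the expansion frontier first, with the
consumer following behind: a successive, "detoxifier-first" range expansion
that *opposes* intermixing. This package implements the agent-based model
of that system for anyone who wants to reproduce, probe or extend the
mechanism: colonies of soft-disc cells coupled to reaction–diffusion
lattices of S, I and P.

Per unit biomass, conversion follows Michaelis–Menten kinetics
(ν_S = k₁E₁·S/(K₁+S), ν_I = k₂E₂·I/(K₂+I)) and growth is Monod in the
product with a Hill-type toxicity factor and a maintenance rate:

    g = kg · P/(Kg+P) · 1/(1 + (θS)³) − d

The model sweeps substrate concentration S₀ (C-mM), toxicity coefficient θ
(1/C-mM) and solute diffusivity D, and quantifies each colony with radial
abundance profiles, frontier composition, an intermixing index, and a
succession classifier. See `docs/methods.md` for the full model
description, parameter defaults and limitations.

## A worked example

```python
import crossrange as cr
import crossrange.metrics as m

# high-toxicity scenario: theta = 0.5, 10 C-mM substrate, 1:1 inoculum
cfg = cr.ScenarioConfig(S0=10.0, theta=0.5, seed=1)
traj = cr.run(cfg)

final = traj.final
print("terminated:", traj.termination_reason, "at t =", round(final.time, 1), "h")
print("population:", len(final.cells))
print("frontier detoxifier fraction:", round(m.frontier_fraction(final), 3))
print("intermixing index:", round(m.intermixing_index(final), 3))
print("pattern:", cr.classify_succession(traj).value)
```

prints

```
terminated: max_population at t = 141.2 h
population: 8106
frontier detoxifier fraction: 0.829
intermixing index: 0.178
pattern: detoxifier_first
```

The colony grew from a 100-cell mixed inoculum to 8106 cells; by the end
the expansion frontier is 83 % detoxifier (against 50 % at inoculation) and
the run classifies as a detoxifier-first succession. Re-running with
`theta=0.0` leaves the frontier near parity and the pattern
`simultaneous` — toxicity, not the cross-feeding itself, drives the
succession. Scenario sweeps, the well-mixed ODE oracle and CSV/PNG exports
are available from the command line:

```bash
crossrange init-config --out scenario.yaml
crossrange run --config scenario.yaml --out results/
crossrange sweep --theta 0 --theta 0.3 --s0 5 --s0 15 --out sweep/
crossrange oracle --config scenario.yaml
```

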