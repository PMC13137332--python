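# Model and methods

## The system

`crossrange` simulates the range expansion of a two-member cross-feeding
bacterial consortium on a plate whose sole carbon source is a toxic
substrate (the motivating system: *Pseudomonas stutzeri* degrading
salicylate). The **detoxifier** converts the substrate S into an
intermediate I (salicylate → catechol); the **consumer** converts I into a
diffusible product P (pyruvate / acetyl-CoA) that feeds the growth of both
strains. The substrate inhibits the growth of both strains, so the
detoxifier — by depleting S around itself — engineers the landscape in
which the competition for the frontier plays out. The question the model
answers is how initial substrate concentration S₀, the toxicity coefficient
θ and the solute diffusivity D select between a *simultaneous* (intermixed,
sectored) expansion and a *successive*, "detoxifier-first" expansion in
which the detoxifier colonises the frontier and the consumer follows.

## Kinetics

Each cell carries a biomass m and experiences the solute concentrations
interpolated at its position. Per unit biomass:

* substrate conversion (detoxifier): ν_S = k₁E₁ · S/(K₁+S)
* intermediate conversion (consumer): ν_I = k₂E₂ · I/(K₂+I)
* growth: g = kg · P/(Kg+P) · 1/(1+(θS)³) − d

Enzyme levels are constant (induction is maintained), so k·E is a single
catalytic capacity per strain. The Hill inhibition factor 1/(1+(θS)ⁿ) uses
n = 3; θ = 0 recovers plain Monod growth minus maintenance. Conversion does
not require growth: enzymes keep working in non-growing and jammed cells,
which is what lets a stalled colony detoxify its surroundings before
expanding.

## Space and the reaction–diffusion coupling

S, I and P live on a shared node-centred square lattice (default 144×144,
spacing h = 1) with explicit FTCS diffusion, no-flux boundaries and
automatic sub-stepping to respect the stability bound D·dt/h² ≤ 1/4. The
plate starts with uniform S = S₀ and no I or P, and is never replenished.

Cells sense concentrations by bilinear interpolation and withdraw mass from
their nearest lattice node; every node scales its claimants down
proportionally so no concentration ever goes negative, and the *realized*
(possibly capped) product uptake is fed back into the growth rate, so
biomass is never created from carbon that was not withdrawn. Two coupling
details matter for robustness:

* all withdrawals are settled against the start-of-step lattices and the
  step's conversion products are deposited afterwards — a producer cannot
  eat its own same-step output, which would otherwise couple the allocation
  of scarce product to the step size;
* deposits are spread over the 3×3 node neighbourhood (a secretion plume a
  few cell lengths wide, still much narrower than a species sector), so a
  producing cell does not hold a privileged claim on its own output during
  the well-mixed early phase, while sector-scale source/sink geometry is
  preserved.

## Cells and mechanics

Cells are soft discs (radius ∝ √biomass, base radius 0.35 lattice units at
the birth mass, so a few cells share a solute voxel). Biomass integrates
exponentially (m ← m·e^{g·dt}, exact for constant g); a cell divides at
exactly twice the birth mass into two equal daughters displaced along a
random axis with ±5 % jitter, and dies (and is removed) when decay brings
it below a quarter of the birth mass. Overlapping discs are relaxed by
iterative pairwise half-overlap displacements (momentum-free), which is
what physically pushes the colony outward. Cells whose residual overlap
after relaxation exceeds 12 % of their radius are *jammed* and pause
growth (contact inhibition) until the crowding resolves; this confines
active growth to a peripheral layer, as in packed real colonies, and
replaces the mechanical jamming that rod-shaped-cell engines provide
implicitly. Rod geometry itself (nematic order, anisotropic pushing) is
deliberately not modelled.

## Scenarios

A scenario is a uniform-substrate plate inoculated at the centre with a
well-mixed disc (default 100 cells, radius 7, detoxifier fraction 0.5,
initial biomasses uniform in [1, 2)× birth mass) and run with one global
time step (dt = 0.1 h) until the colony reaches 8100 cells, a time cap
(400 h), or extinction. One root seed spawns independent sub-streams for
placement and division axes, so runs are bit-reproducible. Sweeps over
(θ, S₀, D, inoculum ratio, seed) expand to tagged configs; everything
round-trips through YAML.

## Default parameters and how they were chosen

The strains' true kinetic constants are not available here, so the defaults
are model choices, made once to place the consortium in the regime the
biology implies, and all overridable per config:

| parameter | detoxifier | consumer | units | role |
|---|---|---|---|---|
| catalytic capacity k·E | 10.5 | 0.9 | C-mM/h per biomass | conversion speed |
| half-saturation K | 90 | 2 | C-mM | conversion affinity |
| max growth kg | 0.3 | 0.3 | 1/h | growth ceiling |
| growth half-sat Kg | 0.1 | 0.1 | C-mM | product affinity |
| maintenance d | 0.005 | 0.005 | 1/h | decay |
| yield | 1.0 | 1.0 | biomass per C-mM·voxel | carbon cost of growth |
| θ (swept) | shared | shared | 1/C-mM | toxicity |
| D (swept) | 1.0 | — | lattice²/h | all three solutes |

The reasoning: (i) the detoxifier's K is far above the experimental S₀
range, so substrate supply scales almost linearly with S₀ (15 C-mM supplies
~2.7× more carbon flux than 5 C-mM); (ii) the consumer's conversion stage
is the capacity bottleneck — at high S₀ the incoming intermediate exceeds
what consumers can process and convert-to-product, so surplus product
escapes to the detoxifier (product-saturated, near-parity growth), while at
low S₀ the consumer processes everything and its proximity to the product
source gives it the growth edge (product-limited, consumer-favoured);
(iii) conversion is fast enough that an inoculum under 15 C-mM of toxic
substrate clears its surroundings within tens of hours, before maintenance
decay kills it. Maintenance is kept ≪ kg, as bacterial maintenance rates
are small compared with maximal growth rates.

## Pattern metrics

All abundances are count-based (matching pixel-fraction quantification of
two-colour images). The **radial profile** bins alive cells into annuli of
width 2 from the inoculum edge r₀ outward (cells inside r₀ are the original
inoculum footprint and are excluded; empty bins are flagged, never
interpolated). The **frontier band** is every cell within w = 4 cell
diameters (2.8 lattice units) of the maximum centroid distance; its
detoxifier share is the frontier fraction. The **intermixing index** orders
band cells by polar angle and counts cyclic species transitions divided by
band size (0 = demixed or single-species, 1 = perfect alternation; the
experimental formula is not public, but this boundary-counting index is
monotone in visual intermixing, which is what the directional comparison
needs). The **succession classifier** labels a run detoxifier-first when
the final frontier fraction exceeds the lowest well-populated bin of the
final radial profile by more than 0.15 (the profile rises toward the
frontier — the spatial signature of succession, absent when a strain
dominates at every radius) *and* the frontier fraction stayed above 0.65
for at least 20 % of the expansion-phase snapshots (the pre-expansion
detoxification lag is excluded from the window); consumer-first is the
mirror rule. The growth-rate ratio
divides the mean instantaneous detoxifier rate by the consumer's and
reports the signed pair instead when the consumer mean is non-positive.

## Verification

* FTCS diffusion conserves each solute's mass to < 10⁻¹⁰ relative over
  thousands of steps; uniform fields are fixed points; pulses stay
  symmetric.
* A per-step carbon ledger (substrate converted = intermediate produced;
  product consumed = biomass created × yield at zero maintenance) closes to
  first-order integration tolerance over full runs.
* A spatially homogeneous ODE twin of the kinetics (the well-mixed oracle,
  integrated with an adaptive Runge–Kutta scheme) matches the agent-based
  totals within 5 % when the agents run at high diffusivity on a small
  plate with contact inhibition disabled — an independent implementation of
  the same kinetics through a different code path.
* Identical (config, seed) reruns are bit-identical; halving dt changes
  seed-averaged frontier fractions by < 0.05 on reduced-scale colonies.

## Problem sizes

Full-scale simulations terminate at 8100 cells on the 144×144 plate
(final colony radius ≈ 30–37, i.e. a 4–5× radial expansion from the
inoculum); headline comparisons average 3 replicate seeds. Reduced
colonies (1200–1500 cells, 96×96) are used where a check needs many runs
(dt-halving uses 6 seeds per scenario and step size, the carbon ledger one
longer run).

## Known limitations

* **What the generator emulates.** Synthetic scenarios reproduce the
  *structure* of the experiments — two isogenic strains, a 1:1 (or swept)
  well-mixed circular inoculum, uniform substrate — not their measured
  kinetics; OD-based inoculum ratios are mapped 1:1 to cell-count ratios.
  Passing tests therefore demonstrate the mechanism (toxicity-driven
  succession) in a self-consistent model, not quantitative agreement with
  any particular strain pair.
* **Consumer frontier bias at no toxicity.** The expanding frontier is a
  pulled front that self-organises to marginal, product-scarce growth, and
  under scarcity the consumer's adjacency to the product source gives it a
  persistent edge. At θ = 0 and high S₀ the model therefore undershoots
  parity at the frontier (seed-mean detoxifier fraction ≈ 0.3 rather than
  ≈ 0.5), and the radial profile of the maintenance counterfactual inherits
  the same drift. Calibration could not remove this bias without
  sacrificing the high-toxicity frontier dominance; it is the model's main
  known divergence from the motivating observations.
* **Detoxifier excess at low toxic substrate.** At θ = 0.3 with S₀ = 5
  C-mM the model's frontier comes out mildly detoxifier-enriched (~0.5–0.7
  across seeds) where the motivating observations show a consumer
  majority: the local substrate contrast that detoxification creates
  already outweighs the consumer's product-proximity advantage at this
  concentration. Slowing the detoxifier's conversion restores the consumer
  majority here but then colonies cannot establish at all under the
  harshest toxicity-substrate combination (θ = 0.5, S₀ = 15), which was
  judged the worse failure.
* **Diffusivity range.** The detoxifier-first pattern is robust for
  D ∈ {0.5, 1, 2} but dissolves at D = 5 (in this model's lattice units):
  fast diffusion both smears the local substrate contrast the mechanism
  needs and prolongs the detoxification lag. The robustness claim holds
  over a ~4× range here, not the full 10× range reported for the original
  rod-cell implementation.
* Dead cells are removed outright (no inert debris); the plate wall is a
  hard clamp; agar depth, motility, adhesion and enzyme-expression dynamics
  are not modelled.
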