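# Methods

## The model

`psfsim` simulates a plant community on a square lattice (default 100 × 100)
with at most one plant per cell. Species interact *only* through plant–soil
feedback: every plant conditions the soil of its cell with its own species
identity, and that conditioning sets the growth rate of the **next** occupant
of the cell (the previous-occupant effect). All species are otherwise
identical, so every difference between scenarios is attributable to the
interaction network alone.

Each time step applies four processes in order:

1. **Immigration** — each empty cell is colonised with probability
   `p_immigration` (default 0.001) by a uniformly random species from the
   resident pool of `n_resident_species` (default 100). The invader never
   immigrates.
2. **Recruitment** — every cell still empty is filled by an offspring of the
   standing community; the recruit's species is drawn with probability
   proportional to total current species biomass (larger plants are more
   fecund; dispersal is global). No recruitment happens on the first step,
   so the first immigrants can establish, and none while total biomass is
   zero.
3. **Growth** — each plant's biomass is multiplied by its growth rate,
   subject to the neighbourhood cap (below).
4. **Mortality** — each plant, including same-step recruits, dies with
   probability `p_mortality` (default 0.1); the dead plant's species remains
   as soil conditioning.

A plant's growth rate is fixed once, at establishment, by the interaction
table entry for (its species, the cell's soil state): `slow` = 1.49,
`standard` = 1.65 or `fast` = 1.82 per time step; never-occupied soil gives
`standard`. Rates are not re-evaluated afterwards — otherwise every plant
would immediately experience its own conspecific conditioning, erasing the
conspecific-feedback contrast the design manipulates.

## Interaction networks

Heterospecific interactions are arranged in one of three architectures, each
in a positive (`fast`) or negative (`slow`) variant and at group size
5, 10 or 20, plus a null control:

* **modular** — species interact bidirectionally within contiguous blocks of
  `g` species; each species is affected by `g − 1` others.
* **nested** — the first `g` species (the focal set) one-directionally
  affect every other species, focal members included; non-focal species are
  affected by `g` soils, focal ones by `g − 1`.
* **ring** — species `j` affects species `j+1 … j+g` around a circle;
  in-degree = out-degree = `g` for everyone, and no species is a global
  winner (intransitivity).

With the conspecific toggle (`NC`), every resident additionally grows `slow`
on soil conditioned by its own species. This yields
(3 architectures × 3 sizes × 2 signs + null) = 19 heterospecific scenarios,
38 with the conspecific toggle, and 76 simulation scenarios once crossed
with the invasion arm. Module membership, the focal set and the ring order
follow species index canonically; species labels are exchangeable, so any
other labelling is an equivalent relabelling.

A single invader (species index `n_resident`) facilitates itself (`fast` on
its own soil) and has no heterospecific interactions in either direction.
In invasion runs, 100 invader individuals are placed into randomly chosen
empty cells at the start of step 10,001 of a 12,000-step run, before that
step's immigration; invasibility is the invader's percentage of total
community biomass at the final step.

## The neighbourhood cap

The only size regulation is local: the combined biomass of a focal plant and
its four von Neumann neighbours (five individuals) may not exceed
`neighbourhood_cap` (default 100 biomass units; plants establish at
`initial_biomass` = 1). A combined-biomass ceiling on a neighbourhood can
be enforced in more than one way, and the choice changes how strongly
growth-rate differences are expressed, so the engine exposes three
explicit mechanics (`SimConfig.cap_mode`):

* **`rescale` (default)** — after multiplicative growth, every over-cap
  five-cell neighbourhood is shrunk back to the cap; each plant takes the
  most restrictive `cap / neighbourhood-sum` factor among the five
  neighbourhoods it belongs to. Plants can lose biomass to faster-growing
  neighbours, so the cap acts as zero-sum local competition and per-step
  rate ratios compound into lifetime biomass ratios (≈ `(r_i/r_j)^age`).
  It is the only mechanic that maintains the cap as a true post-step
  invariant, and the only one of the three under which the expected
  invasion regime emerges (heavy, reliable invasion of negative-nested
  communities with negative conspecific feedback; no invasion of
  positive-modular communities).
* **`share`** — plants never shrink; growth increments `b·(r−1)` contest
  the remaining room in each neighbourhood and are scaled proportionally
  where demand exceeds it. Rate advantages are damped to `(r−1)` ratios
  gated by local slack. The cap invariant also holds exactly.
* **`clip`** — growth is truncated at `cap −` (pre-step neighbour sum) and
  never shrinks a plant. Under this mechanic realised biomass is set mainly
  by vacancy timing, growth-rate differences barely compound, and
  simultaneous growth of co-neighbours into the same slack can overshoot
  the cap (it is bounded per focal plant, not per neighbourhood). Kept for
  comparison.

All three updates are synchronous (computed from the pre-step field), hence
independent of cell order and reproducible.

The absolute cap value sets the biomass scale, but the ratio
`neighbourhood_cap / (5 · initial_biomass)` is a real dynamical parameter:
it fixes the biomass share at which the 100 invader individuals enter the
community and hence how exposed the invader is to stochastic loss right
after introduction. With the defaults that share is ≈ 0.05%, which makes
final invader percentages in weakly-invaded scenarios strongly bimodal
across replicates (extinction or escape); replicate means for those
scenarios are therefore noisy and their confidence intervals wide. The
scaled-down acceptance suite reports sensitivity of the headline
comparisons to the cap at 50/100/200.

## Metrics

Over resident species only (all pre-invasion time points precede the
invasion):

* **Inverse Simpson diversity** `1/D = 1/Σ p_i²` at step 10,000, with
  biomass shares by default (count shares also computed and stored).
* **Bray–Curtis compositional change** `Σ|x−y| / Σ(x+y)` between the
  resident biomass vectors at steps 5,000 and 10,000.
* **Community average growth rate** — the expected establishment rate of a
  random propagule under global dispersal, `Σ_ij p_i p_j · rate(i, j)` with
  count frequencies `p` at step 10,000 and the scenario's interaction
  table. This is the natural frequency-only estimator of the establishment
  rate a random propagule experiences under global dispersal; it is
  bounded in [1.49, 1.82] and behaves as expected — negative conspecific
  feedback lowers it, and less so in more diverse communities.
* **Invasibility** — invader % of total biomass at the final step.

Scenario-level summaries report means with normal-approximation 95%
confidence intervals (mean ± 1.96·SE over replicates).

## Experiment orchestration and seeds

`ExperimentPlan` crosses scenarios × invasion arms × replicates; the full
design is 38 × 2 × 100 = 7,600 runs. Replicate `r` (0-based) of any
scenario/arm batch uses `base_seed + r`, so batches are reproducible and
replicate streams are paired across scenarios. One `numpy` Generator per
replicate drives every stochastic draw. `run_plan` persists one JSON row
per completed run and skips existing rows, so interrupted batches resume.

## Problem sizes used in the shipped suites

The full factorial at 100 replicates is a batch job, not a test. The
package's own verification suites use the full-size grid and full 12,000
step horizon but reduced replication: 12 replicates for the headline
invasibility comparisons, 4 for the cap-sensitivity arms at caps 50 and
200, with CI-aware assertions (a directional claim passes when the stated
direction holds and, where required, the intervals exclude the reverse
ordering). Conspecific-feedback direction checks use the null,
negative-nested and negative-modular scenario pairs, whose effects are
resolvable at this replication; in positive architectures the
conspecific growth-rate effect is of order 5·10⁻⁴ per step against
replicate noise an order of magnitude larger, so its direction is not
testable at desk scale. The acceptance script uses 15 replicates per
scenario.

## Known limitations

* The growth/cap mechanics are a declared interpretation (see above); the
  `cap_mode` switch makes the choice explicit rather than buried.
* Hard (non-toroidal) grid edges by default; border plants have fewer
  neighbours. A toroidal option exists; edge effects are small at 100×100.
* The generator emulates the idealised study system (identical species,
  global dispersal, previous-occupant feedback only). It does not emulate
  real communities: no trait variation, no local dispersal or spatial
  clustering, no invader–resident heterospecific interactions, no
  current-neighbour effects. Passing tests therefore validate the
  simulator's internal contracts and the network-architecture effects
  within this idealised model, not predictions about field communities.
* Weakly-invaded scenarios have bimodal invasion outcomes under the default
  mechanics (see the cap section); their replicate means should be read
  together with their dispersion.
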