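# Methods

## Model and assumptions

The dynamics are a generalized consumer-resource system with metabolic
leakage. Species grow on the energy they harvest from explicitly modeled
resources; a fraction `l` of every unit harvested is leaked back into the
environment as by-products, routed between resources by a row-stochastic
metabolic matrix `D` (energy conservation forces each row to sum to 1).
The model deliberately keeps four simplifications: all resources carry
equal energy density, the functional response is linear (no saturation),
uptake rates are binary (a species either consumes a resource at unit rate
or not at all), and every resource is externally supplied at the same rate.
Species may leak by-products they also consume.

The maintenance cost

```
z = χ0 (1 + ε) (1 − l) Σ_j c_j
```

scales with the number of encoded uptake pathways, so that neither
generalists nor specialists are favored a priori, and with `1 − l`, which
makes the zero-growth resource level `Σ_j c_j R*_j = χ0 (1 + ε) Σ_j c_j`
independent of leakage: consumers deplete resources to the same
concentration regardless of how leaky they are, so communities with
different leakage can be mixed without a built-in efficiency bias. A
leakage-independent variant (`leakage_dependent_cost=False`) is available
for comparison. The cost fluctuation ε is drawn from N(0, σ) with σ = 0.1
interpreted as a standard deviation; draws ≤ −1 (which would make the cost
negative) are rejected and resampled — at σ = 0.1 this is a ~10⁻²³ event.
The biomass-per-energy factor `g` is fixed at 1; it rescales time per
species and does not affect equilibria or any reported metric.

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| κ | supply rate of each resource | 2 | mol s⁻¹ |
| τ | resource dilution timescale | 0.25 | s |
| χ0 | mean cost per metabolic pathway | 0.1 | energy |
| σ (ε) | sd of the cost fluctuation | 0.1 | — |
| s, m | species / resource counts | 60, 60 | — |
| l | leakage fraction | grid {0.1, 0.5, 0.9} | — |
| k_c, k_f | competition / facilitation structure factors | grid {0, 0.5, 0.9} | — |
| K_c, K_f | inter-guild factors | (0.1, 0.9) | — |
| N(0) | inoculation abundance | 1 | biomass |
| R(0) | initial resource concentration | κ·τ = 0.5 | mol |

Initial resource concentrations are not prescribed anywhere authoritative;
the consumer-free supply equilibrium κ·τ is used as the natural reference
state (and is what coalescence resets resources to). Initial abundances
default to 1 for every species. Both are configurable.

## Structured sampling (the synthetic-data generator)

The generator is the pipeline's data source; its defaults are the study
conditions for every experiment.

**Preference counts.** Each species draws its number of preferences `m_r`
from a geometric distribution (discrete analogue of an exponential) with
minimum 1, truncated at `m` by rejection. The untruncated mean defaults to
5 — a value chosen so that the realized count spectrum has substantial
support up to `m_r ≈ 30` at `m = 60` while specialists remain the modal
group. The mean is a free parameter of the generator.

**Preference matrix.** Preferences are assigned sequentially with weight
`(1 − k_c)/m + k_c (d_j + 1)/Σ_k (d_k + 1)`, where `d_j` counts prior
assignments of resource `j` across the whole draw. At `k_c = 0` this is
exactly uniform; as `k_c → 1` it is preferential attachment, concentrating
demand on emergent hub resources and hence raising pairwise niche overlap.

**Metabolic matrix.** Each row of `D` mixes a uniform kernel with the
community demand profile: `D[j, k] ∝ (1 − k_f)/m + k_f · d_k/Σ d`, then is
normalized to sum to exactly 1. At `k_f = 0` all entries are `1/m`; at
`k_f = 1` secretion is fully determined by demand, directing by-products
toward the community's own bottleneck resources. The demand vector is the
column-sum of the same community's preference matrix (self-consistent
structure). These two kernels are this package's concrete realization of
"uniform at 0, demand-determined at 1"; each is isolated behind a single
function so alternative kernels (e.g. Dirichlet rows with the same mean)
can be swapped in.

**Guilds.** Optionally, resources are partitioned into equal contiguous
classes with matching consumer guilds. Each preference pick falls outside
the species' own class with probability `K_c`; each metabolic row routes a
`K_f` share of its mass outside the class of the consumed resource. The
`k_c`/`k_f` kernels operate within the chosen side. The mechanism is
defined on `K ∈ [0, 1]` so that the fully modular (`K = 0`, block-diagonal
C and D) and fully mixed limits are reachable; production configs restrict
to the standard `(0.1, 0.9)` range.

In the standard (parent-assembly) mode all species of a community share one
`D` and one leakage value; both assumptions are relaxed in coalescence,
where every species carries its own leakage, metabolism and cost.

## Assembly and stability certification

The ODEs are integrated with the BDF method and the analytic Jacobian
(validated elementwise against central finite differences at 10⁻⁶ relative
tolerance). Integration proceeds in chunks, initially 10³ time units and
growing geometrically (×2, capped at 10⁶) so that slow final transients do
not pay per-chunk setup costs. After each chunk, species below the
extinction threshold (10⁻⁹ biomass) are removed — extinction is absorbing,
so pruning cannot change the attractor — and tiny negative excursions are
clamped to zero. Convergence is declared when
`max |dx/dt| / max(|x|, 10⁻⁶) < 10⁻⁸` over all surviving state variables.
The time budget is 10⁷ units: growth rates scale with `(1 − l)`, so
high-leakage communities need roughly ten times longer to shed their last
doomed near-threshold species; runs that still have not converged are
flagged and excluded from downstream analysis (≲1% of runs at `l = 0.9`,
none at lower leakage in our suites).

Every converged equilibrium is certified locally asymptotically stable by
requiring all eigenvalue real parts of the Jacobian — evaluated on the
reduced system of survivors plus all resources, since extinct species'
zero rows are trivially marginal — to be ≤ 10⁻⁶. Integrator tolerances are
rtol 10⁻⁷ / atol 10⁻¹⁰; halving the convergence tolerance changes surviving
abundances by < 10⁻³ relative on the test fixtures.

## Coalescence protocols

Mixing concatenates both parents' survivors (origin labels preserved; all
per-species parameters carried over), resets resources to `R(0)` and
restarts every species at `N(0) = 1`. Restart-versus-carry-over of parent
abundances is an open choice; restart is the default because resources are
explicitly reset to their initial concentrations, signalling a fresh
environment, and a switch (`restart_abundance=None`) gives the
carry-over behavior. The dominance index is computed from presence/absence
of origin labels, so identical parameter draws in different parents never
alias; mixing an empty parent is handled as a degenerate case with
`S = ∓1`.

**Random protocol:** distinct pairs are drawn from a pool of assembled
communities sharing one leakage value but spanning the `k` grid; per-pair
`S` is recorded against the net-competition difference
`(C1 − F1) − (C2 − F2)` and binned into 20 equal-width bins (bins with
fewer than 5 pairs are flagged as unplotted).

**Recursive protocol:** parent A is assembled once; parent B's draw
(preferences, metabolism, cost fluctuations) is held fixed while its
leakage is set to each value of an increasing grid, its costs recomputed,
and it is re-assembled before mixing with the fixed A. `S` is oriented so
positive values mean B dominance. The acceptance experiment runs this at
`k_c = k_f = 0.9` for both parents: the cooperative advantage of
higher-leakage communities is carried by demand-aligned secretion, and a
power analysis showed the paired effect of ramping `l_B` from 0.1 to 0.9 is
+0.10 ± 0.03 at `k = 0.9` but exactly zero at `k = 0`, where the uniform
metabolic matrix feeds every consumer equally and no community-specific
facilitation exists to be selected.

**Serial protocol:** a resident (structure factors fixed at the grid
midpoint 0.5 so replicate trajectories start comparable) is invaded each
event by a freshly sampled, independently assembled community whose
`k_c = k_f` is drawn uniformly from the grid; survivors of each mix become
the new resident. Tracked per event: C, F, mean maintenance cost, mean
equilibrium resource concentration, richness, cumulative successful
invasions (invader-origin survivors), and the abundance fractions of the
1–5-preference groups. The default event count is 30 (the figure-style
axis length is not prescribed); acceptance runs use 15.

## Problem sizes used in the test and acceptance suites

Desk-scale experiments use `s = m = 30` communities: a 90-community
assembled pool (3 `k` values × 30 replicates, `l = 0.1`) feeding 500 random
coalescence pairs; recursive runs with 25 replicates per `l_A ∈ {0.1, 0.5,
0.9}`; serial runs with 15 events × 10 replicates; and 400 pooled
assemblies for the composition spectrum. Full-scale runs (s = m = 60,
2·10⁴ pairs, 100 assemblies per grid cell) are supported through the same
API and CLI.

## Composition statistics

For preference group `m_r`, `Δm_r = (T_mr/r − T⁰_mr/r⁰)/p(m_r)` measures
the richness-normalized change in the group's share through assembly
(positive: the group gained representation), and `w_mr` is the group's
share of surviving biomass. Groups with zero sampling probability are
excluded. At desk scale the per-`m_r` estimates carry sampling noise
comparable to the adjacent-group differences even with several hundred
pooled replicates, so the acceptance check evaluates Δ on coarse groups
({1}, {2}, {3}, {4–5}, {6–12}) — the well-sampled range — where the
specialist-to-generalist trend is resolved with adequate power.

## Conventions and known limitations

* Pairwise averages for C and F exclude self-pairs (`α ≠ β`, ordered); the
  convention is a single switch in the implementation. Dominance reasoning
  concerns interactions between distinct species.
* The sampling kernels realize the documented limiting behavior but are not
  a bit-for-bit reconstruction of any particular published sampling code;
  structural conclusions that depend on fine kernel details (notably the
  direction of mean facilitation under long serial invasion sequences)
  can differ between realizations. In this implementation, serial
  coalescence robustly decreases competition, mean cost and equilibrium
  resource concentrations and increases richness, while mean pairwise
  facilitation declines along with competition — selection for low niche
  overlap drags down demand-derived cross-feeding — and the across-replicate
  spread of the C and F curves at `s = 30` (richness ≈ 19) is roughly
  50–75% of the mean, a pair-count effect that shrinks with community size.
* The generator emulates structured random communities, not any empirical
  microbiome: there is no environmental fluctuation, no saturating uptake,
  no resource energy heterogeneity, and invasion happens as whole-community
  inoculation at equal abundance. Passing tests demonstrate internal
  consistency of the model and protocols at the stated scales, not
  predictions about real communities.
* Global stability, permanence, and limit-cycle detection beyond
  non-convergence flagging are out of scope.
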