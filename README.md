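# commcoal

Consumer-resource simulation of **microbial community coalescence** — the
mixing and joint reassembly of separately assembled microbial communities —
with tunable competition and cooperation (cross-feeding).

Microbial communities constantly collide: soils mix, leaves fall into
streams, fecal transplants meet resident gut flora. Which parent community
dominates such an encounter? `commcoal` lets you assemble in-silico
communities whose interaction structure you control, coalesce them under
three protocols, and quantify the outcome.

## The model

`s` consumer species share `m` substitutable resources. Species α has a
binary preference vector `c_α`, leaks a fraction `l_α` of its energy uptake
back into the environment as by-products (partitioned by a row-stochastic
metabolic matrix `D_α`), and pays a maintenance cost `z_α`:

```
dN_α/dt = g_α N_α ( (1 − l_α) Σ_j c_αj R_j − z_α )
dR_j/dt = κ_j − R_j/τ − Σ_α N_α c_αj R_j + Σ_{α,k} N_α l_α D_α[k,j] c_αk R_k

z_α = χ0 (1 + ε_α) (1 − l_α) Σ_j c_αj
```

Community-level interaction metrics, averaged over ordered pairs of
distinct species:

* competition `C = ⟨c_α · c_β⟩` (shared resource preferences),
* facilitation `F = ⟨l_α c_αᵀ D_α c_β⟩` (cross-feeding flow α → β),
* net competition `C − F` (its negative is the community's cohesion).

Sampling is structured by a competition factor `k_c` (preferential
attachment onto already-demanded resources — hubs of high demand) and a
facilitation factor `k_f` (secretion aligned with community demand), with
optional consumer guilds (`K_c`, `K_f`). Communities are integrated to a
steady state with a stiff implicit solver, extinct species are pruned, and
every equilibrium is certified locally asymptotically stable through the
eigenvalues of the analytic Jacobian.

Coalescence mixes the survivors of two parents in a fresh environment and
scores the outcome with the richness-normalized dominance index

```
S₁,₂ = p_f · (p₂/r₂ − p₁/r₁)   ∈ [−1, 1]
```

(−1: parent 1 reproduced exactly; +1: parent 2). Three protocols are
provided: **random** pairwise coalescence of a same-leakage pool,
**recursive** coalescence of one pair while parent B's leakage is ramped
up, and **serial** coalescence where a resident is repeatedly invaded by
freshly sampled communities.

## Worked example

```python
import numpy as np
import commcoal as cc

env = cc.Environment.table_defaults(30)          # κ=2, τ=0.25, m=30
spec_a = cc.SamplingSpec(s=30, m=30, k_c=0.0, k_f=0.0, leakage=0.1, seed=1)
spec_b = cc.SamplingSpec(s=30, m=30, k_c=0.9, k_f=0.9, leakage=0.1, seed=2)

a = cc.integrate_to_steady_state(cc.build_community(spec_a), env)
b = cc.integrate_to_steady_state(cc.build_community(spec_b), env)
post, rec = cc.mix(a, b, env)

print(f"parent A: r={a.richness}, C-F={rec.parent1_summary.net_competition:.2f}")
print(f"parent B: r={b.richness}, C-F={rec.parent2_summary.net_competition:.2f}")
print(f"dominance S = {rec.S:+.3f}, post richness {rec.post_summary.richness}, "
      f"stable={rec.stable}")
```

prints

```
parent A: r=18, C-F=1.43
parent B: r=13, C-F=0.53
dominance S = +0.291, post richness 21, stable=True
```

For this particular pair of draws, assembly left parent B with markedly
lower net competition than parent A (the factors `k_c`, `k_f` shift these
metrics only on average), and after coalescence the merged community leans
toward B (`S > 0`: B contributed a larger share of its surviving species) —
illustrating the central result that the less net competitive parent
dominates. The merged equilibrium is again certified stable.

The same experiments can be run from the shell on a YAML/JSON/TOML config:

```bash
commcoal assemble run.yaml
commcoal coalesce-random run.yaml
commcoal coalesce-recursive run.yaml
commcoal coalesce-serial run.yaml
```

Each writes tidy TSV record tables plus a JSON manifest with the full
configuration and seeds; rerunning with the same config and seed reproduces
the tables exactly.

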