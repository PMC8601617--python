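"""Structured random sampling of consumer preferences and metabolisms.

This is the synthetic-data generator of the pipeline: communities are not
read from data but sampled under structural constraints that set their
competitive and cooperative character before assembly.

Two knobs shape the matrices.  The competition factor ``k_c`` biases
preference sampling toward resources already demanded by previously sampled
species (preferential attachment): at ``k_c = 0`` preferences are uniform at
random, and as ``k_c → 1`` hubs of highly demanded resources form, which
accentuates pairwise niche overlap.  The facilitation factor ``k_f`` aligns
by-product secretion with community demand: at ``k_f = 0`` every consumed
resource is released in equiprobable fractions (all entries ``1/m``), and as
``k_f → 1`` secretion flows preferentially toward the most demanded
resources, feeding the community's bottleneck niches.

Optionally, resources are partitioned into classes with matching consumer
guilds; the inter-guild factors ``K_c`` and ``K_f`` set how much preference
and secretion mass crosses class boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import Community, Environment, maintenance_cost

logger = logging.getLogger("commcoal")


@dataclass
class GuildSpec:
    """Partition of species into guilds matched to resource classes."""

    n_guilds: int
    K_c: float = 0.5  # inter-guild competition factor
    K_f: float = 0.5  # inter-guild facilitation factor

    def __post_init__(self) -> None:
        if self.n_guilds < 1:
            raise ValueError("need at least one guild")
        # the mechanism is defined on [0, 1]; production configs restrict to
        # the standard (0.1, 0.9) range, but the 0/1 limits (fully modular /
        # fully mixed guilds) are meaningful and kept reachable here
        if not 0.0 <= self.K_c <= 1.0 or not 0.0 <= self.K_f <= 1.0:
            raise ValueError("K_c and K_f must lie in [0, 1]")


@dataclass
class SamplingSpec:
    """Parameters of one community draw.

    Defaults follow the standard parameterization: 60 species on 60
    resources, a mean of 5 metabolic preferences per species, uptake cost
    χ0 = 0.1 with cost fluctuations of standard deviation 0.1.
    """

    s: int = 60
    m: int = 60
    k_c: float = 0.0
    k_f: float = 0.0
    n_pref_mean: float = 5.0
    leakage: float | np.ndarray = 0.5
    chi0: float = 0.1
    eps_sigma: float = 0.1
    growth_factor: float = 1.0
    leakage_dependent_cost: bool = True
    shared_metabolism: bool = True
    N0: float = 1.0
    guilds: GuildSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.s < 1 or self.m < 1:
            raise ValueError("s and m must be positive")
        if not 0.0 <= self.k_c < 1.0:
            raise ValueError("k_c must lie in [0, 1)")
        if not 0.0 <= self.k_f <= 1.0:
            raise ValueError("k_f must lie in [0, 1]")
        if self.n_pref_mean < 1:
            raise ValueError("mean preference count must be at least 1")
        lk = np.atleast_1d(np.asarray(self.leakage, dtype=float))
        if np.any(lk < 0) or np.any(lk >= 1):
            raise ValueError("leakage must lie in [0, 1)")
        if self.guilds is not None:
            if self.s % self.guilds.n_guilds or self.m % self.guilds.n_guilds:
                raise ValueError("guild count must divide both s and m")

    def leakage_vector(self) -> np.ndarray:
        lk = np.atleast_1d(np.asarray(self.leakage, dtype=float))
        if lk.size == 1:
            return np.full(self.s, lk.item())
        if lk.size != self.s:
            raise ValueError("per-species leakage must have length s")
        return lk

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Preference-count distribution p(m_r)
# ---------------------------------------------------------------------------


def preference_count_pmf(n_pref_mean: float, m: int) -> np.ndarray:
    """pmf of the per-species preference count on support 1..m.

    Geometric (the discrete analogue of an exponential) with minimum 1 and
    untruncated mean ``n_pref_mean``, renormalized after truncation at ``m``.
    Index ``i`` of the returned array is the probability of ``m_r = i + 1``.
    """
    if n_pref_mean < 1:
        raise ValueError("mean preference count must be at least 1")
    if n_pref_mean == 1.0:
        pmf = np.zeros(m)
        pmf[0] = 1.0
        return pmf
    p = 1.0 / n_pref_mean
    k = np.arange(1, m + 1)
    pmf = p * (1.0 - p) ** (k - 1)
    return pmf / pmf.sum()


def sample_preference_counts(spec: SamplingSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one preference count per species from the truncated geometric."""
    if spec.n_pref_mean == 1.0:
        return np.ones(spec.s, dtype=int)
    counts = rng.geometric(p=1.0 / spec.n_pref_mean, size=spec.s)
    # rejection step implements the truncation at m
    while np.any(counts > spec.m):
        bad = counts > spec.m
        counts[bad] = rng.geometric(p=1.0 / spec.n_pref_mean, size=int(bad.sum()))
    return counts


# ---------------------------------------------------------------------------
# Preference matrix C
# ---------------------------------------------------------------------------


def _attachment_weights(demand: np.ndarray, k_c: float, m: int) -> np.ndarray:
    # mixture of a uniform kernel and preferential attachment on running demand
    return (1.0 - k_c) / m + k_c * (demand + 1.0) / (demand + 1.0).sum()


def sample_preference_matrix(
    spec: SamplingSpec,
    rng: np.random.Generator,
    counts: np.ndarray | None = None,
) -> np.ndarray:
    """Sample the binary s×m preference matrix C.

    Resources are assigned sequentially; each pick is weighted by
    ``(1−k_c)/m + k_c (d_j + 1)/Σ_k (d_k + 1)`` where ``d_j`` counts prior
    assignments of resource ``j`` across the whole draw, so large ``k_c``
    concentrates demand on emergent hub resources.
    """
    if counts is None:
        counts = sample_preference_counts(spec, rng)
    C = np.zeros((spec.s, spec.m), dtype=np.int8)
    demand = np.zeros(spec.m)
    for a in range(spec.s):
        taken = np.zeros(spec.m, dtype=bool)
        for _ in range(int(counts[a])):
            w = _attachment_weights(demand, spec.k_c, spec.m)
            w[taken] = 0.0
            w /= w.sum()
            j = rng.choice(spec.m, p=w)
            C[a, j] = 1
            taken[j] = True
            demand[j] += 1.0
    return C


# ---------------------------------------------------------------------------
# Metabolic matrix D
# ---------------------------------------------------------------------------


def sample_metabolic_matrix(
    spec: SamplingSpec, demand: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample the m×m row-stochastic metabolic matrix D.

    Row ``j`` gives the fractions in which consumed resource ``j`` is leaked
    as each by-product: a ``(1−k_f)`` share spread uniformly plus a ``k_f``
    share proportional to community demand.  ``rng`` is accepted for
    interface symmetry; the kernel itself is deterministic given the demand
    vector.
    """
    demand = np.asarray(demand, dtype=float)
    if demand.size != spec.m or np.any(demand < 0):
        raise ValueError("demand must be a nonnegative length-m vector")
    total = demand.sum()
    if total == 0 and spec.k_f > 0:
        logger.warning("all-zero resource demand with k_f=%g; falling back to uniform secretion", spec.k_f)
        row = np.full(spec.m, 1.0 / spec.m)
    else:
        share = demand / total if total > 0 else np.full(spec.m, 1.0 / spec.m)
        row = (1.0 - spec.k_f) / spec.m + spec.k_f * share
    D = np.tile(row / row.sum(), (spec.m, 1))
    return D


# ---------------------------------------------------------------------------
# Guild-structured sampling
# ---------------------------------------------------------------------------


def _resource_classes(m: int, n_guilds: int) -> np.ndarray:
    """Class label of each resource (contiguous equal blocks)."""
    return np.repeat(np.arange(n_guilds), m // n_guilds)


def sample_guild_structured(
    spec: SamplingSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (C, D) with consumer guilds matched to resource classes.

    Each preference pick lands outside the species' own resource class with
    probability ``K_c`` (more cross-guild competition) and inside otherwise;
    within the chosen class set the ``k_c`` preferential-attachment kernel
    applies.  Each metabolic row allocates a ``K_f`` share of its secretion
    outside the class of the consumed resource (more cross-guild
    facilitation) and ``1 − K_f`` within; inside each side the ``k_f``
    demand-mixture kernel applies.  Rows of D still sum to exactly 1.
    """
    if spec.guilds is None:
        raise ValueError("guild specification required")
    gs = spec.guilds
    classes = _resource_classes(spec.m, gs.n_guilds)
    guild_of_species = np.repeat(np.arange(gs.n_guilds), spec.s // gs.n_guilds)

    counts = sample_preference_counts(spec, rng)
    C = np.zeros((spec.s, spec.m), dtype=np.int8)
    demand = np.zeros(spec.m)
    for a in range(spec.s):
        own = classes == guild_of_species[a]
        taken = np.zeros(spec.m, dtype=bool)
        for _ in range(int(counts[a])):
            inside = rng.random() >= gs.K_c
            mask = own if inside else ~own
            w = _attachment_weights(demand, spec.k_c, spec.m)
            w = np.where(mask & ~taken, w, 0.0)
            if w.sum() == 0.0:  # chosen side exhausted; fall back to the other
                w = _attachment_weights(demand, spec.k_c, spec.m)
                w[taken] = 0.0
            w /= w.sum()
            j = rng.choice(spec.m, p=w)
            C[a, j] = 1
            taken[j] = True
            demand[j] += 1.0

    # metabolic matrix: per-row split between own class and the rest
    total = demand.sum()
    share = demand / total if total > 0 else np.full(spec.m, 1.0 / spec.m)
    base = (1.0 - spec.k_f) / spec.m + spec.k_f * share
    D = np.zeros((spec.m, spec.m))
    for j in range(spec.m):
        own = classes == classes[j]
        row = np.zeros(spec.m)
        for mask, weight in ((own, 1.0 - gs.K_f), (~own, gs.K_f)):
            side = np.where(mask, base, 0.0)
            if side.sum() > 0:
                row += weight * side / side.sum()
        D[j] = row / row.sum()
    return C, D


# ---------------------------------------------------------------------------
# Community construction
# ---------------------------------------------------------------------------


def draw_epsilon(spec: SamplingSpec, rng: np.random.Generator) -> np.ndarray:
    """Cost fluctuations ε ~ N(0, σ), resampled if ε ≤ −1."""
    eps = rng.normal(0.0, spec.eps_sigma, size=spec.s)
    while np.any(eps <= -1.0):
        bad = eps <= -1.0
        eps[bad] = rng.normal(0.0, spec.eps_sigma, size=int(bad.sum()))
    return eps


_community_counter = 0


def _next_community_id() -> int:
    global _community_counter
    _community_counter += 1
    return _community_counter


def build_community(spec: SamplingSpec, rng: np.random.Generator | None = None) -> Community:
    """Sample a full pre-assembly community under ``spec``.

    In the default shared-metabolism mode all species reference one D matrix
    derived from the community's own demand profile (column sums of C).
    """
    if rng is None:
        rng = spec.rng()
    if spec.guilds is not None:
        C, D = sample_guild_structured(spec, rng)
    else:
        C = sample_preference_matrix(spec, rng)
        D = sample_metabolic_matrix(spec, C.sum(axis=0).astype(float), rng)
    leakage = spec.leakage_vector()
    eps = draw_epsilon(spec, rng)
    cost = np.array(
        [
            maintenance_cost(
                C[a], leakage[a], spec.chi0, eps[a], spec.leakage_dependent_cost
            )
            for a in range(spec.s)
        ]
    )
    cid = _next_community_id()
    return Community(
        prefs=C.astype(float),
        D=D if spec.shared_metabolism else np.tile(D, (spec.s, 1, 1)),
        leakage=leakage,
        cost=cost,
        growth=np.full(spec.s, spec.growth_factor),
        eps=eps,
        abundances=np.full(spec.s, spec.N0),
        origins=[(cid, i) for i in range(spec.s)],
    )


def set_leakage(
    community: Community,
    leakage: float,
    chi0: float = 0.1,
    leakage_dependent_cost: bool = True,
) -> Community:
    """Same species draw at a different leakage level, costs recomputed.

    Competition (a function of C alone) is untouched; facilitation scales
    with the new leakage.  Used by the recursive coalescence protocol.
    """
    lk = np.full(community.s, float(leakage))
    cost = np.array(
        [
            maintenance_cost(
                community.prefs[i], lk[i], chi0, community.eps[i], leakage_dependent_cost
            )
            for i in range(community.s)
        ]
    )
    return Community(
        prefs=community.prefs.copy(),
        D=community.D.copy(),
        leakage=lk,
        cost=cost,
        growth=community.growth.copy(),
        eps=community.eps.copy(),
        abundances=np.ones(community.s),
        origins=list(community.origins),
    )


def default_environment(spec: SamplingSpec, kappa: float = 2.0, tau: float = 0.25) -> Environment:
    return Environment.table_defaults(spec.m, kappa=kappa, tau=tau)
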