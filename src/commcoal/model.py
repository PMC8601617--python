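"""Consumer-resource dynamics with metabolic leakage.

The community model couples ``s`` consumer species to ``m`` substitutable
resources.  Species ``α`` harvests energy at rate ``Σ_j c_αj R_j`` (binary
uptake, linear functional response), leaks a fraction ``l_α`` of that intake
back into the environment as metabolic by-products (partitioned between
resources by its row-stochastic metabolic matrix ``D_α``), and converts the
remainder, minus a maintenance cost ``z_α``, into biomass:

    dN_α/dt = g_α N_α ( (1 − l_α) Σ_j c_αj R_j − z_α )
    dR_j/dt = κ_j − R_j/τ − Σ_α N_α c_αj R_j
              + Σ_{α,k} N_α l_α D_α[k, j] c_αk R_k

Resources are externally supplied at rate ``κ_j`` and diluted on a timescale
``τ``.  The maintenance cost scales with the number of encoded uptake
pathways so that neither generalists nor specialists are systematically
favored, and (optionally) with ``1 − l`` so that consumers deplete resources
to similar concentrations regardless of their leakage level:

    z_α = χ0 (1 + ε_α) (1 − l_α) Σ_j c_αj

with ``ε_α`` a small random cost fluctuation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("commcoal")

#: rows of a metabolic matrix must sum to 1 within this tolerance
ROW_STOCHASTIC_TOL = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Environment:
    """Abiotic context: resource supply, dilution, and initial concentrations.

    Parameters
    ----------
    kappa
        Per-resource supply rate (mol s⁻¹); scalar values broadcast to ``m``.
    tau
        Dilution timescale (s).
    R0
        Initial resource concentrations (mol).  Defaults to the consumer-free
        supply equilibrium ``κ·τ``.
    """

    kappa: np.ndarray
    tau: float = 0.25
    R0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        if np.any(self.kappa < 0):
            raise ValueError("supply rates kappa must be nonnegative")
        if self.tau <= 0:
            raise ValueError("dilution timescale tau must be positive")
        if self.R0 is None:
            self.R0 = self.kappa * self.tau
        else:
            self.R0 = np.asarray(self.R0, dtype=float)
            if self.R0.shape != self.kappa.shape:
                raise ValueError("R0 and kappa must have the same length")
            if np.any(self.R0 < 0):
                raise ValueError("initial resource concentrations must be nonnegative")

    @property
    def m(self) -> int:
        return self.kappa.size

    @classmethod
    def table_defaults(cls, m: int, kappa: float = 2.0, tau: float = 0.25) -> "Environment":
        """Environment with every resource supplied at the default rate."""
        return cls(kappa=np.full(m, float(kappa)), tau=tau)


@dataclass
class Species:
    """A single consumer: its uptake genotype, metabolism, and energetics."""

    preferences: np.ndarray  # binary length-m vector c_α
    metabolism: np.ndarray  # m×m row-stochastic D_α
    leakage: float  # l_α ∈ [0, 1)
    cost: float  # z_α ≥ 0
    growth_factor: float = 1.0  # g_α
    epsilon: float = 0.0  # cost fluctuation ε_α
    origin: tuple = ()  # opaque (community id, species index) label

    def __post_init__(self) -> None:
        self.preferences = np.asarray(self.preferences)
        self.metabolism = np.asarray(self.metabolism, dtype=float)
        if not 0.0 <= self.leakage < 1.0:
            raise ValueError("leakage must lie in [0, 1)")
        if self.cost < 0:
            raise ValueError("maintenance cost must be nonnegative")
        if self.preferences.sum() < 1:
            raise ValueError("species must consume at least one resource")
        rows = self.metabolism.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("metabolic matrix rows must sum to 1")


@dataclass
class Community:
    """An ordered collection of consumers sharing a common resource space.

    Species attributes are stored columnar (one array entry per species) so
    the dynamics can be evaluated without Python-level loops.  ``D`` is either
    a single shared ``(m, m)`` matrix (the shared-core-metabolism assumption
    used during parent assembly) or an ``(s, m, m)`` per-species stack (the
    fully general form used in coalescence of communities with distinct
    metabolisms).
    """

    prefs: np.ndarray  # (s, m) binary
    D: np.ndarray  # (m, m) shared or (s, m, m) per-species
    leakage: np.ndarray  # (s,)
    cost: np.ndarray  # (s,)
    growth: np.ndarray  # (s,)
    eps: np.ndarray  # (s,)
    abundances: np.ndarray  # (s,)
    origins: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.prefs = np.atleast_2d(np.asarray(self.prefs, dtype=float))
        s = self.prefs.shape[0]
        for name in ("leakage", "cost", "growth", "eps", "abundances"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.size == 1 and s > 1:
                arr = np.full(s, arr.item())
            if arr.size != s:
                raise ValueError(f"{name} has length {arr.size}, expected {s}")
            setattr(self, name, arr)
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim not in (2, 3):
            raise ValueError("D must be (m, m) or (s, m, m)")
        if self.D.shape[-1] != self.m or self.D.shape[-2] != self.m:
            raise ValueError("metabolic matrix shape inconsistent with m")
        if self.D.ndim == 3 and self.D.shape[0] != s:
            raise ValueError("per-species D stack must have one matrix per species")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be nonnegative")
        if not self.origins:
            self.origins = [(id(self), i) for i in range(s)]
        elif len(self.origins) != s:
            raise ValueError("one origin label per species required")

    # -- basic geometry ----------------------------------------------------

    @property
    def s(self) -> int:
        return self.prefs.shape[0]

    @property
    def m(self) -> int:
        return self.prefs.shape[1]

    @property
    def richness(self) -> int:
        """Number of species with strictly positive abundance."""
        return int(np.count_nonzero(self.abundances > 0))

    @property
    def shared_metabolism(self) -> bool:
        return self.D.ndim == 2

    def metabolism_of(self, i: int) -> np.ndarray:
        return self.D if self.shared_metabolism else self.D[i]

    def D_stack(self) -> np.ndarray:
        """Per-species (s, m, m) view of the metabolic matrices."""
        if self.shared_metabolism:
            return np.broadcast_to(self.D, (self.s, self.m, self.m))
        return self.D

    # -- species-level views -----------------------------------------------

    @property
    def species(self) -> list[Species]:
        return [
            Species(
                preferences=self.prefs[i],
                metabolism=self.metabolism_of(i),
                leakage=float(self.leakage[i]),
                cost=float(self.cost[i]),
                growth_factor=float(self.growth[i]),
                epsilon=float(self.eps[i]),
                origin=self.origins[i],
            )
            for i in range(self.s)
        ]

    @classmethod
    def from_species(cls, species: Sequence[Species], abundances=None) -> "Community":
        if not species:
            raise ValueError("cannot build a community from zero species")
        if abundances is None:
            abundances = np.ones(len(species))
        return cls(
            prefs=np.array([sp.preferences for sp in species], dtype=float),
            D=np.array([sp.metabolism for sp in species], dtype=float),
            leakage=np.array([sp.leakage for sp in species]),
            cost=np.array([sp.cost for sp in species]),
            growth=np.array([sp.growth_factor for sp in species]),
            eps=np.array([sp.epsilon for sp in species]),
            abundances=np.asarray(abundances, dtype=float),
            origins=[sp.origin for sp in species],
        )

    # -- structural operations ----------------------------------------------

    def subset(self, idx: np.ndarray) -> "Community":
        """Community restricted to species ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return Community(
            prefs=self.prefs[idx],
            D=self.D if self.shared_metabolism else self.D[idx],
            leakage=self.leakage[idx],
            cost=self.cost[idx],
            growth=self.growth[idx],
            eps=self.eps[idx],
            abundances=self.abundances[idx],
            origins=[self.origins[i] for i in np.atleast_1d(idx)],
        )

    def with_abundances(self, abundances: np.ndarray) -> "Community":
        return replace(self, abundances=np.asarray(abundances, dtype=float),
                       origins=list(self.origins))

    @staticmethod
    def concatenate(a: "Community", b: "Community") -> "Community":
        """Pool two communities over a common resource space."""
        if a.m != b.m:
            raise ValueError("communities live in different resource spaces")
        # per-species D stack unless both share the *same* matrix
        if a.shared_metabolism and b.shared_metabolism and a.D is b.D:
            D = a.D
        else:
            D = np.concatenate([a.D_stack(), b.D_stack()], axis=0)
        return Community(
            prefs=np.concatenate([a.prefs, b.prefs], axis=0),
            D=D,
            leakage=np.concatenate([a.leakage, b.leakage]),
            cost=np.concatenate([a.cost, b.cost]),
            growth=np.concatenate([a.growth, b.growth]),
            eps=np.concatenate([a.eps, b.eps]),
            abundances=np.concatenate([a.abundances, b.abundances]),
            origins=list(a.origins) + list(b.origins),
        )


@dataclass
class SystemState:
    """Instantaneous state (consumer abundances, resource concentrations)."""

    N: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.atleast_1d(np.asarray(self.N, dtype=float))
        self.R = np.atleast_1d(np.asarray(self.R, dtype=float))
        if np.any(self.N < 0) or np.any(self.R < 0):
            raise ValueError("state variables must be nonnegative")


# ---------------------------------------------------------------------------
# Maintenance cost
# ---------------------------------------------------------------------------


def maintenance_cost(
    preferences: np.ndarray,
    leakage: float,
    chi0: float = 0.1,
    epsilon: float = 0.0,
    leakage_dependent: bool = True,
) -> float:
    """Maintenance energy rate of a consumer.

    ``z = χ0 (1 + ε) (1 − l) Σ_j c_j`` in the default (leakage-dependent)
    form; the ``(1 − l)`` efficiency factor is dropped when
    ``leakage_dependent`` is False, giving the cost variant that does not
    compensate for leakage losses.
    """
    preferences = np.asarray(preferences)
    if preferences.size == 0:
        raise ValueError("preferences must be nonempty")
    if chi0 < 0:
        raise ValueError("chi0 must be nonnegative")
    if epsilon <= -1.0:
        raise ValueError("epsilon must exceed -1 (negative cost would subsidize growth)")
    n_pref = float(preferences.sum())
    z = chi0 * (1.0 + epsilon) * n_pref
    if leakage_dependent:
        z *= 1.0 - leakage
    return z


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def make_rhs(
    community: Community, env: Environment
) -> tuple[Callable[[float, np.ndarray], np.ndarray], Callable[[float, np.ndarray], np.ndarray]]:
    """Build ``(f, jac)`` closures over the packed state ``x = (N, R)``.

    These skip domain validation so stiff integrators may probe slightly
    negative trial states; user-facing entry points validate separately.
    """
    s, m = community.s, community.m
    prefs = community.prefs
    l = community.leakage
    z = community.cost
    g = community.growth
    kappa = env.kappa
    inv_tau = 1.0 / env.tau
    shared = community.shared_metabolism
    D = community.D

    def f(t: float, x: np.ndarray) -> np.ndarray:
        N, R = x[:s], x[s:]
        u = prefs * R  # (s, m): per-species resource-energy flux density
        harvest = u.sum(axis=1)
        dN = g * N * ((1.0 - l) * harvest - z)
        Nu = N[:, None] * u
        uptake = Nu.sum(axis=0)
        W = (N * l)[:, None] * u
        if shared:
            inflow = W.sum(axis=0) @ D
        else:
            inflow = np.einsum("sk,skj->j", W, D)
        dR = kappa - inv_tau * R - uptake + inflow
        return np.concatenate([dN, dR])

    def jac(t: float, x: np.ndarray) -> np.ndarray:
        N, R = x[:s], x[s:]
        u = prefs * R
        harvest = u.sum(axis=1)
        J = np.zeros((s + m, s + m))
        # ∂(dN)/∂N: diagonal (no direct consumer-consumer coupling)
        np.fill_diagonal(J[:s, :s], g * ((1.0 - l) * harvest - z))
        # ∂(dN_α)/∂R_j = g_α N_α (1 − l_α) c_αj
        J[:s, s:] = (g * N * (1.0 - l))[:, None] * prefs
        # ∂(dR_j)/∂N_β = −c_βj R_j + l_β Σ_k D_β[k,j] c_βk R_k
        if shared:
            V = l[:, None] * (u @ D)
        else:
            V = l[:, None] * np.einsum("sk,skj->sj", u, D)
        J[s:, :s] = (V - u).T
        # ∂(dR_j)/∂R_k
        if shared:
            M = ((N * l) @ prefs)[:, None] * D  # M[k, j]
        else:
            M = np.einsum("s,sk,skj->kj", N * l, prefs, D)
        JRR = M.T
        diag = -inv_tau - N @ prefs
        JRR[np.diag_indices(m)] += diag
        J[s:, s:] = JRR
        return J

    return f, jac


def dynamics_rhs(
    state: SystemState, community: Community, env: Environment
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives ``(dN/dt, dR/dt)`` of the community model."""
    if state.N.size != community.s:
        raise ValueError("abundance vector length does not match community")
    if state.R.size != env.m or env.m != community.m:
        raise ValueError("resource vector length does not match environment")
    f, _ = make_rhs(community, env)
    dx = f(0.0, np.concatenate([state.N, state.R]))
    return dx[: community.s], dx[community.s :]


def jacobian(state: SystemState, community: Community, env: Environment) -> np.ndarray:
    """Analytic ``(s+m)×(s+m)`` Jacobian of the dynamics at ``state``."""
    if state.N.size != community.s or state.R.size != community.m:
        raise ValueError("state dimensions inconsistent with community")
    _, jacf = make_rhs(community, env)
    return jacf(0.0, np.concatenate([state.N, state.R]))
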