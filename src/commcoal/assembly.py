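"""Community assembly: integrate the dynamics to a certified equilibrium.

Starting from the sampled species pool, the coupled consumer-resource ODEs
are integrated in chunks with a stiff-capable implicit method and the
analytic Jacobian.  Between chunks, species whose biomass has fallen below
the extinction threshold are removed (extinction is absorbing, so pruning
accelerates convergence without changing the attractor), and the system is
declared at steady state once the largest relative rate of change over all
surviving state variables drops below the convergence tolerance.  Each
putative equilibrium is then certified locally asymptotically stable via the
eigenvalues of the reduced Jacobian (extinct species removed, since their
zero rows are trivially marginal).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .metrics import summarize_interactions
from .model import Community, Environment, make_rhs
from .sampling import SamplingSpec, build_community, default_environment

logger = logging.getLogger("commcoal")


@dataclass
class AssemblyControls:
    """Numerical controls of the steady-state search.

    extinction_threshold : biomass below which a species is removed (B_a).
    conv_tol             : convergence bound on max |dx/dt| / max(|x|, floor).
    chunk                : initial integration chunk length (s); later chunks
                           grow geometrically so slow final transients do not
                           pay per-chunk setup costs.
    max_time             : give up (flag non-convergence) beyond this time;
                           generous because near-threshold extinction
                           transients decay at rates scaled by (1 − l), so
                           high-leakage communities need ~10x longer to shed
                           their last doomed species.
    rtol, atol           : integrator tolerances; tight atol keeps
                           near-extinct abundances meaningful.
    method               : any stiff-capable ``solve_ivp`` method.
    stability_tol        : certified stable iff max Re(eigenvalue) ≤ this.
    rate_floor           : denominator floor of the relative-rate criterion.
    """

    extinction_threshold: float = 1e-9
    conv_tol: float = 1e-8
    chunk: float = 1e3
    chunk_growth: float = 2.0  # chunks lengthen geometrically up to chunk_max
    chunk_max: float = 1e6
    max_time: float = 1e7
    rtol: float = 1e-7
    atol: float = 1e-10
    method: str = "BDF"
    stability_tol: float = 1e-6
    rate_floor: float = 1e-6


@dataclass
class AssemblyResult:
    """A pruned community at its (putative, certified) equilibrium."""

    community: Community  # survivors, abundances = N*
    R_star: np.ndarray
    stable: bool
    converged: bool
    n_extinctions: int
    trajectory_summary: dict = field(default_factory=dict)

    @property
    def R_tot_star(self) -> float:
        return float(self.R_star.sum())

    @property
    def richness(self) -> int:
        return self.community.richness


def _max_relative_rate(dx: np.ndarray, x: np.ndarray, floor: float) -> float:
    if x.size == 0:
        return 0.0
    return float(np.max(np.abs(dx) / np.maximum(np.abs(x), floor)))


def integrate_to_steady_state(
    community: Community,
    env: Environment,
    controls: AssemblyControls | None = None,
) -> AssemblyResult:
    """Integrate to equilibrium, pruning extinctions between chunks."""
    if controls is None:
        controls = AssemblyControls()
    if community.m != env.m:
        raise ValueError("community and environment disagree on resource count")

    t0 = time.perf_counter()
    current = community
    N = current.abundances.astype(float).copy()
    R = env.R0.astype(float).copy()
    s0 = current.s
    t = 0.0
    converged = False
    f, jacf = make_rhs(current, env)
    chunk = controls.chunk

    while t < controls.max_time:
        x0 = np.concatenate([N, R])
        sol = solve_ivp(
            f,
            (t, min(t + chunk, controls.max_time)),
            x0,
            method=controls.method,
            jac=jacf,
            rtol=controls.rtol,
            atol=controls.atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={t:g}: {sol.message} "
                f"(s={current.s}, m={current.m})"
            )
        t = sol.t[-1]
        x = sol.y[:, -1]
        N = np.clip(x[: current.s], 0.0, None)  # clamp tiny negative excursions
        R = np.clip(x[current.s :], 0.0, None)
        # absorb extinctions and shrink the system
        dead = N < controls.extinction_threshold
        if np.any(dead):
            keep = np.flatnonzero(~dead)
            current = current.subset(keep)
            N = N[keep]
            f, jacf = make_rhs(current, env)
        dx = f(t, np.concatenate([N, R]))
        if _max_relative_rate(dx, np.concatenate([N, R]), controls.rate_floor) < controls.conv_tol:
            converged = True
            break
        chunk = min(chunk * controls.chunk_growth, controls.chunk_max)

    current = current.with_abundances(N)
    result = AssemblyResult(
        community=current,
        R_star=R,
        stable=False,
        converged=converged,
        n_extinctions=s0 - current.s,
        trajectory_summary={
            "t_final": t,
            "max_rel_rate": _max_relative_rate(
                f(t, np.concatenate([N, R])), np.concatenate([N, R]), controls.rate_floor
            ),
            "wall_seconds": time.perf_counter() - t0,
        },
    )
    if converged:
        result.stable = verify_stability(result, env, controls)
    else:
        logger.warning(
            "assembly did not converge within t=%g (max relative rate %.3g)",
            controls.max_time,
            result.trajectory_summary["max_rel_rate"],
        )
    return result


def verify_stability(
    result: AssemblyResult,
    env: Environment,
    controls: AssemblyControls | None = None,
) -> bool:
    """Local asymptotic stability of the reduced equilibrium.

    Evaluates the analytic Jacobian on the surviving species plus all
    resources and requires every eigenvalue real part to be at most the
    stability tolerance.
    """
    if controls is None:
        controls = AssemblyControls()
    if not result.converged:
        raise ValueError("stability is only certified for converged equilibria")
    community = result.community
    _, jacf = make_rhs(community, env)
    J = jacf(0.0, np.concatenate([community.abundances, result.R_star]))
    eigs = np.linalg.eigvals(J)
    return bool(np.max(eigs.real) <= controls.stability_tol)


def assemble_batch(
    specs: list[SamplingSpec],
    env: Environment | None = None,
    controls: AssemblyControls | None = None,
) -> tuple[list[AssemblyResult | None], pd.DataFrame]:
    """Run independent assemblies and tabulate per-community metrics.

    Returns the results (``None`` where a run failed or did not converge)
    and a tidy table with one row per converged community: seed, k_c, k_f,
    leakage, richness, C, F, R*_tot and the stability flag.
    """
    results: list[AssemblyResult | None] = []
    rows = []
    for spec in specs:
        local_env = env if env is not None else default_environment(spec)
        try:
            community = build_community(spec)
            res = integrate_to_steady_state(community, local_env, controls)
        except Exception:
            logger.exception("assembly failed for seed=%s; skipping", spec.seed)
            results.append(None)
            continue
        if not res.converged:
            results.append(None)
            continue
        results.append(res)
        summary = summarize_interactions(res.community)
        lk = spec.leakage_vector()
        rows.append(
            {
                "seed": spec.seed,
                "s": spec.s,
                "m": spec.m,
                "k_c": spec.k_c,
                "k_f": spec.k_f,
                "leakage": float(lk.mean()),
                "richness": summary.richness,
                "competition": summary.competition,
                "facilitation": summary.facilitation,
                "net_competition": summary.net_competition,
                "R_tot_star": res.R_tot_star,
                "stable": res.stable,
            }
        )
    return results, pd.DataFrame(rows)
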