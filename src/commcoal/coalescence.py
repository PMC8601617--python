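"""Community coalescence protocols and the dominance index.

Coalescence mixes the surviving species of two independently assembled
parent communities in a fresh environment (resources reset to their initial
concentrations, all species restarted at the inoculation abundance) and
integrates the combined system to a new certified equilibrium.  The outcome
is scored by the richness-normalized dominance index

    S_{1,2} = p_f · (p_2 / r_2 − p_1 / r_1)

where p_f, p_1, p_2 are presence/absence vectors over the pooled species
list and r_i the parent richness values: S = −1 reproduces parent 1 exactly,
S = +1 reproduces parent 2, and the normalization removes any bias toward
the richer parent.

Three protocols are provided: random pairwise coalescence of a pool of
communities sharing a leakage level, recursive coalescence of one pair with
the leakage of parent B ramped up between events, and serial coalescence in
which a resident community is successively invaded by freshly sampled
communities while its structural and functional properties are tracked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import AssemblyControls, AssemblyResult, integrate_to_steady_state
from .metrics import InteractionSummary, summarize_interactions
from .model import Community, Environment
from .sampling import SamplingSpec, build_community, set_leakage

logger = logging.getLogger("commcoal")


@dataclass
class CoalescenceRecord:
    parent1_summary: InteractionSummary
    parent2_summary: InteractionSummary
    parent1_R_tot: float
    parent2_R_tot: float
    S: float
    post_summary: InteractionSummary
    stable: bool
    converged: bool = True
    params: dict = field(default_factory=dict)

    @property
    def net_competition_difference(self) -> float:
        """(C1 − F1) − (C2 − F2), the x axis of the dominance curve."""
        return self.parent1_summary.net_competition - self.parent2_summary.net_competition


# ---------------------------------------------------------------------------
# Dominance index
# ---------------------------------------------------------------------------


def similarity(post: Community, parent1: Community, parent2: Community) -> float:
    """Dominance index S ∈ [−1, 1] of the coalesced community.

    Species identity is tracked through origin labels, so duplicated
    parameter draws across parents never alias.
    """
    r1, r2 = parent1.richness, parent2.richness
    if r1 == 0 or r2 == 0:
        raise ValueError("dominance index undefined for an empty parent")
    post_alive = {post.origins[i] for i in np.flatnonzero(post.abundances > 0)}
    labels1 = [parent1.origins[i] for i in np.flatnonzero(parent1.abundances > 0)]
    labels2 = [parent2.origins[i] for i in np.flatnonzero(parent2.abundances > 0)]
    surv1 = sum(1 for lab in labels1 if lab in post_alive)
    surv2 = sum(1 for lab in labels2 if lab in post_alive)
    return surv2 / r2 - surv1 / r1


# ---------------------------------------------------------------------------
# Pairwise mixing
# ---------------------------------------------------------------------------


def mix(
    parent1: AssemblyResult,
    parent2: AssemblyResult,
    env: Environment,
    controls: AssemblyControls | None = None,
    restart_abundance: float | None = 1.0,
) -> tuple[AssemblyResult, CoalescenceRecord]:
    """Coalesce two assembled parents and score the outcome.

    Resources are reset to the environment's initial concentrations; both
    parents' survivors are inoculated at ``restart_abundance`` (pass ``None``
    to carry over the parents' equilibrium abundances instead).  Per-species
    leakage, metabolism and cost carry over unchanged, so mixed communities
    run the model in its fully general per-species form.
    """
    c1, c2 = parent1.community, parent2.community
    if c1.richness == 0 or c2.richness == 0:
        # degenerate mix: the non-empty parent re-equilibrates alone and
        # dominates completely
        survivor = parent1 if c1.richness > 0 else parent2
        post = integrate_to_steady_state(survivor.community, env, controls)
        record = CoalescenceRecord(
            parent1_summary=summarize_interactions(c1),
            parent2_summary=summarize_interactions(c2),
            parent1_R_tot=parent1.R_tot_star,
            parent2_R_tot=parent2.R_tot_star,
            S=-1.0 if c1.richness > 0 else 1.0,
            post_summary=summarize_interactions(post.community),
            stable=post.stable,
            converged=post.converged,
        )
        return post, record
    combined = Community.concatenate(c1, c2)
    if restart_abundance is not None:
        combined = combined.with_abundances(np.full(combined.s, float(restart_abundance)))
    post = integrate_to_steady_state(combined, env, controls)
    record = CoalescenceRecord(
        parent1_summary=summarize_interactions(c1),
        parent2_summary=summarize_interactions(c2),
        parent1_R_tot=parent1.R_tot_star,
        parent2_R_tot=parent2.R_tot_star,
        S=similarity(post.community, c1, c2),
        post_summary=summarize_interactions(post.community),
        stable=post.stable,
        converged=post.converged,
    )
    return post, record


# ---------------------------------------------------------------------------
# Protocol 1: random pairwise coalescence
# ---------------------------------------------------------------------------


def bin_dominance_curve(
    x: np.ndarray, y: np.ndarray, n_bins: int = 20, min_count: int = 5
) -> pd.DataFrame:
    """Mean ± sd of y in equal-width bins of x; sparse bins are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append(
            {
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "mean_S": float(y[sel].mean()),
                "sd_S": float(y[sel].std(ddof=0)),
                "n": n,
                "plotted": n >= min_count,
            }
        )
    return pd.DataFrame(rows)


def random_coalescence(
    pool: list[AssemblyResult],
    n_pairs: int,
    rng: np.random.Generator,
    env: Environment,
    controls: AssemblyControls | None = None,
    n_bins: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coalesce randomly sampled distinct pairs from a same-leakage pool.

    The pool should span the competition-factor grid at a fixed leakage so
    pairs cover a broad range of net-competition differences.  Returns the
    per-pair record table and the 20-bin dominance curve of S against
    (C1 − F1) − (C2 − F2).
    """
    if len(pool) < 2:
        raise ValueError("need at least two assembled communities to coalesce")
    rows = []
    for p in range(n_pairs):
        i, j = rng.choice(len(pool), size=2, replace=False)
        post, rec = mix(pool[i], pool[j], env, controls)
        rows.append(
            {
                "pair": p,
                "parent1": int(i),
                "parent2": int(j),
                "S": rec.S,
                "net_competition_difference": rec.net_competition_difference,
                "C1": rec.parent1_summary.competition,
                "F1": rec.parent1_summary.facilitation,
                "C2": rec.parent2_summary.competition,
                "F2": rec.parent2_summary.facilitation,
                "r1": rec.parent1_summary.richness,
                "r2": rec.parent2_summary.richness,
                "post_richness": rec.post_summary.richness,
                "stable": rec.stable,
                "converged": rec.converged,
            }
        )
    records = pd.DataFrame(rows)
    ok = records[records["converged"]]
    if len(ok) < len(records):
        logger.warning(
            "%d/%d coalescence runs did not converge; excluded from the binned curve",
            len(records) - len(ok), len(records),
        )
    curve = bin_dominance_curve(
        ok["net_competition_difference"].to_numpy(),
        ok["S"].to_numpy(),
        n_bins=n_bins,
    )
    return records, curve


# ---------------------------------------------------------------------------
# Protocol 2: recursive coalescence along a leakage ramp
# ---------------------------------------------------------------------------


def recursive_coalescence(
    base_spec: SamplingSpec,
    l_A: float,
    l_B_grid: np.ndarray,
    replicates: int,
    rng: np.random.Generator,
    env: Environment,
    controls: AssemblyControls | None = None,
) -> pd.DataFrame:
    """Dominance of parent B as its leakage is ramped up against a fixed A.

    Per replicate, community A is sampled and assembled once at ``l_A``; the
    B draw (preferences, metabolism, cost fluctuations) is held fixed while
    its leakage takes each value of ``l_B_grid`` in turn, its costs are
    recomputed, and it is re-assembled before coalescing with A.  S is
    oriented so positive values mean B dominance.
    """
    l_B_grid = np.asarray(l_B_grid, dtype=float)
    if np.any(np.diff(l_B_grid) <= 0):
        raise ValueError("l_B grid must be strictly increasing")
    rows = []
    from dataclasses import replace

    for rep in range(replicates):
        seed_a, seed_b = rng.integers(0, 2**31 - 1, size=2)
        spec_a = replace(base_spec, leakage=l_A, seed=int(seed_a))
        A = integrate_to_steady_state(build_community(spec_a), env, controls)
        if not A.converged or A.richness == 0:
            logger.warning("recursive replicate %d: parent A failed; skipping", rep)
            continue
        spec_b = replace(base_spec, leakage=float(l_B_grid[0]), seed=int(seed_b))
        B_draw = build_community(spec_b)
        for l_B in l_B_grid:
            B_community = set_leakage(
                B_draw, float(l_B), chi0=base_spec.chi0,
                leakage_dependent_cost=base_spec.leakage_dependent_cost,
            )
            B = integrate_to_steady_state(B_community, env, controls)
            if not B.converged or B.richness == 0:
                logger.warning(
                    "recursive replicate %d, l_B=%.3g: parent B failed; skipping", rep, l_B
                )
                continue
            _, rec = mix(A, B, env, controls)
            draw_summary = summarize_interactions(B_community, surviving_only=False)
            rows.append(
                {
                    "replicate": rep,
                    "l_A": l_A,
                    "l_B": float(l_B),
                    "S": rec.S,
                    "C_B": rec.parent2_summary.competition,
                    "F_B": rec.parent2_summary.facilitation,
                    "C_B_draw": draw_summary.competition,
                    "F_B_draw": draw_summary.facilitation,
                    "r_A": rec.parent1_summary.richness,
                    "r_B": rec.parent2_summary.richness,
                    "stable": rec.stable,
                    "converged": rec.converged,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Protocol 3: serial coalescence (repeated invasion)
# ---------------------------------------------------------------------------


def serial_coalescence(
    base_spec: SamplingSpec,
    l_R: float,
    l_I: float,
    n_events: int,
    replicates: int,
    rng: np.random.Generator,
    env: Environment,
    controls: AssemblyControls | None = None,
    k_grid: tuple[float, ...] = (0.0, 0.5, 0.9),
    resident_k: float | None = 0.5,
    track_w_max: int = 5,
) -> pd.DataFrame:
    """Track a resident community through repeated whole-community invasions.

    Each event samples and assembles a fresh invader (independent metabolic
    matrix and competition/facilitation factors drawn from ``k_grid``) at
    leakage ``l_I``, coalesces it with the resident, and promotes the
    survivors to the new resident.  Residents start from structure factors
    ``resident_k`` (pass ``None`` to draw them from ``k_grid`` instead, like
    invaders); a fixed starting structure keeps the replicate trajectories
    comparable.  Event 0 records the resident as first assembled.  Per event the resident's competition, facilitation, mean
    maintenance cost, mean equilibrium resource concentration, richness, the
    cumulative number of successful invasions (invader-origin survivors) and
    the abundance fractions of the 1..``track_w_max`` preference groups are
    recorded.
    """
    if n_events < 1:
        raise ValueError("need at least one coalescence event")
    from dataclasses import replace

    rows = []
    for rep in range(replicates):
        seed_r = int(rng.integers(0, 2**31 - 1))
        kc = float(rng.choice(k_grid)) if resident_k is None else float(resident_k)
        spec_r = replace(base_spec, leakage=l_R, k_c=kc, k_f=kc, seed=seed_r,
                         shared_metabolism=False)
        resident = integrate_to_steady_state(build_community(spec_r), env, controls)
        if not resident.converged or resident.richness == 0:
            logger.warning("serial replicate %d: resident assembly failed; skipping", rep)
            continue
        cumulative_invasions = 0
        rows.append(_serial_row(rep, 0, resident, cumulative_invasions, track_w_max))
        for event in range(1, n_events + 1):
            seed_i = int(rng.integers(0, 2**31 - 1))
            kc_i = float(rng.choice(k_grid))
            spec_i = replace(base_spec, leakage=l_I, k_c=kc_i, k_f=kc_i, seed=seed_i,
                             shared_metabolism=False)
            invader = integrate_to_steady_state(build_community(spec_i), env, controls)
            if not invader.converged or invader.richness == 0:
                logger.warning("serial replicate %d event %d: invader failed; skipping event", rep, event)
                rows.append(_serial_row(rep, event, resident, cumulative_invasions, track_w_max))
                continue
            invader_labels = set(invader.community.origins)
            post, _ = mix(resident, invader, env, controls)
            new_invasions = sum(
                1
                for i in np.flatnonzero(post.community.abundances > 0)
                if post.community.origins[i] in invader_labels
            )
            cumulative_invasions += new_invasions
            resident = post
            rows.append(_serial_row(rep, event, resident, cumulative_invasions, track_w_max))
    return pd.DataFrame(rows)


def _serial_row(
    rep: int, event: int, resident: AssemblyResult, cumulative_invasions: int, track_w_max: int
) -> dict:
    community = resident.community
    summary = summarize_interactions(community)
    npref = community.prefs.sum(axis=1).astype(int)
    total = community.abundances.sum()
    row = {
        "replicate": rep,
        "event": event,
        "richness": summary.richness,
        "competition": summary.competition,
        "facilitation": summary.facilitation,
        "net_competition": summary.net_competition,
        "mean_cost": float(community.cost.mean()),
        "mean_R_star": float(resident.R_star.mean()),
        "R_tot_star": resident.R_tot_star,
        "cumulative_invasions": cumulative_invasions,
        "stable": resident.stable,
    }
    for mr in range(1, track_w_max + 1):
        sel = npref == mr
        row[f"w_{mr}"] = float(community.abundances[sel].sum() / total) if total > 0 else 0.0
    return row
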