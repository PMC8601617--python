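"""Community-level interaction and composition statistics.

Pairwise competition between consumers α and β is the niche overlap
``c_α · c_β`` (number of shared resource preferences); pairwise facilitation
α → β is ``l_α c_αᵀ D_α c_β``, the fraction of α's secretions that β can
consume per unit resource abundance.  Community-level values C and F average
these over ordered pairs of distinct species; self-pairs are excluded since
coalescence outcomes are reasoned about through interactions *between*
species.  ``C − F`` is the community's net competition (its negative, the
community's cohesion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Community


@dataclass
class InteractionSummary:
    competition: float
    facilitation: float
    richness: int

    @property
    def net_competition(self) -> float:
        return self.competition - self.facilitation


@dataclass
class CompositionSpectrum:
    """Per-preference-group composition change and abundance share.

    ``delta[i]`` is the richness-normalized change in the proportion of
    species with ``m_r[i]`` preferences between the pre-assembly pool and
    the surviving community, scaled by ``1/p(m_r)``; ``w[i]`` is the group's
    share of total surviving biomass.
    """

    m_r: np.ndarray
    T_before: np.ndarray
    T_after: np.ndarray
    delta: np.ndarray
    w: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m_r": self.m_r,
                "T_before": self.T_before,
                "T_after": self.T_after,
                "delta": self.delta,
                "w": self.w,
            }
        )


def community_competition(C_matrix: np.ndarray) -> float:
    """Mean niche overlap ``c_α · c_β`` over ordered distinct species pairs."""
    C_matrix = np.atleast_2d(np.asarray(C_matrix, dtype=float))
    s = C_matrix.shape[0]
    if s <= 1:
        return 0.0
    G = C_matrix @ C_matrix.T
    return float((G.sum() - np.trace(G)) / (s * (s - 1)))


def community_facilitation(community: Community) -> float:
    """Mean cross-feeding flow ``l_α c_αᵀ D_α c_β`` over ordered distinct pairs."""
    s = community.s
    if s <= 1:
        return 0.0
    C = community.prefs
    if community.shared_metabolism:
        P = community.leakage[:, None] * (C @ community.D)
    else:
        P = community.leakage[:, None] * np.einsum("sk,skj->sj", C, community.D)
    Fmat = P @ C.T  # Fmat[α, β] = l_α c_αᵀ D_α c_β
    return float((Fmat.sum() - np.trace(Fmat)) / (s * (s - 1)))


def summarize_interactions(community: Community, surviving_only: bool = True) -> InteractionSummary:
    """C, F and richness of a community (by default its surviving species)."""
    if surviving_only:
        alive = np.flatnonzero(community.abundances > 0)
        community = community.subset(alive) if alive.size < community.s else community
    return InteractionSummary(
        competition=community_competition(community.prefs),
        facilitation=community_facilitation(community),
        richness=community.richness,
    )


def composition_spectrum(
    before: Community,
    after: Community,
    p_mr: np.ndarray,
    warn_zero_p: bool = True,
) -> CompositionSpectrum:
    """Change in the m-preferences composition through assembly.

    ``p_mr[i]`` is the sampling probability of ``m_r = i + 1`` preferences;
    groups with zero sampling probability are excluded (their proportions
    carry too much uncertainty to normalize).
    """
    p_mr = np.asarray(p_mr, dtype=float)
    m = before.m
    npref_before = before.prefs.sum(axis=1).astype(int)
    alive = np.flatnonzero(after.abundances > 0)
    npref_after = after.prefs.sum(axis=1).astype(int)[alive]
    n_after = after.abundances[alive]

    r0 = npref_before.size
    r = npref_after.size
    if r0 == 0 or r == 0:
        raise ValueError("composition spectrum undefined for empty communities")

    mr_values = np.arange(1, m + 1)
    T0 = np.bincount(npref_before, minlength=m + 1)[1:]
    T = np.bincount(npref_after, minlength=m + 1)[1:]
    biomass = np.zeros(m)
    np.add.at(biomass, npref_after - 1, n_after)

    supported = p_mr[: m] > 0
    observed = (T0 > 0) | (T > 0)
    keep = supported & observed
    dropped = observed & ~supported
    if warn_zero_p and np.any(dropped):
        import logging

        logging.getLogger("commcoal").warning(
            "excluding m_r groups with zero sampling probability: %s",
            mr_values[dropped].tolist(),
        )
    delta = (T[keep] / r - T0[keep] / r0) / p_mr[: m][keep]
    w = biomass[keep] / n_after.sum()
    return CompositionSpectrum(
        m_r=mr_values[keep],
        T_before=T0[keep],
        T_after=T[keep],
        delta=delta,
        w=w,
    )
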