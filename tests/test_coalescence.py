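"""Coalescence protocols and the dominance index."""

import numpy as np
import pandas as pd
import pytest

import commcoal as cc


def labeled_community(n, m, label, cost=0.1, leakage=0.0):
    """n distinct specialists on the first n of m resources."""
    prefs = np.zeros((n, m))
    for i in range(n):
        prefs[i, i % m] = 1
    return cc.Community(
        prefs=prefs, D=np.full((m, m), 1.0 / m),
        leakage=np.full(n, leakage), cost=np.full(n, cost),
        growth=np.ones(n), eps=np.zeros(n), abundances=np.ones(n),
        origins=[(label, i) for i in range(n)],
    )


def brute_force_similarity(post, p1, p2):
    pooled = list(p1.origins) + list(p2.origins)
    alive = {post.origins[i] for i in np.flatnonzero(post.abundances > 0)}
    pf = np.array([lab in alive for lab in pooled], dtype=float)
    v1 = np.array([lab in set(p1.origins) for lab in pooled], dtype=float)
    v2 = np.array([lab in set(p2.origins) for lab in pooled], dtype=float)
    r1, r2 = v1.sum(), v2.sum()
    return float(pf @ (v2 / r2 - v1 / r1))


class TestSimilarity:
    def test_post_identical_to_parent1(self):
        p1 = labeled_community(3, 6, "one")
        p2 = labeled_community(2, 6, "two")
        assert cc.similarity(p1, p1, p2) == pytest.approx(-1.0)

    def test_post_identical_to_parent2(self):
        p1 = labeled_community(3, 6, "one")
        p2 = labeled_community(2, 6, "two")
        assert cc.similarity(p2, p1, p2) == pytest.approx(1.0)

    def test_partial_overlap_worked_case(self):
        """r1=4, r2=2; post keeps 2 of parent1 and 1 of parent2 → S = 0."""
        p1 = labeled_community(4, 8, "one")
        p2 = labeled_community(2, 8, "two")
        post = cc.Community.concatenate(p1.subset(np.array([0, 1])), p2.subset(np.array([0])))
        assert cc.similarity(post, p1, p2) == pytest.approx(1 * (1 / 2) - 1 * (2 / 4))

    def test_empty_parent_is_an_error(self):
        p1 = labeled_community(3, 6, "one")
        empty = p1.subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty parent"):
            cc.similarity(p1, p1, empty)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_presence_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p1 = labeled_community(5, 10, f"a{seed}")
        p2 = labeled_community(4, 10, f"b{seed}")
        pool = cc.Community.concatenate(p1, p2)
        keep = np.flatnonzero(rng.random(9) < 0.6)
        if keep.size == 0:
            keep = np.array([0])
        post = pool.subset(keep)
        assert cc.similarity(post, p1, p2) == pytest.approx(
            brute_force_similarity(post, p1, p2)
        )

    def test_extreme_values_iff_exact_parent_sets(self, rng):
        p1 = labeled_community(4, 8, "x")
        p2 = labeled_community(3, 8, "y")
        pool = cc.Community.concatenate(p1, p2)
        for _ in range(20):
            keep = np.flatnonzero(rng.random(7) < 0.5)
            if keep.size == 0:
                continue
            post = pool.subset(keep)
            S = cc.similarity(post, p1, p2)
            is_p1 = set(post.origins) == set(p1.origins)
            is_p2 = set(post.origins) == set(p2.origins)
            assert (abs(S) == pytest.approx(1.0)) == (is_p1 or is_p2)


class TestMix:
    def _assembled(self, spec, env):
        return cc.integrate_to_steady_state(cc.build_community(spec), env)

    def test_single_resource_toy_competitive_exclusion(self):
        """Parent 1's specialist is cheaper, so it wins outright: S = −1."""
        env = cc.Environment.table_defaults(1)
        p1 = labeled_community(1, 1, "cheap", cost=0.08)
        p2 = labeled_community(1, 1, "dear", cost=0.12)
        a1 = cc.integrate_to_steady_state(p1, env)
        a2 = cc.integrate_to_steady_state(p2, env)
        post, rec = cc.mix(a1, a2, env)
        assert rec.S == pytest.approx(-1.0)
        assert post.community.origins == [("cheap", 0)]

    def test_mix_with_empty_parent_is_degenerate(self):
        env = cc.Environment.table_defaults(2)
        p1 = labeled_community(2, 2, "solo", cost=0.1)
        a1 = cc.integrate_to_steady_state(p1, env)
        empty = cc.integrate_to_steady_state(
            p1.subset(np.array([], dtype=int)), env
        )
        post, rec = cc.mix(a1, empty, env)
        assert rec.S == -1.0
        assert set(post.community.origins) == set(a1.community.origins)

    def test_self_mix_of_identical_copy_is_neutral(self):
        """Mixing a community with a relabeled copy gives S = 0 by symmetry."""
        env = cc.Environment.table_defaults(6)
        spec = cc.SamplingSpec(s=6, m=6, k_f=0.5, leakage=0.3, seed=77)
        com = cc.build_community(spec)
        copy = cc.Community(
            prefs=com.prefs.copy(), D=com.D.copy(), leakage=com.leakage.copy(),
            cost=com.cost.copy(), growth=com.growth.copy(), eps=com.eps.copy(),
            abundances=com.abundances.copy(),
            origins=[("copy", i) for i in range(com.s)],
        )
        a = cc.integrate_to_steady_state(com, env)
        b = cc.integrate_to_steady_state(copy, env)
        _, rec = cc.mix(a, b, env)
        assert rec.S == pytest.approx(0.0, abs=1e-12)

    def test_swapping_parents_negates_S(self):
        env = cc.Environment.table_defaults(10)
        a = self._assembled(cc.SamplingSpec(s=10, m=10, k_c=0.0, k_f=0.0, leakage=0.2, seed=1), env)
        b = self._assembled(cc.SamplingSpec(s=10, m=10, k_c=0.9, k_f=0.9, leakage=0.2, seed=2), env)
        _, rec_ab = cc.mix(a, b, env)
        _, rec_ba = cc.mix(b, a, env)
        assert rec_ab.S == pytest.approx(-rec_ba.S)

    def test_post_coalescence_equilibria_are_certified(self):
        env = cc.Environment.table_defaults(10)
        a = self._assembled(cc.SamplingSpec(s=10, m=10, k_c=0.5, k_f=0.5, leakage=0.5, seed=5), env)
        b = self._assembled(cc.SamplingSpec(s=10, m=10, k_c=0.0, k_f=0.0, leakage=0.5, seed=6), env)
        post, rec = cc.mix(a, b, env)
        assert post.converged and rec.stable


@pytest.fixture(scope="module")
def small_pool():
    env = cc.Environment.table_defaults(10)
    specs = [
        cc.SamplingSpec(s=10, m=10, k_c=k, k_f=k, leakage=0.2, seed=i)
        for i, k in enumerate([0.0, 0.5, 0.9] * 2)
    ]
    pool, _ = cc.assemble_batch(specs, env)
    return env, [r for r in pool if r is not None and r.richness > 0]


class TestRandomProtocol:
    def test_distinct_parents_and_bin_bookkeeping(self, small_pool, rng):
        env, pool = small_pool
        records, curve = cc.random_coalescence(pool, 30, rng, env)
        assert (records["parent1"] != records["parent2"]).all()
        assert len(curve) <= 20
        assert curve["n"].sum() == 30

    def test_sparse_bins_flagged_not_plotted(self, rng):
        x = np.concatenate([np.zeros(10), [100.0]])
        y = np.concatenate([np.linspace(-1, 1, 10), [0.5]])
        curve = cc.bin_dominance_curve(x, y, n_bins=20, min_count=5)
        assert not curve.loc[curve["n"] < 5, "plotted"].any()

    def test_pool_of_one_is_an_error(self, small_pool, rng):
        env, pool = small_pool
        with pytest.raises(ValueError, match="at least two"):
            cc.random_coalescence(pool[:1], 5, rng, env)


class TestRecursiveProtocol:
    def test_competition_of_B_constant_along_leakage_ramp(self, rng):
        env = cc.Environment.table_defaults(10)
        spec = cc.SamplingSpec(s=10, m=10, k_c=0.5, k_f=0.5)
        df = cc.recursive_coalescence(
            spec, l_A=0.5, l_B_grid=np.array([0.1, 0.5, 0.9]),
            replicates=2, rng=rng, env=env,
        )
        for _, grp in df.groupby("replicate"):
            # draw-level competition depends only on C, hence not on l
            assert grp["C_B_draw"].nunique() == 1
            assert grp["F_B_draw"].is_monotonic_increasing

    def test_decreasing_grid_rejected(self, rng):
        env = cc.Environment.table_defaults(4)
        spec = cc.SamplingSpec(s=4, m=4)
        with pytest.raises(ValueError, match="increasing"):
            cc.recursive_coalescence(spec, 0.5, np.array([0.9, 0.1]), 1, rng, env)


class TestSerialProtocol:
    def test_invasion_counter_nondecreasing_and_events_indexed(self, rng):
        env = cc.Environment.table_defaults(8)
        spec = cc.SamplingSpec(s=8, m=8)
        df = cc.serial_coalescence(
            spec, l_R=0.5, l_I=0.5, n_events=3, replicates=2, rng=rng, env=env
        )
        for _, grp in df.groupby("replicate"):
            assert list(grp["event"]) == [0, 1, 2, 3]
            assert grp["cumulative_invasions"].is_monotonic_increasing
            assert (grp["richness"] >= 1).all()
        w_cols = [c for c in df.columns if c.startswith("w_")]
        assert len(w_cols) == 5
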