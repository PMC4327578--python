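"""Direct-method primitives: propensities, tau, selection, firing, trajectories."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssabatch import (
    ModelSpec,
    ReactionSpec,
    RNGStream,
    SimState,
    crs_from_model,
    dense_from_model,
    fire_reaction,
    propensity,
    reaction_time,
    run_trajectory,
    select_reaction,
    total_propensity,
)
from ssabatch.direct import propensity_vector

from conftest import random_valid_model


class TestPropensity:
    def test_unimolecular_at_benchmark_state(self, decay_model):
        counts = np.array([10_000, 0, 0])
        assert propensity(decay_model.reactions[0], counts) == 10_000.0

    def test_homodimer_single_molecule_has_no_pair(self, decay_model):
        assert propensity(decay_model.reactions[1], np.array([1, 0, 0])) == 0.0

    @pytest.mark.parametrize("x", [2, 3, 7, 10_000])
    def test_homodimer_counts_distinct_pairs(self, x):
        r = ReactionSpec("dim", 0.002, reactants=((0, 2),))
        a = propensity(r, np.array([x]))
        if x <= 10:  # brute-force pair enumeration oracle
            pairs = len(list(itertools.combinations(range(x), 2)))
            assert a == pytest.approx(0.002 * pairs)
        assert a == pytest.approx(0.002 * x * (x - 1) / 2)

    def test_non_combinatorial_switch(self):
        r = ReactionSpec("dim", 0.5, reactants=((0, 2),))
        assert propensity(r, np.array([4]), combinatorial=False) == 0.5 * 16

    def test_heterodimer_and_zeroth_order(self):
        het = ReactionSpec("het", 2.0, reactants=((0, 1), (1, 1)))
        assert propensity(het, np.array([3, 5])) == 30.0
        z = ReactionSpec("z", 7.5)
        assert propensity(z, np.array([0, 0])) == 7.5

    def test_total_propensity_examples(self):
        assert total_propensity([10_000.0, 99_990.0, 0.0, 0.0]) == 109_990.0
        assert total_propensity([]) == 0.0
        assert total_propensity([3.25]) == 3.25


class TestReactionTime:
    def test_r1_one_gives_zero_tau(self):
        assert reaction_time(5.0, 1.0) == 0.0

    def test_closed_form(self):
        assert reaction_time(1.0, math.exp(-1)) == pytest.approx(1.0)

    def test_absorbing_state_rejected(self):
        with pytest.raises(ValueError):
            reaction_time(0.0, 0.5)


class TestSelectReaction:
    def test_single_live_channel(self):
        for r2 in (1e-9, 0.5, 1.0):
            assert select_reaction([0.0, 5.0, 0.0], r2) == 1

    def test_boundary_is_inclusive_above(self):
        # r2*a_total == 1 == cumulative sum at index 0: the <= side selects 0
        assert select_reaction([1.0, 1.0], 0.5) == 0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            select_reaction([0.0, 0.0], 0.5)

    @given(
        st.lists(st.floats(0.0, 10.0), min_size=1, max_size=8).filter(
            lambda a: sum(a) > 0
        ),
        st.floats(1e-12, 1.0),
    )
    def test_double_inequality_holds(self, a, r2):
        m = select_reaction(a, r2)
        a_total = total_propensity(a)
        below = sum(a[:m])
        assert below < r2 * a_total or math.isclose(below, r2 * a_total)
        assert r2 * a_total <= sum(a[: m + 1]) or m == max(
            i for i, x in enumerate(a) if x > 0
        )


class TestFireReaction:
    def test_dimerization_update(self, decay_model, decay_crs):
        state = SimState(np.array([10_000, 0, 0]))
        out = fire_reaction(state, decay_crs, 1, 0.25)
        assert out.counts.tolist() == [9_998, 1, 0]
        assert out.t == 0.25 and out.step == 1

    def test_zero_net_change_row_advances_time_only(self):
        m = ModelSpec(
            ("A",),
            (5,),
            (ReactionSpec("idle", 1.0, reactants=((0, 1),), products=((0, 1),)),),
        )
        crs = crs_from_model(m)
        out = fire_reaction(SimState(np.array([5])), crs, 0, 0.1)
        assert out.counts.tolist() == [5] and out.step == 1 and out.t == 0.1

    def test_negative_count_is_invariant_violation(self, decay_model, decay_crs):
        with pytest.raises(RuntimeError, match="negative"):
            fire_reaction(SimState(np.array([0, 0, 0])), decay_crs, 0, 0.1)

    @pytest.mark.parametrize("model_seed", [0, 1, 2, 3])
    def test_crs_update_matches_dense_oracle(self, model_seed):
        rng = np.random.default_rng(model_seed)
        model = random_valid_model(rng)
        dense = dense_from_model(model).matrix
        crs = crs_from_model(model)
        counts = np.array(model.initial_counts) + 10  # headroom so nothing absorbs
        state = SimState(counts.copy())
        for _ in range(50):
            j = int(rng.integers(0, model.n))
            ref = state.counts + dense[:, j]
            if (ref < 0).any():
                continue
            state = fire_reaction(state, crs, j, 0.0)
            assert np.array_equal(state.counts, ref)


class TestRNGStream:
    def test_uniforms_in_half_open_unit_interval(self):
        u = RNGStream(1, 0).uniforms(10_000)
        assert (u > 0).all() and (u <= 1).all()

    def test_same_key_reproduces_stream(self):
        assert np.array_equal(RNGStream(3, 5).uniforms(100), RNGStream(3, 5).uniforms(100))

    def test_distinct_streams_are_uncorrelated(self):
        a = RNGStream(3, 0).uniforms(20_000)
        b = RNGStream(3, 1).uniforms(20_000)
        assert not np.array_equal(a[:100], b[:100])
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.02


class TestRunTrajectory:
    def test_benchmark_step_budget(self, decay_model):
        tc = run_trajectory(decay_model, seed=0, max_steps=11_000)
        assert tc.steps[-1] == 11_000 and tc.n_records == 11_001
        assert not tc.absorbed
        assert (tc.counts >= 0).all()
        assert (np.diff(tc.times) >= 0).all()
        assert (np.diff(tc.steps) == 1).all()

    def test_empty_system_absorbs_immediately(self):
        m = ModelSpec(
            ("A",), (0,), (ReactionSpec("decay", 1.0, reactants=((0, 1),)),)
        )
        tc = run_trajectory(m, seed=0, max_steps=100)
        assert tc.absorbed and tc.n_records == 1 and tc.steps[0] == 0

    def test_bitwise_determinism(self, decay_model):
        a = run_trajectory(decay_model, seed=9, stream=2, max_steps=500)
        b = run_trajectory(decay_model, seed=9, stream=2, max_steps=500)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.times, b.times)

    def test_max_time_stop_overshoots_then_stops(self, decay_model):
        tc = run_trajectory(decay_model, seed=0, max_time=0.01)
        assert tc.times[-1] >= 0.01 and tc.times[-2] < 0.01

    def test_cadence_subsamples_every_kth_step(self, decay_model):
        full = run_trajectory(decay_model, seed=4, max_steps=200, cadence=1)
        sub = run_trajectory(decay_model, seed=4, max_steps=200, cadence=10)
        assert sub.steps.tolist() == list(range(0, 201, 10))
        keep = np.isin(full.steps, sub.steps)
        assert np.array_equal(full.counts[keep], sub.counts)

    def test_loop_matches_stepwise_ops_and_uses_two_uniforms_per_step(
        self, decay_model, decay_crs
    ):
        """The fused loop must equal the documented step 2-7 composition."""
        n_steps = 200
        tc = run_trajectory(decay_model, seed=11, max_steps=n_steps)
        rng = RNGStream(11, 0)
        state = SimState(np.array(decay_model.initial_counts))
        for k in range(n_steps):
            a = propensity_vector(decay_model, state.counts)
            a_total = total_propensity(a)
            r1, r2 = rng.uniform(), rng.uniform()
            tau = reaction_time(a_total, r1)
            m = select_reaction(list(a), r2, a_total)
            state = fire_reaction(state, decay_crs, m, tau)
            assert np.array_equal(state.counts, tc.counts[k + 1])
            assert state.t == pytest.approx(tc.times[k + 1], rel=1e-12)

    def test_decay_dimer_conservation_per_step(self, decay_model):
        """Q = S1 + 2 S2 + 2 S3 drops by 1 exactly on S1-decay firings."""
        tc = run_trajectory(decay_model, seed=2, max_steps=2_000)
        q = tc.counts @ np.array([1, 2, 2])
        drops = -np.diff(q)
        assert set(np.unique(drops)) <= {0, 1}
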