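"""Update rules, stepping, termination, and the mean-field oracle."""

import numpy as np
import pytest

from disinfosim import (
    Agent,
    GraphSpec,
    ModelConfig,
    Opinion,
    SimState,
    assign_weights,
    build_graph,
    choose_shared_opinion,
    densities,
    interact,
    meanfield_critical_point,
    meanfield_fixed_point,
    run,
    run_python,
    sample_commitment,
    select_committed,
    step,
)

A, B, AB = Opinion.A, Opinion.B, Opinion.AB
BASE = ModelConfig()


def _freq(outcomes, value):
    return sum(o == value for o in outcomes) / len(outcomes)


class TestChooseSharedOpinion:
    @pytest.mark.parametrize("opinion", [A, B])
    def test_single_opinion_speakers_are_deterministic(self, opinion):
        rng = np.random.RandomState(0)
        agent = Agent(opinion)
        assert all(
            choose_shared_opinion(agent, BASE, rng) == opinion for _ in range(20)
        )

    @pytest.mark.parametrize("beta, p_b", [(0.0, 0.5), (0.1, 0.55)])
    def test_mixed_speaker_voicing_bias(self, beta, p_b):
        # P(B) - P(A) = beta with P(A) + P(B) = 1 forces P(B) = (1 + beta)/2
        rng = np.random.RandomState(1)
        cfg = ModelConfig(attention_beta=beta)
        n = 40_000
        voiced = [choose_shared_opinion(Agent(AB), cfg, rng) for _ in range(n)]
        sigma = np.sqrt(p_b * (1 - p_b) / n)
        assert _freq(voiced, B) == pytest.approx(p_b, abs=3 * sigma)


# Table of base-model update rules: (speaker, voiced, listener) -> (speaker', listener')
BASE_RULES = {
    (A, A, A): (A, A),
    (A, A, B): (A, AB),
    (A, A, AB): (A, A),
    (B, B, A): (B, AB),
    (B, B, B): (B, B),
    (B, B, AB): (B, B),
    (AB, A, A): (A, A),
    (AB, A, B): (AB, AB),
    (AB, A, AB): (A, A),
    (AB, B, A): (AB, AB),
    (AB, B, B): (B, B),
    (AB, B, AB): (B, B),
}


class TestInteract:
    @pytest.mark.parametrize("key", sorted(BASE_RULES, key=str))
    def test_base_model_row(self, key):
        s_op, voiced, l_op = key
        rng = np.random.RandomState(0)
        s, l = interact(Agent(s_op), Agent(l_op), voiced, BASE, rng)
        assert (s.opinion, l.opinion) == BASE_RULES[key]
        assert s.committed_to is None and l.committed_to is None

    def test_closure_over_all_valid_inputs(self):
        # every valid (speaker, listener, voiced) combination, committed or
        # not, maps to a valid pair of agent states
        rng = np.random.RandomState(3)
        speakers = [Agent(A), Agent(B), Agent(AB), Agent(A, A), Agent(B, B),
                    Agent(A, A, 0.7)]
        listeners = speakers + [Agent(B, B, 1.0)]
        for cfg in (BASE, ModelConfig(attention_beta=0.1)):
            for sp in speakers:
                for li in listeners:
                    for voiced in (A, B):
                        if sp.opinion != AB and sp.opinion != voiced:
                            continue
                        s2, l2 = interact(sp, li, voiced, cfg, rng)
                        for agent in (s2, l2):
                            assert agent.opinion in (A, B, AB)
                            if agent.committed_to is not None:
                                assert agent.opinion == agent.committed_to

    def test_fully_committed_listener_never_changes(self):
        rng = np.random.RandomState(4)
        committed = Agent(A, A)
        for _ in range(200):
            _, l2 = interact(Agent(B), committed, B, BASE, rng)
            assert l2 == committed

    def test_committed_speaker_side_never_gated(self):
        rng = np.random.RandomState(5)
        s2, l2 = interact(Agent(A, A), Agent(B), A, BASE, rng)
        assert s2 == Agent(A, A) and l2.opinion == AB

    def test_partially_committed_switch_frequency(self):
        # a c = 0.6 committed-A listener hearing B decommits with prob 0.4
        rng = np.random.RandomState(6)
        n = 40_000
        outcomes = [
            interact(Agent(B), Agent(A, A, 0.6), B, BASE, rng)[1] for _ in range(n)
        ]
        switched = [o for o in outcomes if o.committed_to is None]
        assert all(o.opinion == AB and o.c == 1.0 for o in switched)
        sigma = np.sqrt(0.4 * 0.6 / n)
        assert len(switched) / n == pytest.approx(0.4, abs=3 * sigma)

    def test_partially_committed_ignores_same_opinion(self):
        rng = np.random.RandomState(7)
        for _ in range(100):
            _, l2 = interact(Agent(A), Agent(A, A, 0.55), A, BASE, rng)
            assert l2 == Agent(A, A, 0.55)

    def test_attention_gates_b_listener_only(self):
        cfg = ModelConfig(attention_beta=0.1)
        rng = np.random.RandomState(8)
        n = 40_000
        stays = sum(
            interact(Agent(A), Agent(B), A, cfg, rng)[1].opinion == B
            for _ in range(n)
        )
        sigma = np.sqrt(0.1 * 0.9 / n)
        assert stays / n == pytest.approx(0.1, abs=3 * sigma)
        # AB listeners hearing A are not gated
        for _ in range(50):
            assert interact(Agent(A), Agent(AB), A, cfg, rng)[1].opinion == A

    def test_inconsistent_voiced_opinion_asserts(self):
        with pytest.raises(AssertionError):
            interact(Agent(A), Agent(B), B, BASE, np.random.RandomState(0))


class TestStepAndRun:
    def test_all_b_is_absorbing(self, k400):
        state = SimState.initial(k400)
        assert step(state, BASE, np.random.RandomState(0)) is False

    def test_all_committed_a_is_absorbing(self, path3):
        state = SimState.initial(path3, committed_a=range(3))
        assert step(state, BASE, np.random.RandomState(0)) is False

    def test_run_without_committed_terminates_immediately(self, path3):
        res = run(SimState.initial(path3), BASE, seed=1)
        assert res == type(res)(0.0, 1.0, 0.0, 1, "consensus")

    def test_run_all_committed(self, path3):
        res = run(SimState.initial(path3, committed_a=range(3)), BASE, seed=1)
        assert res.n_A == 1.0 and res.steps == 1 and res.terminated_by == "consensus"

    def test_densities_arithmetic(self, k400):
        state = SimState.initial(assign_weights_path10())
        state.opinion[:4] = A
        state.opinion[9] = AB
        assert densities(state) == pytest.approx((0.4, 0.5, 0.1))

    def test_densities_all_committed(self, path3):
        state = SimState.initial(path3, committed_a=range(3))
        assert densities(state) == (1.0, 0.0, 0.0)

    def test_committed_count_conserved_in_base_model(self, k400):
        rng = np.random.default_rng(11)
        ca = select_committed(k400.n, 0.12, rng)
        state = SimState.initial(k400, ca)
        run(state, BASE, seed=5)
        assert np.count_nonzero(state.committed == 1) == ca.size
        assert np.all(state.opinion[ca] == A)

    def test_seed_determinism(self, k400):
        results = []
        for _ in range(2):
            rng = np.random.default_rng(2)
            state = SimState.initial(k400, select_committed(k400.n, 0.09, rng))
            results.append(run(state, BASE, seed=77))
        assert results[0] == results[1]

    def test_above_tipping_reaches_disinformation_consensus(self, k400):
        # p_a = 0.20 is far above the critical fraction: truth dies out, in
        # agreement with the mean-field fixed point
        rng = np.random.default_rng(3)
        state = SimState.initial(k400, select_committed(k400.n, 0.20, rng))
        res = run(state, BASE, seed=9)
        assert res.n_B == 0.0
        assert meanfield_fixed_point(0.20)[1] == pytest.approx(0.0, abs=1e-9)


def assign_weights_path10():
    import networkx as nx

    from disinfosim import assign_weights

    return assign_weights(nx.path_graph(10))


class TestEngineEquivalence:
    """The compiled kernel and the pure-Python stepper consume the same RNG
    stream, so whole trajectories must agree bitwise."""

    @pytest.mark.parametrize("seed", [0, 1, 123])
    def test_base_model_trajectories_bitwise_equal(self, seed):
        sg = assign_weights(
            build_graph(GraphSpec(family="watts_strogatz", n=40, k=6, p=0.3, seed=2))
        )
        rng = np.random.default_rng(seed)
        ca = select_committed(sg.n, 0.15, rng)
        cfg = ModelConfig(max_steps=150)
        s_fast, s_ref = SimState.initial(sg, ca), SimState.initial(sg, ca)
        r_fast = run(s_fast, cfg, seed=seed)
        r_ref = run_python(s_ref, cfg, seed=seed)
        assert r_fast == r_ref
        assert np.array_equal(s_fast.opinion, s_ref.opinion)

    def test_strategy_gates_trajectories_bitwise_equal(self):
        sg = assign_weights(
            build_graph(GraphSpec(family="erdos_renyi", n=40, p=0.2, seed=4))
        )
        rng = np.random.default_rng(5)
        ca = select_committed(sg.n, 0.2, rng)
        levels = dict(zip(ca.tolist(), sample_commitment(0.5, rng, ca.size).tolist()))
        cfg = ModelConfig(max_steps=150, attention_beta=0.1)
        s_fast = SimState.initial(sg, ca, commitment_levels=levels)
        s_ref = s_fast.copy()
        r_fast = run(s_fast, cfg, seed=6)
        r_ref = run_python(s_ref, cfg, seed=6)
        assert r_fast == r_ref
        assert np.array_equal(s_fast.opinion, s_ref.opinion)
        assert np.array_equal(s_fast.committed, s_ref.committed)
        assert np.array_equal(s_fast.c, s_ref.c)

    def test_unit_commitment_reduces_to_base_model(self, k400):
        # explicit c = 1 for every committed agent is the base model exactly
        rng = np.random.default_rng(8)
        ca = select_committed(k400.n, 0.08, rng)
        cfg = ModelConfig(max_steps=300)
        s_base = SimState.initial(k400, ca)
        s_unit = SimState.initial(k400, ca, commitment_levels={int(i): 1.0 for i in ca})
        r_base = run(s_base, cfg, seed=13)
        r_unit = run(s_unit, cfg, seed=13)
        assert r_base == r_unit
        assert np.array_equal(s_base.opinion, s_unit.opinion)


class TestMeanField:
    def test_no_committed_minority_is_truth_fixed_point(self):
        assert meanfield_fixed_point(0.0) == pytest.approx((0.0, 1.0, 0.0))

    def test_densities_sum_to_one(self):
        for p in (0.02, 0.08, 0.12, 0.3):
            na, nb, nab = meanfield_fixed_point(p)
            assert na + nb + nab == pytest.approx(1.0, abs=1e-9)

    def test_critical_point_location(self):
        # dense scan oracle for the disappearance of the B-dominant branch
        grid = np.arange(0.09, 0.1001, 0.0005)
        scan = next(p for p in grid if meanfield_fixed_point(p)[1] < 0.5)
        pc = meanfield_critical_point(tol=1e-4)
        assert 0.09 < pc < 0.10
        assert pc == pytest.approx(scan, abs=0.001)

    def test_invalid_committed_fraction(self):
        with pytest.raises(ValueError):
            meanfield_fixed_point(1.0)

    @pytest.mark.parametrize("p_a", [0.05, 0.15])
    def test_simulation_agrees_with_mean_field_away_from_criticality(self, k400, p_a):
        nb_mf = meanfield_fixed_point(p_a)[1]
        vals = []
        for rep in range(10):
            rng = np.random.default_rng([rep, int(p_a * 100)])
            state = SimState.initial(k400, select_committed(k400.n, p_a, rng))
            vals.append(run(state, BASE, seed=int(rng.integers(2**31))).n_B)
        assert np.mean(vals) == pytest.approx(nb_mf, abs=0.05)
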