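"""Event-level rules, absorbing-state detection and full runs."""

import numpy as np
import pytest
from scipy import stats

from axelrod_groups import (
    CultureState,
    LatticeTopology,
    ModelConfig,
    attempt_interaction,
    eligible_features,
    init_random,
    interaction_probability,
    is_absorbing,
    is_pair_active,
    run_to_absorption,
    shared_feature_count,
)
from conftest import make_config


def brute_can_change(state, topology, config):
    """Oracle: enumerate every (i, j, feature) event and ask whether any
    possible outcome changes the state."""
    for i in range(state.N):
        for j in topology.neighbors(i):
            vi, vj = state.traits[i], state.traits[int(j)]
            if interaction_probability(vi, vj, config) == 0:
                continue
            if config.mode == "standard":
                candidates = [k for k in range(config.F) if vi[k] != vj[k]]
            elif config.selection_rule == "literal_two_stage":
                candidates = [
                    k for k in range(config.F)
                    if vi[k] != vj[k] and abs(int(vi[k]) - int(vj[k])) <= config.a
                ]
            else:
                candidates = sorted(eligible_features(vi, vj, config))
            if candidates:
                return True
    return False


class TestPairAlgebra:
    def test_shared_feature_count_examples(self):
        assert shared_feature_count([0, 1, 2], [0, 1, 2]) == 3
        assert shared_feature_count([0, 1, 2], [0, 1, 4]) == 2
        with pytest.raises(ValueError):
            shared_feature_count([0, 1], [0, 1, 2])

    def test_shared_count_equals_hamming_complement(self, rng):
        for _ in range(50):
            a = rng.integers(0, 3, 6)
            b = rng.integers(0, 3, 6)
            hamming = sum(1 for x, y in zip(a, b) if x != y)
            assert shared_feature_count(a, b) == 6 - hamming

    def test_eligible_features_modes(self):
        std = make_config()
        assert eligible_features([0, 1, 2], [0, 1, 4], std) == {2}
        thr = make_config(mode="threshold", a=1, F=2)
        assert eligible_features([0, 4], [1, 0], thr) == {0}
        two = thr.replace(selection_rule="literal_two_stage")
        assert eligible_features([0, 4], [1, 0], two) == {0, 1}
        assert eligible_features([2, 2], [2, 2], thr) == set()

    def test_interaction_probability(self):
        std = make_config()
        assert interaction_probability([0, 1, 2], [0, 1, 4], std) == pytest.approx(2 / 3)
        thr = make_config(mode="threshold", a=1, F=4)
        # distances 1,2,3,0 -> features 0 and 3 within threshold
        assert interaction_probability(
            [0, 0, 0, 0], [1, 2, 3, 0], thr
        ) == pytest.approx(2 / 4)

    @pytest.mark.parametrize("trial", range(5))
    def test_max_threshold_probability_is_one(self, rng, trial):
        # a = q - 1: every trait distance is within the threshold
        cfg = make_config(mode="threshold", a=4, F=4)
        vi = rng.integers(0, 5, 4)
        vj = rng.integers(0, 5, 4)
        assert interaction_probability(vi, vj, cfg) == 1.0

    def test_is_pair_active(self):
        std = make_config(F=2, q=5)
        assert not is_pair_active([1, 2], [1, 2], std)
        assert not is_pair_active([0, 0], [1, 1], std)  # zero overlap
        assert is_pair_active([0, 0], [0, 1], std)
        thr = make_config(mode="threshold", a=1, F=2)
        assert not is_pair_active([0, 0], [2, 3], thr)  # all distances >= 2
        assert is_pair_active([0, 0], [2, 1], thr)


class TestInitRandom:
    def test_shape_range_and_determinism(self):
        cfg = ModelConfig(L=2, F=1, q=2, seed=5)
        s1 = init_random(cfg, np.random.default_rng(5))
        s2 = init_random(cfg, np.random.default_rng(5))
        assert s1.traits.shape == (4, 1)
        assert set(np.unique(s1.traits)) <= {0, 1}
        assert s1.step_count == 0
        assert np.array_equal(s1.traits, s2.traits)

    def test_uniform_trait_frequencies(self, rng):
        # pooled per-cell tallies over many re-initialisations vs uniform
        cfg = ModelConfig(L=10, F=3, q=5)
        counts = np.zeros(5)
        for _ in range(200):
            s = init_random(cfg, rng)
            counts += np.bincount(s.traits.ravel(), minlength=5)
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01


class TestAttemptInteraction:
    def test_consensus_state_only_null_events(self, rng, lattice4):
        cfg = make_config()
        state = CultureState(np.full((16, 3), 2), q=5)
        before = state.traits.copy()
        for _ in range(100):
            ev = attempt_interaction(state, lattice4, cfg, rng)
            assert ev.copied_feature is None
        assert np.array_equal(state.traits, before)
        assert state.step_count == 100

    def test_zero_overlap_pair_frozen(self, rng):
        # standard mode, two-agent lattice column with nothing in common
        cfg = ModelConfig(L=2, F=3, q=5)
        topo = LatticeTopology.build(2)
        state = CultureState(
            np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]]), q=5
        )
        before = state.traits.copy()
        for _ in range(200):
            ev = attempt_interaction(state, topo, cfg, rng)
            assert not ev.interacted
        assert np.array_equal(state.traits, before)

    def test_copy_rate_matches_closed_form(self, rng):
        # threshold, F=1, q=5, a=1, neighbors at 2 and 3: p = 1, so the
        # very first event copies and the pair then agrees forever.
        cfg = ModelConfig(L=2, F=1, q=5, mode="threshold", a=1)
        topo = LatticeTopology.build(2)
        copies = 0
        for _ in range(300):
            state = CultureState(np.array([[2], [3], [2], [3]]), q=5)
            ev = attempt_interaction(state, topo, cfg, rng)
            if ev.interacted:
                copies += 1
                assert state.traits[ev.i, 0] == state.traits[ev.j, 0]
            else:  # the drawn pair was already identical (p=1, nothing to copy)
                assert ev.copied_feature is None
        assert copies > 0  # non-identical draws always interact (p = 1)

    def test_locality_one_entry_per_event(self, rng, lattice4):
        cfg = make_config(mode="threshold", a=2)
        state = CultureState(rng.integers(0, 5, (16, 3)), q=5)
        for _ in range(300):
            before = state.traits.copy()
            attempt_interaction(state, lattice4, cfg, rng)
            assert (state.traits != before).sum() <= 1
            assert state.traits.min() >= 0 and state.traits.max() < 5

    def test_literal_two_stage_rejects_out_of_threshold_candidate(self, rng):
        # one feature within threshold, one far outside: the two-stage rule
        # sometimes draws the far one and must then produce a null copy
        cfg = ModelConfig(L=2, F=2, q=5, mode="threshold", a=1,
                          selection_rule="literal_two_stage")
        topo = LatticeTopology.build(2)
        rejected = copied = 0
        for _ in range(400):
            state = CultureState(np.array([[0, 0], [1, 4], [0, 0], [1, 4]]), q=5)
            ev = attempt_interaction(state, topo, cfg, rng)
            if not ev.interacted:
                continue
            if ev.copied_feature is None:
                rejected += 1
                assert np.array_equal(state.traits[ev.i], [0, 0]) or \
                    np.array_equal(state.traits[ev.i], [1, 4])
            else:
                assert ev.copied_feature == 0
                copied += 1
        assert rejected > 0 and copied > 0


class TestAbsorbing:
    def test_consensus_absorbing(self, lattice4):
        state = CultureState(np.full((16, 3), 1), q=5)
        assert is_absorbing(state, lattice4, make_config())

    def test_two_frozen_halves(self):
        # 2x2 lattice, left column culture A, right column culture B,
        # zero shared features: every edge inactive in standard mode
        topo = LatticeTopology.build(2)
        state = CultureState(
            np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]]), q=5
        )
        assert is_absorbing(state, topo, make_config(L=2))

    @pytest.mark.parametrize(
        "mode_kw",
        [
            dict(mode="standard"),
            dict(mode="threshold", a=1),
            dict(mode="threshold", a=2, selection_rule="literal_two_stage"),
        ],
    )
    def test_matches_event_enumeration_oracle(self, rng, lattice4, mode_kw):
        cfg = make_config(q=4, **mode_kw)
        for _ in range(30):
            state = CultureState(rng.integers(0, 4, (16, 3)), q=4)
            assert is_absorbing(state, lattice4, cfg) == (
                not brute_can_change(state, lattice4, cfg)
            )


class TestRunToAbsorption:
    def test_consensus_limit_small(self):
        cfg = ModelConfig(L=3, F=1, q=2, mode="threshold", a=1, seed=42)
        res = run_to_absorption(cfg)
        assert res.absorbed
        assert len(np.unique(res.final_state.traits, axis=0)) == 1

    @pytest.mark.parametrize("engine", ["numba", "python"])
    def test_frozen_limit_a0(self, engine):
        cfg = ModelConfig(L=4, F=3, q=5, mode="threshold", a=0, seed=7)
        res = run_to_absorption(cfg, engine=engine)
        assert res.absorbed
        init = init_random(cfg, np.random.default_rng(7))
        assert np.array_equal(res.final_state.traits, init.traits)

    @pytest.mark.parametrize("engine", ["numba", "python"])
    def test_determinism_and_oracle(self, engine, lattice4):
        cfg = ModelConfig(L=4, F=3, q=3, mode="threshold", a=1, seed=99,
                          max_steps=200_000)
        r1 = run_to_absorption(cfg, engine=engine)
        r2 = run_to_absorption(cfg, engine=engine)
        assert np.array_equal(r1.final_state.traits, r2.final_state.traits)
        assert (r1.steps, r1.absorbed) == (r2.steps, r2.absorbed)
        assert r1.absorbed
        assert not brute_can_change(r1.final_state, lattice4, cfg)

    def test_max_steps_cap_returns_unabsorbed(self):
        cfg = ModelConfig(L=6, F=8, q=5, seed=1, max_steps=50, check_every=50)
        res = run_to_absorption(cfg)
        assert not res.absorbed
        assert res.steps == 50

    def test_explicit_initial_state(self, rng):
        cfg = ModelConfig(L=3, F=2, q=4, mode="threshold", a=3, seed=3)
        init = CultureState(rng.integers(0, 4, (9, 2)), q=4)
        keep = init.traits.copy()
        res = run_to_absorption(cfg, initial_state=init)
        assert np.array_equal(init.traits, keep)  # caller's state untouched
        assert res.absorbed

    def test_run_result_save(self, tmp_path):
        cfg = ModelConfig(L=3, F=2, q=3, seed=11)
        res = run_to_absorption(cfg)
        out = tmp_path / "final.csv"
        res.save(out)
        reloaded = CultureState.from_csv(out)
        assert np.array_equal(reloaded.traits, res.final_state.traits)
        assert reloaded.step_count == res.final_state.step_count
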