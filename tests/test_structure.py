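"""Fast structure learning: uniqueness, renormalization, losslessness, growth."""

import numpy as np
import pytest

from rgm.inference import expand_top
from rgm.model_core import mutual_information, normalize
from rgm.structure import (
    add_label_level,
    coarse_grain,
    fast_structure_learn,
    gate_growth,
    one_hot_likelihoods,
    quad_merge,
    segment_paths,
    unique_state_columns,
    unique_transitions,
)

from conftest import make_obs


class TestUniqueStateColumns:
    def test_basic_order_of_first_appearance(self):
        states, idx = unique_state_columns(np.array([[0, 1], [2, 2], [0, 1]]))
        assert states.shape[0] == 2
        np.testing.assert_array_equal(idx, [0, 1, 0])
        np.testing.assert_array_equal(states[0], [0, 1])

    def test_hashing_oracle_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            codes = rng.integers(0, 3, size=(rng.integers(2, 40), rng.integers(1, 4)))
            states, idx = unique_state_columns(codes)
            assert states.shape[0] == len({tuple(r) for r in codes})
            np.testing.assert_array_equal(states[idx], codes)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            unique_state_columns(np.zeros((0, 2), dtype=int))

    def test_one_hot_likelihoods_columns(self):
        states = np.array([[0, 2], [1, 0]])
        A = one_hot_likelihoods(states, alphabet=[2, 3])
        assert A[0].shape == (2, 2) and A[1].shape == (3, 2)
        assert np.all(A[0].sum(axis=0) == 1) and np.all(A[1].sum(axis=0) == 1)


class TestUniqueTransitions:
    def test_deterministic_cycle_single_permutation_slice(self):
        B = unique_transitions(np.array([0, 1, 2, 0, 1, 2, 0]), 3)
        assert B.shape[2] == 1
        perm = (B[:, :, 0] > 0).astype(int)
        assert np.all(perm.sum(axis=0) == 1) and np.all(perm.sum(axis=1) == 1)

    def test_branching_source_gets_two_slices(self):
        B = unique_transitions(np.array([0, 1, 0, 2]), 3)
        assert B.shape[2] == 2
        assert B[1, 0, 0] > 0 and B[2, 0, 1] > 0

    def test_slices_one_hot_by_column(self):
        rng = np.random.default_rng(12)
        seq = rng.integers(0, 4, size=100)
        B = unique_transitions(seq, 4)
        for u in range(B.shape[2]):
            nonzero = (B[:, :, u] > 0).sum(axis=0)
            assert np.all(nonzero <= 1)

    def test_path_count_equals_max_out_degree(self):
        rng = np.random.default_rng(13)
        seq = rng.integers(0, 3, size=200)
        B = unique_transitions(seq, 3)
        succ = {s: set() for s in range(3)}
        for a, b in zip(seq[:-1], seq[1:]):
            succ[a].add(b)
        assert B.shape[2] == max(len(v) for v in succ.values())


class TestCoarseGrain:
    def test_pairwise_halves_sequence(self):
        codes = np.arange(32).reshape(32, 1) % 4
        new, level = coarse_grain(codes, [[0]], R=2)
        assert new.shape == (16, 1)

    def test_constant_sequence_single_symbol(self):
        new, level = coarse_grain(np.zeros((10, 1), dtype=int), [[0]], R=2)
        assert level.groups[0].n_symbols == 1
        assert np.all(new == 0)

    def test_round_trip_reproduces_indices(self):
        rng = np.random.default_rng(14)
        codes = rng.integers(0, 3, size=(24, 2))
        new, level = coarse_grain(codes, [[0, 1]], R=2)
        grp = level.groups[0]
        # expand: symbol -> R spatial states -> member codes
        rebuilt = grp.spatial_states[grp.segments[new[:, 0]].reshape(-1)]
        np.testing.assert_array_equal(rebuilt, codes)

    def test_trailing_segment_dropped_with_warning(self):
        codes = np.zeros((7, 1), dtype=int)
        with pytest.warns(UserWarning):
            new, _ = coarse_grain(codes, [[0]], R=2)
        assert new.shape[0] == 3

    def test_segment_paths_bijection(self):
        segs = np.array([[0, 1, 2], [0, 2, 1], [1, 0, 2]])
        path_idx, B = segment_paths(segs, 3)
        # same initial state, different continuations -> distinct paths
        assert path_idx[0] != path_idx[1]
        assert B.shape[0] == 3


class TestQuadMerge:
    def test_4x4_to_2x2(self):
        merge, grid = quad_merge((4, 4))
        assert grid == (2, 2) and len(merge) == 4
        assert sorted(c for m in merge for c in m) == list(range(16))

    def test_final_collapse(self):
        merge, grid = quad_merge((1, 1))
        assert merge == [[0]] and grid == (1, 1)


class TestFastStructureLearn:
    def test_lossless_compression(self, periodic_obs, periodic_model):
        regen = expand_top(periodic_model, periodic_model.top.sequence)
        np.testing.assert_array_equal(regen, periodic_obs.codes)

    def test_lossless_on_random_sequences(self):
        rng = np.random.default_rng(15)
        codes = rng.integers(0, 4, size=(32, 3))
        obs = make_obs(codes, alphabet=[4, 4, 4])
        model = fast_structure_learn(obs, [1, 2, 2], merge_schedule=[[[0, 1, 2]], [[0]]])
        np.testing.assert_array_equal(expand_top(model, model.top.sequence), codes)

    def test_top_state_bound(self):
        rng = np.random.default_rng(16)
        codes = rng.integers(0, 2, size=(64, 2))
        obs = make_obs(codes, alphabet=[2, 2])
        model = fast_structure_learn(obs, [1, 2, 2], merge_schedule=[[[0, 1]], [[0]]])
        assert model.top.n_states <= int(np.ceil(64 / model.temporal_factor))

    def test_segment_hash_oracle(self):
        rng = np.random.default_rng(17)
        codes = rng.integers(0, 16, size=(40, 1))
        obs = make_obs(codes, alphabet=[16])
        model = fast_structure_learn(obs, [1, 2], merge_schedule=[[[0]]])
        segs = {tuple(codes[t : t + 2, 0]) for t in range(0, 40, 2)}
        assert model.top.n_states == len(segs)

    def test_deterministic(self, periodic_obs):
        m1 = fast_structure_learn(periodic_obs, [1, 2], merge_schedule=[[[0, 1]]])
        m2 = fast_structure_learn(periodic_obs, [1, 2], merge_schedule=[[[0, 1]]])
        np.testing.assert_array_equal(m1.top.sequence, m2.top.sequence)
        np.testing.assert_array_equal(m1.top.B, m2.top.B)

    def test_single_repeated_frame_one_state_everywhere(self):
        obs = make_obs(np.zeros((8, 2), dtype=int), alphabet=[2, 2])
        model = fast_structure_learn(obs, [1, 2], merge_schedule=[[[0, 1]]])
        assert model.top.n_states == 1
        for lv in model.levels:
            for g in lv.groups:
                assert g.n_symbols == 1

    def test_inconsistent_schedules_raise(self, periodic_obs):
        with pytest.raises(ValueError):
            fast_structure_learn(periodic_obs, [1, 2, 2], merge_schedule=[[[0, 1]]])

    def test_exemplar_mode_requires_R1(self, exemplar_obs):
        with pytest.raises(ValueError):
            fast_structure_learn(exemplar_obs, [1, 2], temporal=False)


class TestLabelLevel:
    def test_mapping_shape(self, exemplar_model):
        labels = np.array([0, 0, 1, 1, 2])
        add_label_level(exemplar_model, labels)
        assert exemplar_model.label.counts.shape == (5, 3)

    def test_single_class_single_state(self, exemplar_model):
        add_label_level(exemplar_model, np.zeros(5, dtype=int))
        assert exemplar_model.label.n_classes == 1

    def test_class_conditional_generation_exhaustive(self, exemplar_obs, exemplar_model):
        labels = np.array([0, 0, 1, 1, 2])
        add_label_level(exemplar_model, labels)
        like = normalize(exemplar_model.label.counts)  # P(state | class)
        for k in range(3):
            states = np.flatnonzero(like[:, k] > 0)
            for s in states:
                codes = expand_top(exemplar_model, np.array([s]))
                # generated exemplar belongs to class k's training set
                rows = exemplar_obs.codes[labels == k]
                assert any(np.array_equal(codes[0], r) for r in rows)

    def test_label_count_mismatch_raises(self, exemplar_model):
        with pytest.raises(ValueError):
            add_label_level(exemplar_model, np.array([0, 1]))


class TestGateGrowth:
    def test_already_explained_rejected(self):
        a = np.eye(3)
        obs = np.array([1.0, 0, 0])
        d = gate_growth(obs, a, obs)
        assert not d.accepted

    def test_orthogonal_observation_accepted(self):
        a = np.array([[1.0, 0], [0, 1.0], [0, 0]])
        obs = np.array([0.0, 0, 1.0])
        d = gate_growth(obs, a, obs)
        assert d.accepted and d.delta_F > 0

    def test_two_state_toy_matches_brute_force(self):
        floor = 1 / 32
        a = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        cand = np.array([0.0, 0.5, 0.5])
        obs = np.array([0.0, 0.5, 0.5])
        d = gate_growth(cand, a, obs, floor=floor)
        # independent evaluation of both terms
        aug = np.concatenate([a, cand[:, None]], axis=1)
        def best_acc(counts):
            p = (counts + floor) / (counts + floor).sum(axis=0, keepdims=True)
            return max(float(obs @ np.log(p[:, j])) for j in range(p.shape[1]))
        dF = best_acc(aug) - best_acc(a)
        dG = mutual_information(aug + floor) - mutual_information(a + floor)
        assert d.delta_F == pytest.approx(dF, abs=1e-9)
        assert d.delta_G == pytest.approx(dG, abs=1e-9)
        assert d.accepted == (dF + dG > 0)

    def test_unnormalized_candidate_rejected(self):
        with pytest.raises(ValueError):
            gate_growth(np.array([2.0, 0.0]), np.eye(2), np.array([1.0, 0.0]))
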