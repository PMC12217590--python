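"""Model inversion: exact marginals, free-energy descent, generation, completion."""

import itertools

import numpy as np
import pytest

from rgm.inference import (
    ObservationStream,
    SingleLevelPOMDP,
    classify,
    complete,
    exact_posterior,
    expand_top,
    generate,
    infer,
    vmp_fixed_point,
)
from rgm.model_core import normalize
from rgm.structure import add_label_level, fast_structure_learn

from conftest import make_obs


def enumerate_posterior(m, obs):
    """Brute-force oracle: sum over every joint (path, s_0..s_T) configuration."""
    T = obs[0].shape[0]
    A = [normalize(a) for a in m.A]
    D, E = normalize(m.D), normalize(m.E)
    n, npth = m.n_states, m.n_paths
    qs = np.zeros((T, n))
    qu = np.zeros(npth)
    Z = 0.0
    for u in range(npth):
        P = normalize(m.B[:, :, u])
        for states in itertools.product(range(n), repeat=T):
            p = E[u] * D[states[0]]
            for t in range(1, T):
                p *= P[states[t], states[t - 1]]
            for t in range(T):
                for g, a in enumerate(A):
                    p *= float(obs[g][t] @ a[:, states[t]])
            Z += p
            qu[u] += p
            for t in range(T):
                qs[t, states[t]] += p
    return qs / Z, qu / Z, -np.log(Z)


def toy_pomdp(seed=0, n=3, npaths=2):
    rng = np.random.default_rng(seed)
    A = [rng.random((4, n)) + 0.2]
    B = rng.random((n, n, npaths)) + 0.2
    D = rng.random(n) + 0.2
    E = rng.random(npaths) + 0.2
    return SingleLevelPOMDP(A=A, B=B, D=D, E=E)


class TestExactPosterior:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_enumeration(self, seed):
        m = toy_pomdp(seed, n=4, npaths=2)
        rng = np.random.default_rng(100 + seed)
        obs = [rng.random((3, 4)) + 0.1]
        obs[0] /= obs[0].sum(axis=1, keepdims=True)
        qs, qu, F = exact_posterior(m, obs)
        qs0, qu0, F0 = enumerate_posterior(m, obs)
        np.testing.assert_allclose(qs, qs0, atol=1e-6)
        np.testing.assert_allclose(qu, qu0, atol=1e-6)
        assert F == pytest.approx(F0, abs=1e-6)

    def test_three_state_chain_example(self):
        m = toy_pomdp(7, n=3, npaths=1)
        obs = [np.eye(4)[:3]]
        qs, _, _ = exact_posterior(m, obs)
        qs0, _, _ = enumerate_posterior(m, obs)
        np.testing.assert_allclose(qs, qs0, atol=1e-6)


class TestVmpFixedPoint:
    def test_free_energy_non_increasing(self):
        for seed in range(5):
            m = toy_pomdp(seed)
            rng = np.random.default_rng(seed)
            obs = [rng.random((4, 4)) + 0.1]
            obs[0] /= obs[0].sum(axis=1, keepdims=True)
            _, _, F = vmp_fixed_point(m, obs, tol=0.0, max_sweeps=16)
            assert np.all(np.diff(F) <= 1e-9)

    def test_precise_likelihood_one_hot_posterior(self):
        A = [np.eye(3) * 100 + 0.5]
        m = SingleLevelPOMDP(A=A, B=np.ones((3, 3, 1)), D=np.ones(3), E=np.ones(1))
        obs = [np.array([[1.0, 0, 0]])]
        qs, _, _ = vmp_fixed_point(m, obs)
        assert qs[0, 0] > 0.99

    def test_uniform_observation_symmetric_posterior(self):
        m = SingleLevelPOMDP(
            A=[np.eye(2) * 10 + 0.5], B=np.ones((2, 2, 1)), D=np.ones(2), E=np.ones(1)
        )
        obs = [np.full((1, 2), 0.5)]
        qs, _, _ = vmp_fixed_point(m, obs)
        np.testing.assert_allclose(qs[0], [0.5, 0.5], atol=1e-9)


class TestHierarchicalInfer:
    def test_elbo_is_minus_log_n_for_exemplars(self, exemplar_obs, exemplar_model):
        # uniform prior over N = 5 distinct exemplars, precise observation
        one = make_obs(exemplar_obs.codes[[2]], alphabet=[2, 2, 2])
        post = infer(exemplar_model, one, floor=0.0)
        assert post.elbo == pytest.approx(-np.log(5), abs=1e-6)

    def test_lossless_recognition(self, periodic_obs, periodic_model):
        post = infer(periodic_model, periodic_obs, floor=0.0)
        np.testing.assert_array_equal(
            np.argmax(post.top, axis=1), periodic_model.top.sequence
        )

    def test_recognition_generation_consistency(self, exemplar_model, exemplar_obs):
        for s in range(exemplar_model.top.n_states):
            gen = generate(exemplar_model, s, horizon=1)
            post = infer(exemplar_model, gen, floor=0.0)
            assert int(np.argmax(post.top[0])) == s

    def test_timescale_separation_counters(self, periodic_model, periodic_obs):
        post = infer(periodic_model, periodic_obs, floor=0.0)
        counts = post.update_counts
        # each level performs exactly R child updates per own update
        for i in range(1, len(counts)):
            assert counts[i] == counts[i - 1] // periodic_model.levels[i - 1].R
        assert post.top.shape[0] == counts[-1] // periodic_model.levels[-1].R

    def test_alphabet_mismatch_raises(self, periodic_model):
        bad = make_obs(np.zeros((4, 2), dtype=int), alphabet=[5, 5])
        with pytest.raises(ValueError):
            infer(periodic_model, bad)

    def test_posteriors_normalized(self, periodic_model, periodic_obs):
        post = infer(periodic_model, periodic_obs, floor=1 / 32)
        np.testing.assert_allclose(post.top.sum(axis=1), 1.0, atol=1e-9)
        for lv in post.level_symbols:
            for q in lv:
                np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-9)


class TestGenerate:
    def test_periodic_orbit_cycles(self, periodic_obs, periodic_model):
        # 8-step cycle -> 4 top events per cycle (R=2); generate 4 cycles
        horizon = 32
        gen = generate(periodic_model, int(periodic_model.top.sequence[0]), horizon)
        np.testing.assert_array_equal(gen.codes, np.tile(periodic_obs.codes[:8], (4, 1)))

    def test_horizon_must_divide(self, periodic_model):
        with pytest.raises(ValueError):
            generate(periodic_model, 0, horizon=3)

    def test_seeded_generation_reproducible(self):
        # branching orbit: two observed successors of state 0
        codes = np.array([[0], [1], [0], [2], [0], [1], [0], [2]])
        obs = make_obs(codes, alphabet=[3])
        model = fast_structure_learn(obs, [1], merge_schedule=None)
        a = generate(model, 0, horizon=8, seed=42)
        b = generate(model, 0, horizon=8, seed=42)
        np.testing.assert_array_equal(a.codes, b.codes)


class TestClassify:
    @pytest.fixture
    def labelled(self, exemplar_obs, exemplar_model):
        add_label_level(exemplar_model, np.array([0, 0, 1, 1, 2]))
        return exemplar_model, exemplar_obs

    def test_training_exemplar_recovers_class(self, labelled):
        # near-precise mappings (tiny floor): each exemplar names its class
        model, obs = labelled
        post, elbo = classify(model, obs, floor=1e-4)
        np.testing.assert_array_equal(np.argmax(post, axis=1), [0, 0, 1, 1, 2])
        assert np.all(post.max(axis=1) > 0.99)

    def test_posterior_rows_sum_to_one(self, labelled):
        model, obs = labelled
        post, _ = classify(model, obs)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_unfamiliar_input_has_low_elbo(self, labelled):
        model, obs = labelled
        _, elbo_train = classify(model, obs)
        noise = make_obs(np.array([[1, 1, 0]]), alphabet=[2, 2, 2])
        _, elbo_noise = classify(model, noise)
        assert elbo_noise[0] < elbo_train.min() - 1.0

    def test_requires_label_level(self, exemplar_model, exemplar_obs):
        exemplar_model.label = None
        with pytest.raises(ValueError):
            classify(exemplar_model, exemplar_obs)


class TestComplete:
    def test_masked_channel_filled_from_periodic_context(
        self, periodic_obs, periodic_model
    ):
        stream = ObservationStream.from_codes(periodic_obs).masked(channels=[1])
        post, codes = complete(periodic_model, stream)
        np.testing.assert_array_equal(codes[4:], periodic_obs.codes[4:])

    def test_fully_observed_matches_training(self, periodic_obs, periodic_model):
        _, codes = complete(periodic_model, periodic_obs)
        np.testing.assert_array_equal(codes, periodic_obs.codes)

    def test_all_missing_returns_prior_predictive(self, periodic_model, periodic_obs):
        stream = ObservationStream.from_codes(periodic_obs).masked()
        post, codes = complete(periodic_model, stream)
        assert codes.shape == periodic_obs.codes.shape  # defined, no error

    def test_ambiguous_prefix_splits_mass(self):
        # two exemplars sharing channel 0; observing only channel 0 is ambiguous
        codes = np.array([[0, 0], [0, 1], [1, 0]])
        obs = make_obs(codes, alphabet=[2, 2])
        model = fast_structure_learn(
            obs, [1, 1], merge_schedule=[[[0, 1]]], temporal=False
        )
        stream = ObservationStream.from_codes(make_obs(codes[[0]], alphabet=[2, 2]))
        partial = stream.masked(channels=[1])
        post = infer(model, partial, floor=1e-6)
        top = post.top[0]
        assert top[0] == pytest.approx(0.5, abs=1e-3)
        assert top[1] == pytest.approx(0.5, abs=1e-3)
        assert top[2] < 1e-2
        # disambiguating evidence resolves the split
        post2 = infer(model, stream, floor=1e-6)
        assert np.argmax(post2.top[0]) == 0 and post2.top[0, 0] > 0.99
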