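"""Elementary operators: normalization, expected logs, MI, serialization."""

import numpy as np
import pytest
from scipy.special import digamma

from rgm.model_core import (
    CountTensor,
    InvalidCountError,
    ModelFormatError,
    dirichlet_log_beta,
    expected_log,
    load_model,
    mutual_information,
    mutual_information_counts,
    normalize,
    save_model,
    softmax,
)
from rgm.structure import fast_structure_learn

from conftest import make_obs


class TestNormalize:
    @pytest.mark.parametrize(
        "col, expected",
        [([2.0, 2.0], [0.5, 0.5]), ([0.0, 0.0], [0.5, 0.5]), ([3.0, 1.0], [0.75, 0.25])],
    )
    def test_columns(self, col, expected):
        np.testing.assert_allclose(normalize(np.array(col)[:, None])[:, 0], expected)

    def test_negative_raises(self):
        with pytest.raises(InvalidCountError):
            normalize(np.array([[-1.0], [2.0]]))

    def test_idempotent_fixed_point(self):
        rng = np.random.default_rng(0)
        a = rng.random((4, 5)) * 10
        once = normalize(a)
        np.testing.assert_allclose(normalize(once), once, atol=1e-12)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(1)
        a = rng.random((3, 4, 2))
        np.testing.assert_allclose(normalize(a).sum(axis=0), 1.0, atol=1e-9)


class TestExpectedLog:
    def test_symmetric_column(self):
        out = expected_log(np.array([[1.0], [1.0]]))
        assert out[0, 0] == pytest.approx(out[1, 0])

    def test_digamma_oracle(self):
        col = np.array([[3.0], [1.0]])
        out = expected_log(col)
        np.testing.assert_allclose(out[:, 0], digamma([3.0, 1.0]) - digamma(4.0))

    def test_large_count_limit_is_log_normalized(self):
        t = 1e6
        out = expected_log(np.array([[t], [t]]))
        np.testing.assert_allclose(out, np.log(0.5), atol=1e-4)

    def test_entries_nonpositive(self):
        rng = np.random.default_rng(2)
        out = expected_log(rng.random((3, 3)) + 0.1)
        assert np.all(out <= 0)

    def test_zero_column_raises(self):
        with pytest.raises(InvalidCountError):
            expected_log(np.array([[0.0], [0.0]]))


class TestSoftmax:
    def test_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros(2)), [0.5, 0.5])

    def test_closed_form(self):
        np.testing.assert_allclose(softmax(np.log([3.0, 1.0])), [0.75, 0.25])

    def test_shift_invariance_and_overflow(self):
        x = np.array([0.0, 1000.0])
        out = softmax(x)
        assert np.isfinite(out).all() and out[1] > 0.999
        np.testing.assert_allclose(softmax(x), softmax(x + 12345.0), atol=1e-12)


def brute_force_mi(joint):
    """Exhaustive-summation oracle: sum p ln(p / (p_row p_col))."""
    p = np.asarray(joint, dtype=float)
    p = p / p.sum()
    mi = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                mi += p[i, j] * np.log(p[i, j] / (p[i].sum() * p[:, j].sum()))
    return mi


class TestMutualInformation:
    def test_diagonal_identity_mapping(self):
        assert mutual_information(np.eye(4) * 1e6) == pytest.approx(np.log(4), abs=1e-9)

    def test_outer_product_independent(self):
        joint = np.outer([2.0, 3.0], [1.0, 4.0, 5.0])
        assert mutual_information(joint) == pytest.approx(0.0, abs=1e-12)

    def test_enumeration_oracle_example(self):
        joint = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert mutual_information(joint) == pytest.approx(brute_force_mi(joint), abs=1e-12)

    def test_exhaustive_oracle_random_joints(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            shape = rng.integers(2, 5, size=2)
            joint = rng.random(tuple(shape)) + 0.01
            assert mutual_information(joint) == pytest.approx(
                brute_force_mi(joint), abs=1e-10
            )
            assert mutual_information_counts(joint) == pytest.approx(
                brute_force_mi(joint), abs=1e-10
            )

    def test_bounds(self):
        rng = np.random.default_rng(4)
        joint = rng.random((3, 4))
        mi = mutual_information(joint)
        assert 0 <= mi <= min(np.log(3), np.log(4)) + 1e-12

    def test_degenerate_single_row(self):
        assert mutual_information(np.array([[1.0, 2.0, 3.0]])) == 0.0


class TestOperatorProperties:
    """Algebraic invariants, searched over by hypothesis (derandomized)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    counts = arrays(
        float,
        (3, 3),
        elements=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
    )

    @given(counts)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_normalize_is_stochastic_and_idempotent(self, a):
        p = normalize(a)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(normalize(p), p, atol=1e-12)

    @given(counts)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_mi_non_negative_and_symmetric(self, a):
        mi = mutual_information(a + 0.01)
        assert mi >= -1e-12
        assert mi == pytest.approx(mutual_information(a.T + 0.01), abs=1e-9)

    @given(
        arrays(float, 4, elements=st.floats(min_value=-50, max_value=50)),
        st.floats(min_value=-100, max_value=100),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_softmax_shift_invariance(self, v, c):
        np.testing.assert_allclose(softmax(v + c), softmax(v), atol=1e-9)


class TestCountTensor:
    def test_roles_must_match_rank(self):
        with pytest.raises(ValueError):
            CountTensor(np.ones((2, 2)), axis_roles=("outcome",))

    def test_floored_adds_epsilon(self):
        t = CountTensor(np.zeros((2, 2)))
        assert np.all(t.floored(0.5).counts == 0.5)


class TestLogBeta:
    def test_two_entry_value(self):
        # B(a, b) = Gamma(a)Gamma(b)/Gamma(a+b); ln B(1,1) = 0
        assert dirichlet_log_beta([1.0, 1.0]) == pytest.approx(0.0)

    def test_requires_positive(self):
        with pytest.raises(InvalidCountError):
            dirichlet_log_beta([1.0, 0.0])


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, periodic_model):
        save_model(periodic_model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        assert loaded.top.n_states == periodic_model.top.n_states
        np.testing.assert_array_equal(loaded.top.B, periodic_model.top.B)
        np.testing.assert_array_equal(loaded.top.sequence, periodic_model.top.sequence)
        for lv, lv2 in zip(periodic_model.levels, loaded.levels):
            assert lv.R == lv2.R and lv.group_children == lv2.group_children
            for g, g2 in zip(lv.groups, lv2.groups):
                np.testing.assert_array_equal(g.spatial_states, g2.spatial_states)
                np.testing.assert_array_equal(g.segments, g2.segments)
                np.testing.assert_array_equal(g.B, g2.B)

    def test_codec_bins_preserved_to_full_precision(self, tmp_path):
        from rgm import frontends
        from rgm.worlds import periodic_video

        frames = periodic_video(8, 4, 16)
        part = frontends.fit_partition(frames, (8, 8), R=1)
        codecs = frontends.fit_codecs(frames, part, max_vectors=4, n_levels=5)
        obs = frontends.encode(frames, part, codecs)
        model = fast_structure_learn(obs, R_schedule=[1, 1], temporal=False)
        model.partition, model.codecs = part, codecs
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        for c, c2 in zip(codecs, loaded.codecs):
            np.testing.assert_array_equal(c.bin_centers, c2.bin_centers)
            np.testing.assert_array_equal(c.basis, c2.basis)

    def test_corrupted_manifest_errors(self, tmp_path, periodic_model):
        save_model(periodic_model, tmp_path / "m")
        (tmp_path / "m" / "manifest.json").write_text("{not json")
        with pytest.raises(ModelFormatError):
            load_model(tmp_path / "m")

    def test_version_mismatch_errors(self, tmp_path, periodic_model):
        import json

        save_model(periodic_model, tmp_path / "m")
        mf = tmp_path / "m" / "manifest.json"
        manifest = json.loads(mf.read_text())
        manifest["format_version"] = 999
        mf.write_text(json.dumps(manifest))
        with pytest.raises(ModelFormatError):
            load_model(tmp_path / "m")
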