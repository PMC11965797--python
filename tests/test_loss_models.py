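import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rediploid import (
    LossModelSpec,
    LossParams,
    ModelFlavor,
    Phylogeny,
    assignment_confidence,
    build_rate_matrix,
    dataset_loglik,
    n_assignment_vectors,
    pillar_conditional_likelihood,
    transition_matrix,
)
from rediploid.loss_models import _assignment_bits

from _oracles import (
    brute_assignment_posterior,
    brute_dataset_likelihood,
    brute_pillar_likelihood,
    series_expm,
)


def pkg_index(bits):
    """Package assignment-vector index for a bit tuple (genome g <-> bit g)."""
    return sum(b << g for g, b in enumerate(bits))


class TestRateMatrix:
    def test_bf_parameterization(self):
        q = build_rate_matrix(LossModelSpec(ModelFlavor.WGD_bf), 0.5, 0.3)
        np.testing.assert_allclose(q[0], [-1.8, 1.0, 0.5, 0.3])
        assert np.all(q[1:] == 0)

    def test_null_model_forces_values(self):
        q = build_rate_matrix(LossModelSpec(ModelFlavor.WGD_n))
        np.testing.assert_allclose(q[0], [-2.0, 1.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            build_rate_matrix(LossModelSpec(ModelFlavor.WGD_n), 1.0, 0.5)
        with pytest.raises(ValueError):
            build_rate_matrix(LossModelSpec(ModelFlavor.WGD_b), 0.5, 0.1)

    @given(eps=st.floats(0, 1), gamma=st.floats(0, 50))
    def test_rows_sum_to_zero(self, eps, gamma):
        q = build_rate_matrix(LossModelSpec(ModelFlavor.WGD_bf), eps, gamma)
        np.testing.assert_allclose(q.sum(axis=1), 0, atol=1e-12)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        q = build_rate_matrix(LossModelSpec(ModelFlavor.WGD_bf), 0.7, 0.2)
        np.testing.assert_allclose(transition_matrix(q, 0.0), np.eye(4))

    def test_closed_form_null_model(self):
        q = build_rate_matrix(LossModelSpec(ModelFlavor.WGD_n))
        p = transition_matrix(q, 0.5)
        assert p[0, 0] == pytest.approx(np.exp(-1), abs=1e-12)
        assert p[0, 1] == pytest.approx((1 - np.exp(-1)) / 2, abs=1e-12)

    def test_negative_time_rejected(self):
        q = build_rate_matrix(LossModelSpec(ModelFlavor.WGD_n))
        with pytest.raises(ValueError):
            transition_matrix(q, -0.1)

    @given(
        eps=st.floats(0.01, 1),
        gamma=st.floats(0, 10),
        t=st.floats(0, 5),
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_series_exponential(self, eps, gamma, t):
        q = build_rate_matrix(LossModelSpec(ModelFlavor.WGD_bf), eps, gamma)
        np.testing.assert_allclose(
            transition_matrix(q, t), series_expm(q, t), atol=1e-9
        )

    @given(s=st.floats(0, 3), t=st.floats(0, 3))
    @settings(max_examples=20, deadline=None)
    def test_semigroup_property(self, s, t):
        q = build_rate_matrix(LossModelSpec(ModelFlavor.WGD_bf), 0.4, 0.6)
        ps, pt = transition_matrix(q, s), transition_matrix(q, t)
        np.testing.assert_allclose(ps @ pt, transition_matrix(q, s + t), atol=1e-10)
        np.testing.assert_allclose(pt.sum(axis=1), 1.0, atol=1e-12)

    def test_absorbing_states_stay(self):
        q = build_rate_matrix(LossModelSpec(ModelFlavor.WGD_bf), 0.2, 1.5)
        p = transition_matrix(q, 7.3)
        np.testing.assert_allclose(p[1:], np.eye(4)[1:])


class TestPillarLikelihood:
    def test_single_leaf_at_zero_distance(self):
        tree = Phylogeny(["A"], [()], [0.0])
        spec = LossModelSpec(ModelFlavor.WGD_n)
        params = LossParams(1.0, 0.0, tree.lengths)
        assert pillar_conditional_likelihood(tree, spec, params, [0], 0) == 1.0
        assert pillar_conditional_likelihood(tree, spec, params, [1], 0) == 0.0

    @pytest.mark.parametrize("flavor,eps,gamma", [
        (ModelFlavor.WGD_n, 1.0, 0.0),
        (ModelFlavor.WGD_b, 0.4, 0.0),
        (ModelFlavor.WGD_bf, 0.6, 0.8),
    ])
    def test_pruning_equals_enumeration(self, three_leaf_tree, flavor, eps, gamma):
        spec = LossModelSpec(flavor)
        params = LossParams(eps, gamma, three_leaf_tree.lengths)
        q = build_rate_matrix(spec, eps, gamma)
        rng = np.random.default_rng(0)
        for _ in range(5):
            codes = rng.integers(0, 3, size=3)
            bits = tuple(rng.integers(0, 2, size=3))
            got = pillar_conditional_likelihood(
                three_leaf_tree, spec, params, codes, pkg_index(bits)
            )
            want = brute_pillar_likelihood(three_leaf_tree, q, codes, bits)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-14)

    def test_two_leaf_enumeration(self, two_leaf_tree):
        spec = LossModelSpec(ModelFlavor.WGD_bf)
        params = LossParams(0.3, 0.2, two_leaf_tree.lengths)
        q = build_rate_matrix(spec, 0.3, 0.2)
        for codes in itertools.product(range(3), repeat=2):
            for bits in itertools.product(range(2), repeat=2):
                got = pillar_conditional_likelihood(
                    two_leaf_tree, spec, params, list(codes), pkg_index(bits)
                )
                want = brute_pillar_likelihood(two_leaf_tree, q, codes, bits)
                assert got == pytest.approx(want, rel=1e-10, abs=1e-14)


class TestDatasetLoglik:
    def test_matches_brute_force_enumeration(self, two_leaf_tree):
        spec = LossModelSpec(ModelFlavor.WGD_b)
        params = LossParams(0.5, 0.0, two_leaf_tree.lengths, switch_prob=0.1)
        q = build_rate_matrix(spec, 0.5, 0.0)
        codes = np.array([[0, 1], [2, 0], [1, 1]], dtype=np.int8)
        got = dataset_loglik(two_leaf_tree, spec, params, codes)
        want = np.log(brute_dataset_likelihood(two_leaf_tree, q, codes, 0.1))
        assert got == pytest.approx(want, rel=1e-10)

    def test_one_pillar_reduces_to_assignment_average(self, two_leaf_tree):
        spec = LossModelSpec(ModelFlavor.WGD_n)
        params = LossParams(1.0, 0.0, two_leaf_tree.lengths, switch_prob=0.2)
        codes = np.array([[1, 2]], dtype=np.int8)
        avg = np.mean([
            pillar_conditional_likelihood(two_leaf_tree, spec, params, codes[0], a)
            for a in range(4)
        ])
        got = dataset_loglik(two_leaf_tree, spec, params, codes)
        assert got == pytest.approx(np.log(avg), rel=1e-12)

    def test_half_switch_prob_makes_pillars_exchangeable(self, two_leaf_tree):
        spec = LossModelSpec(ModelFlavor.WGD_b)
        params = LossParams(0.4, 0.0, two_leaf_tree.lengths, switch_prob=0.5)
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(20, 2)).astype(np.int8)
        base = dataset_loglik(two_leaf_tree, spec, params, codes)
        for _ in range(3):
            perm = rng.permutation(20)
            assert dataset_loglik(
                two_leaf_tree, spec, params, codes[perm]
            ) == pytest.approx(base, rel=1e-12)

    def test_reduction_identities(self, three_leaf_tree, small_table):
        # WGD_b at eps=1 and WGD_f at gamma=0 equal WGD_n exactly
        table, _, _, _ = small_table
        tree = Phylogeny(["A", "B"], [(), (), (0, 1)], [0.4, 0.5, 0.3])
        p_n = LossParams(1.0, 0.0, tree.lengths, 0.03)
        ll_n = dataset_loglik(tree, LossModelSpec(ModelFlavor.WGD_n), p_n, table)
        ll_b = dataset_loglik(tree, LossModelSpec(ModelFlavor.WGD_b), p_n, table)
        ll_f = dataset_loglik(tree, LossModelSpec(ModelFlavor.WGD_f), p_n, table)
        assert ll_b == ll_n
        assert ll_f == ll_n

    def test_zero_probability_dataset_warns_not_raises(self, two_leaf_tree):
        spec = LossModelSpec(ModelFlavor.WGD_n)
        # zero branch lengths make any loss impossible
        params = LossParams(1.0, 0.0, np.zeros(3), switch_prob=0.01)
        codes = np.array([[1, 0]], dtype=np.int8)
        with pytest.warns(UserWarning):
            ll = dataset_loglik(two_leaf_tree, spec, params, codes)
        assert ll == -np.inf


class TestAssignmentConfidence:
    def test_symmetric_losses_give_uniform_posterior(self):
        # zero root branch: no shared losses, so unbiased single-copy
        # observations carry no assignment information at all
        tree = Phylogeny(["A", "B"], [(), (), (0, 1)], [0.4, 0.5, 0.0])
        spec = LossModelSpec(ModelFlavor.WGD_n)
        params = LossParams(1.0, 0.0, tree.lengths, 0.05)
        codes = np.array([[1, 1]], dtype=np.int8)
        post = assignment_confidence(tree, spec, params, codes)
        np.testing.assert_allclose(post.posterior[0], 0.25)
        assert post.c[0] == pytest.approx(0.25)

    def test_posterior_matches_enumeration(self, two_leaf_tree):
        spec = LossModelSpec(ModelFlavor.WGD_b)
        params = LossParams(0.3, 0.0, two_leaf_tree.lengths, switch_prob=0.15)
        q = build_rate_matrix(spec, 0.3, 0.0)
        codes = np.array([[1, 0], [1, 2], [0, 2]], dtype=np.int8)
        got = assignment_confidence(two_leaf_tree, spec, params, codes)
        want = brute_assignment_posterior(two_leaf_tree, q, codes, 0.15)
        # oracle enumerates bit tuples in big-endian product order; remap
        remap = [pkg_index(bits) for bits in itertools.product((0, 1), repeat=2)]
        want_pkg = np.zeros_like(want)
        want_pkg[:, remap] = want
        np.testing.assert_allclose(got.posterior, want_pkg, atol=1e-10)
        assert np.allclose(got.posterior.sum(axis=1), 1.0)

    def test_strong_bias_pins_single_copies_to_subgenome_one(self, two_leaf_tree):
        spec = LossModelSpec(ModelFlavor.WGD_b)
        params = LossParams(1e-4, 0.0, two_leaf_tree.lengths, switch_prob=0.01)
        # genome A single copy on track a; genome B fully retained
        codes = np.array([[1, 0]], dtype=np.int8)
        post = assignment_confidence(two_leaf_tree, spec, params, codes)
        modal = int(post.modal_assignment[0])
        # bit for genome A must be 0: track a <-> subgenome 1
        assert modal & 1 == 0
        # confidence over genome A's bit approaches 1 (genome B stays ambiguous)
        p_bit_a0 = post.posterior[0, [0, 2]].sum()
        assert p_bit_a0 > 0.999

    def test_assignment_vector_count(self):
        assert n_assignment_vectors(5) == 32
        assert _assignment_bits(3).shape == (8, 3)
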