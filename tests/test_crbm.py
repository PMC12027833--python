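"""Dense and convolutional RBM: energies, conditionals, pooling, CD."""

import itertools
import json

import numpy as np
import pytest

from cdbn_lesion.crbm import (
    CRBMLayer,
    DenseRBM,
    cd_update,
    crbm_energy,
    dense_conditionals,
    dense_energy,
    flip_filter,
    gibbs_step,
    hidden_conditional,
    prob_max_pool,
    reconstruction_cross_entropy,
    sigmoid,
    visible_conditional,
)


def make_dense(rng, n=3, m=2, scale=1.0):
    return DenseRBM(
        weights=rng.normal(0, scale, size=(n, m)),
        visible_bias=rng.normal(0, scale, size=n),
        hidden_bias=rng.normal(0, scale, size=m),
    )


class TestDenseRBM:
    def test_zero_states_and_zero_parameters_give_zero_energy(self, rng):
        rbm = make_dense(rng)
        assert dense_energy(rbm, np.zeros(3), np.zeros(2)) == 0.0
        zero = DenseRBM(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert dense_energy(zero, np.ones(3), np.ones(2)) == 0.0

    def test_energy_matches_term_by_term_summation(self, rng):
        rbm = make_dense(rng)
        for v in itertools.product([0, 1], repeat=3):
            for h in itertools.product([0, 1], repeat=2):
                expect = 0.0
                for j in range(3):
                    expect -= rbm.visible_bias[j] * v[j]
                for i in range(2):
                    expect -= rbm.hidden_bias[i] * h[i]
                for j in range(3):
                    for i in range(2):
                        expect -= rbm.weights[j, i] * h[i] * v[j]
                got = dense_energy(rbm, np.array(v, float), np.array(h, float))
                assert got == pytest.approx(expect, abs=1e-12)

    def test_zero_parameters_give_half_probabilities(self):
        rbm = DenseRBM(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        np.testing.assert_allclose(dense_conditionals(rbm, np.ones(3), "visible"), 0.5)
        np.testing.assert_allclose(dense_conditionals(rbm, np.ones(2), "hidden"), 0.5)

    def test_sigmoid_saturates_for_large_input(self):
        rbm = DenseRBM(np.full((1, 1), 30.0), np.zeros(1), np.zeros(1))
        assert dense_conditionals(rbm, np.ones(1), "visible")[0] >= 1 - 1e-13

    def test_conditionals_match_partition_function_enumeration(self, rng):
        rbm = make_dense(rng)
        vstates = np.array(list(itertools.product([0, 1], repeat=3)), float)
        hstates = np.array(list(itertools.product([0, 1], repeat=2)), float)
        energies = np.array([[dense_energy(rbm, v, h) for h in hstates] for v in vstates])
        joint = np.exp(-(energies - energies.min()))
        joint /= joint.sum()
        for vi in range(8):
            cond = joint[vi] / joint[vi].sum()
            expect_h = (hstates * cond[:, None]).sum(axis=0)
            np.testing.assert_allclose(
                dense_conditionals(rbm, vstates[vi], "visible"), expect_h, atol=1e-10
            )
        for hi in range(4):
            cond = joint[:, hi] / joint[:, hi].sum()
            expect_v = (vstates * cond[:, None]).sum(axis=0)
            np.testing.assert_allclose(
                dense_conditionals(rbm, hstates[hi], "hidden"), expect_v, atol=1e-10
            )

    def test_shape_mismatch_rejected(self, rng):
        rbm = make_dense(rng)
        with pytest.raises(ValueError):
            dense_energy(rbm, np.zeros(4), np.zeros(2))
        with pytest.raises(ValueError):
            dense_conditionals(rbm, np.zeros(2), "visible")


def tiny_layer(rng, scale=1.0):
    return CRBMLayer(
        filters=rng.normal(0, scale, size=(1, 2, 2, 1)),
        hidden_bias=rng.normal(0, scale, size=1),
        visible_bias=float(rng.normal(0, scale)),
    )


def enumerate_crbm_conditionals(layer):
    """Exact conditionals of a 3x3-visible / single 2x2-filter CRBM from exp(-E)/Z."""
    W = layer.filters[0, :, :, 0]
    bk = layer.hidden_bias[0]
    c = layer.visible_bias
    vstates = np.array(list(itertools.product([0, 1], repeat=9)), float).reshape(-1, 3, 3)
    hstates = np.array(list(itertools.product([0, 1], repeat=4)), float).reshape(-1, 2, 2)

    def energy(v, h):
        e = 0.0
        for i in range(2):
            for j in range(2):
                conv = sum(W[p, q] * v[i + p, j + q] for p in range(2) for q in range(2))
                e -= h[i, j] * (conv + bk)
        return e - c * v.sum()

    energies = np.array([[energy(v, h) for h in hstates] for v in vstates])
    joint = np.exp(-(energies - energies.min()))
    joint /= joint.sum()
    return vstates, hstates, joint


class TestCRBM:
    def test_zero_states_give_zero_energy(self, rng):
        layer = tiny_layer(rng)
        assert crbm_energy(layer, np.zeros((3, 3)), np.zeros((2, 2))) == 0.0

    def test_all_ones_unit_filter_energy(self):
        layer = CRBMLayer(filters=np.ones((1, 2, 2, 1)), hidden_bias=[0.0], visible_bias=0.0)
        # each of the 4 hidden positions sees a receptive-field sum of 4
        assert crbm_energy(layer, np.ones((3, 3)), np.ones((2, 2))) == pytest.approx(-16.0)

    def test_energy_matches_nested_loop_oracle(self, rng):
        layer = tiny_layer(rng)
        W, bk, c = layer.filters[0, :, :, 0], layer.hidden_bias[0], layer.visible_bias
        v = rng.random((3, 3))
        h = rng.integers(0, 2, size=(2, 2)).astype(float)
        expect = 0.0
        for i in range(2):
            for j in range(2):
                conv = sum(W[p, q] * v[i + p, j + q] for p in range(2) for q in range(2))
                expect -= h[i, j] * (conv + bk)
        expect -= c * v.sum()
        assert crbm_energy(layer, v, h) == pytest.approx(expect, abs=1e-12)

    def test_zero_parameters_give_half_hidden_probabilities(self):
        layer = CRBMLayer(filters=np.zeros((2, 3, 3, 1)), hidden_bias=np.zeros(2))
        np.testing.assert_allclose(hidden_conditional(layer, np.random.rand(5, 5)), 0.5)

    def test_doubling_weights_pushes_probabilities_from_half(self, rng):
        layer = tiny_layer(rng)
        layer.hidden_bias = np.zeros(1)
        doubled = CRBMLayer(filters=2 * layer.filters, hidden_bias=np.zeros(1))
        v = rng.random((4, 4))
        p1 = hidden_conditional(layer, v)
        p2 = hidden_conditional(doubled, v)
        assert np.all(np.abs(p2 - 0.5) >= np.abs(p1 - 0.5) - 1e-12)

    def test_double_flip_is_identity(self, rng):
        w = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(flip_filter(flip_filter(w)), w)

    def test_zero_hidden_maps_give_sigmoid_bias(self, rng):
        layer = tiny_layer(rng)
        probs = visible_conditional(layer, np.zeros((2, 2, 1)), (3, 3))
        np.testing.assert_allclose(probs, sigmoid(np.array(layer.visible_bias)), atol=1e-14)

    def test_conditionals_match_full_enumeration(self, rng):
        layer = tiny_layer(rng)
        vstates, hstates, joint = enumerate_crbm_conditionals(layer)
        vi = 137  # arbitrary binary visible configuration
        cond = joint[vi] / joint[vi].sum()
        expect_h = (hstates * cond[:, None, None]).sum(axis=0)
        np.testing.assert_allclose(
            hidden_conditional(layer, vstates[vi])[:, :, 0], expect_h, atol=1e-10
        )
        hi = 11
        cond = joint[:, hi] / joint[:, hi].sum()
        expect_v = (vstates * cond[:, None, None]).sum(axis=0)
        np.testing.assert_allclose(
            visible_conditional(layer, hstates[hi][:, :, None], (3, 3))[:, :, 0],
            expect_v,
            atol=1e-10,
        )

    def test_lower_energy_state_has_probability_above_half(self, rng):
        # energy/probability duality for a single hidden unit
        layer = tiny_layer(rng)
        v = rng.integers(0, 2, size=(3, 3)).astype(float)
        h = np.zeros((2, 2))
        probs = hidden_conditional(layer, v)[:, :, 0]
        for i in range(2):
            for j in range(2):
                h_on, h_off = h.copy(), h.copy()
                h_on[i, j] = 1.0
                e_on = crbm_energy(layer, v, h_on)
                e_off = crbm_energy(layer, v, h_off)
                if e_on < e_off:
                    assert probs[i, j] > 0.5
                elif e_on > e_off:
                    assert probs[i, j] < 0.5


class TestProbMaxPool:
    def test_zero_activations_pool_to_four_fifths(self):
        assert prob_max_pool(np.zeros((2, 2)), 2)[0, 0] == pytest.approx(0.8)

    def test_saturated_activation_pools_to_one(self):
        a = np.zeros((2, 2))
        a[0, 1] = 1e3
        assert prob_max_pool(a, 2)[0, 0] >= 1 - 1e-10

    def test_matches_direct_formula_at_moderate_activations(self, rng):
        a = rng.uniform(-10, 10, size=(4, 4))
        pooled = prob_max_pool(a, 2)
        for bi in range(2):
            for bj in range(2):
                block = a[2 * bi : 2 * bi + 2, 2 * bj : 2 * bj + 2]
                s = np.exp(block).sum()
                assert pooled[bi, bj] == pytest.approx(s / (1 + s), abs=1e-12)

    def test_strictly_inside_unit_interval_and_increasing(self, rng):
        a = rng.normal(size=(6, 6))
        pooled = prob_max_pool(a, 2)
        assert np.all(pooled > 0) and np.all(pooled < 1)
        bumped = a.copy()
        bumped[1, 1] += 0.5
        assert prob_max_pool(bumped, 2)[0, 0] > pooled[0, 0]

    def test_odd_dimension_cropped(self, rng):
        a = rng.normal(size=(5, 5, 3))
        assert prob_max_pool(a, 2).shape == (2, 2, 3)

    def test_invalid_regions_rejected(self):
        with pytest.raises(ValueError):
            prob_max_pool(np.zeros((4, 4)), 0)
        with pytest.raises(ValueError):
            prob_max_pool(np.zeros((1, 1)), 2)

    def test_overflow_safe_shift_preserves_ratio(self):
        a = np.full((2, 2), 800.0)  # exp would overflow unshifted
        out = prob_max_pool(a, 2)
        assert np.isfinite(out).all() and out[0, 0] >= 1 - 1e-10


class TestGibbsAndCD:
    def test_same_seed_gives_bitwise_identical_samples(self, rng):
        layer = CRBMLayer.initialize(4, 3, rng=1)
        v = rng.random((8, 8))
        h1, r1 = gibbs_step(layer, v, rng_seed=7)
        h2, r2 = gibbs_step(layer, v, rng_seed=7)
        np.testing.assert_array_equal(h1, h2)
        np.testing.assert_array_equal(r1, r2)

    def test_saturated_probabilities_ignore_seed(self):
        layer = CRBMLayer(
            filters=np.full((1, 2, 2, 1), 50.0), hidden_bias=[0.0], visible_bias=0.0
        )
        v = np.ones((3, 3))
        for seed in (0, 1, 2):
            h, _ = gibbs_step(layer, v, rng_seed=seed)
            np.testing.assert_array_equal(h[:, :, 0], 1.0)

    def test_bernoulli_frequency_concentrates(self):
        # probability fixed at 0.3 via bias; 10,000 draws within +-0.02
        p = 0.3
        bias = np.log(p / (1 - p))
        layer = CRBMLayer(filters=np.zeros((1, 1, 1, 1)), hidden_bias=[bias])
        v = np.zeros((100, 100))
        h, _ = gibbs_step(layer, v, rng_seed=3)
        assert h.mean() == pytest.approx(p, abs=0.02)

    def test_zero_learning_rate_leaves_parameters_unchanged(self, rng):
        layer = CRBMLayer.initialize(3, 2, rng=0, learning_rate=0.0)
        batch = rng.random((4, 5, 5, 1))
        new = cd_update(layer, batch, rng_seed=0)
        np.testing.assert_array_equal(new.filters, layer.filters)
        np.testing.assert_array_equal(new.hidden_bias, layer.hidden_bias)

    def test_saturated_perfect_reconstruction_gives_tiny_update(self):
        # all-ones data, strongly positive parameters: hidden and visible
        # probabilities are both ~1, so positive and negative phases cancel
        layer = CRBMLayer(
            filters=np.full((2, 2, 2, 1), 20.0),
            hidden_bias=np.full(2, 20.0),
            visible_bias=20.0,
            learning_rate=1.0,
        )
        batch = np.ones((3, 4, 4, 1))
        new = cd_update(layer, batch, rng_seed=0)
        assert np.abs(new.filters - layer.filters).max() <= 1e-6
        assert np.abs(new.hidden_bias - layer.hidden_bias).max() <= 1e-6

    def test_invalid_inputs_rejected(self, rng):
        layer = CRBMLayer.initialize(2, 2, rng=0)
        with pytest.raises(ValueError):
            cd_update(layer, rng.random((3, 4, 4, 1)), cd_steps=0)
        with pytest.raises(ValueError):
            cd_update(layer, np.empty((0, 4, 4, 1)))

    def test_reconstruction_cross_entropy_is_deterministic(self, rng):
        layer = CRBMLayer.initialize(3, 3, rng=0)
        batch = rng.random((5, 6, 6, 1))
        assert reconstruction_cross_entropy(layer, batch) == reconstruction_cross_entropy(
            layer, batch
        )


class TestSerialization:
    def test_layer_round_trip_is_exact(self, rng):
        layer = CRBMLayer.initialize(4, 3, n_channels=2, rng=5, learning_rate=3e-4)
        restored = CRBMLayer.from_dict(json.loads(json.dumps(layer.to_dict())))
        np.testing.assert_array_equal(restored.filters, layer.filters)
        np.testing.assert_array_equal(restored.hidden_bias, layer.hidden_bias)
        assert restored.visible_bias == layer.visible_bias
        assert restored.learning_rate == layer.learning_rate
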