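"""Architecture ledger, LRN, initialization, forward contracts, gradients."""

import numpy as np
import pytest

from galiverseg.errors import ConfigError, DataError
from galiverseg.network import (GaCNN, LayerSpec, LRNParams, NetworkSpec,
                                count_parameters, default_spec, init_gaussian,
                                lrn, output_shape, shape_chain)

EXPECTED_COUNTS = [1600, 0, 153_792, 0, 442_624, 0, 9_441_280, 8_194, 0]
EXPECTED_TOTAL = 10_047_490
EXPECTED_CHAIN = [(13, 32), (13, 32), (13, 192), (6, 192), (6, 256), (3, 256)]


def tiny_spec(dropout=0.0):
    return NetworkSpec(
        input_shape=(2, 8, 8),
        layers=(
            LayerSpec("conv", kernel=3, stride=1, padding=1, out_channels=3),
            LayerSpec("maxpool", kernel=2, stride=2),
            LayerSpec("fc", out_channels=5),
            LayerSpec("fc", out_channels=2),
            LayerSpec("softmax"),
        ),
        dropout_rate=dropout,
    )


class TestShapesAndCounts:
    @pytest.mark.parametrize("kernel,stride,padding,input_side,expected", [
        (7, 2, 0, 32, 13),   # first conv
        (2, 2, 0, 6, 3),     # last pool
        (5, 1, 2, 13, 13),   # padded conv preserves side
        (1, 1, 0, 9, 9),     # identity layer
    ])
    def test_output_shape_rule(self, kernel, stride, padding, input_side, expected):
        layer = LayerSpec("conv", kernel=kernel, stride=stride,
                          padding=padding, out_channels=1)
        assert output_shape(layer, input_side) == expected

    def test_degenerate_shape_rejected(self):
        layer = LayerSpec("conv", kernel=9, stride=1, padding=0, out_channels=1)
        with pytest.raises(ConfigError):
            output_shape(layer, 4)

    def test_parameter_ledger_matches_reference_table(self):
        counts, total = count_parameters(default_spec())
        assert counts == EXPECTED_COUNTS
        assert total == EXPECTED_TOTAL

    def test_shape_chain_matches_reference_table(self):
        assert shape_chain(default_spec()) == EXPECTED_CHAIN

    def test_realized_network_parameter_shapes_sum_to_total(self):
        model = init_gaussian(default_spec(), sigma=1e-4, seed=0)
        realized = sum(arr.size for arr in model.parameters().values())
        assert realized == EXPECTED_TOTAL


class TestLRN:
    def test_zero_input_zero_output(self):
        assert np.array_equal(lrn(np.zeros((4, 6, 6))), np.zeros((4, 6, 6)))

    def test_single_channel_closed_form(self):
        params = LRNParams(k=2.0, alpha=0.0, beta=0.75, n=1)
        out = lrn(np.ones((1, 1, 1)), params)
        assert out[0, 0, 0] == pytest.approx(2 ** -0.75, abs=1e-12)

    def test_against_triple_loop_oracle(self, rng):
        params = LRNParams(k=2.0, alpha=0.3, beta=0.75, n=5)
        a = rng.standard_normal((5, 7, 7))
        got = lrn(a, params)
        half = params.n // 2
        c = a.shape[0]
        for i in range(c):
            for x in range(7):
                for y in range(7):
                    acc = sum(a[j, x, y] ** 2
                              for j in range(max(0, i - half),
                                             min(c - 1, i + half) + 1))
                    expected = a[i, x, y] / (params.k + params.alpha * acc) ** params.beta
                    assert got[i, x, y] == pytest.approx(expected, abs=1e-6)

    def test_neighbor_energy_never_amplifies(self, rng):
        params = LRNParams(k=2.0, alpha=0.5, beta=0.75, n=5)
        a = rng.standard_normal((5, 3, 3))
        base = np.abs(lrn(a, params))
        boosted = a.copy()
        boosted[2] *= 3.0  # increase squared activation of a neighbor
        out = np.abs(lrn(boosted, params))
        for i in (0, 1, 3, 4):
            assert np.all(out[i] <= base[i] + 1e-12)


class TestInitialization:
    def test_seed_determinism(self):
        a = init_gaussian(tiny_spec(), sigma=0.01, seed=5)
        b = init_gaussian(tiny_spec(), sigma=0.01, seed=5)
        for k in a.parameters():
            assert np.array_equal(a.parameters()[k], b.parameters()[k])

    def test_biases_zero_and_sigma_matches(self):
        model = init_gaussian(default_spec(), sigma=1e-4, seed=2)
        fc1_w = model.parameters()["fc1.weight"]
        assert fc1_w.size == 2304 * 4096
        assert np.std(fc1_w.astype(np.float64)) == pytest.approx(1e-4, rel=0.01)
        for name, arr in model.parameters().items():
            if name.endswith(".bias"):
                assert np.all(arr == 0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ConfigError):
            init_gaussian(tiny_spec(), sigma=0.0, seed=0)


class TestForward:
    def test_rows_are_probabilities(self, rng):
        model = init_gaussian(tiny_spec(), sigma=0.1, seed=1)
        probs = model.forward(rng.standard_normal((6, 2, 8, 8)))
        assert probs.shape == (6, 2)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_deterministic(self, rng):
        model = init_gaussian(default_spec(), sigma=1e-4, seed=1)
        batch = rng.random((4, 1, 32, 32)).astype(np.float32)
        assert np.array_equal(model.forward(batch), model.forward(batch))

    def test_small_init_predicts_near_uniform(self, rng):
        model = init_gaussian(default_spec(), sigma=1e-4, seed=3)
        probs = model.forward(rng.random((8, 1, 32, 32)).astype(np.float32))
        assert np.all(np.abs(probs - 0.5) < 0.01)

    def test_train_mode_dropout_is_stochastic(self, rng):
        model = init_gaussian(tiny_spec(dropout=0.5), sigma=0.5, seed=1)
        batch = rng.standard_normal((8, 2, 8, 8))
        a = model.forward(batch, train=True)
        b = model.forward(batch, train=True)
        assert not np.array_equal(a, b)

    def test_wrong_shape_rejected(self, rng):
        model = init_gaussian(tiny_spec(), sigma=0.1, seed=1)
        with pytest.raises(DataError):
            model.forward(rng.standard_normal((2, 1, 8, 8)))

    def test_relu_blocks_nonnegative(self, rng):
        model = init_gaussian(default_spec(), sigma=0.01, seed=0)
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        for layer in model.layers:
            x = layer.forward(x, False)
            if getattr(layer, "name", "") == "relu":
                assert np.all(x >= 0)
            if x.ndim == 2 and x.shape[1] == 2:
                break


class TestGradients:
    def test_backprop_matches_central_differences(self, rng):
        from galiverseg.train import cost

        model = init_gaussian(tiny_spec(), sigma=0.1, seed=3, dtype=np.float64)
        x = rng.standard_normal((4, 2, 8, 8))
        y = np.array([0, 1, 1, 0])
        probs = model.forward(x, train=False)
        onehot = np.zeros_like(probs)
        onehot[np.arange(4), y] = 1.0
        model.backward((probs - onehot) / 4)
        grads = {k: v.copy() for k, v in model.gradients().items()}
        params = model.parameters()
        eps = 1e-6
        for name, arr in params.items():
            flat = arr.reshape(-1)
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                up = cost(model.forward(x, train=False), y)
                flat[i] = orig - eps
                down = cost(model.forward(x, train=False), y)
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[name].reshape(-1)[i]
                assert numeric == pytest.approx(analytic, abs=1e-7), name


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = init_gaussian(tiny_spec(), sigma=0.1, seed=9)
        path = tmp_path / "model.npz"
        model.save(path, extra={"epoch": 3})
        loaded = GaCNN.load(path)
        batch = rng.standard_normal((3, 2, 8, 8))
        assert np.allclose(model.forward(batch), loaded.forward(batch))
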