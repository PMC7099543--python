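"""Network forward pass, analytic gradients, training loop, checkpoints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import pamcorr as pc
from pamcorr import cnn


finite_arrays = hnp.arrays(
    dtype=np.float64,
    shape=hnp.array_shapes(min_dims=1, max_dims=3, max_side=8),
    elements=st.floats(-1e6, 1e6),
)


class TestRelu:
    def test_definition(self):
        np.testing.assert_array_equal(pc.relu(np.array([-1.0, 0.0, 2.0])),
                                      [0.0, 0.0, 2.0])

    @settings(max_examples=50, derandomize=True)
    @given(finite_arrays)
    def test_idempotent(self, x):
        np.testing.assert_array_equal(pc.relu(pc.relu(x)), pc.relu(x))

    @settings(max_examples=50, derandomize=True)
    @given(finite_arrays)
    def test_relu_plus_mirrored_is_abs(self, x):
        np.testing.assert_array_equal(pc.relu(x) + pc.relu(-x), np.abs(x))


class TestConv2dSame:
    def test_delta_kernel_is_identity(self, rng):
        x = rng.normal(size=(10, 12, 1))
        kernel = np.zeros((5, 5, 1, 1))
        kernel[2, 2, 0, 0] = 1.0
        out = pc.conv2d_same(x, kernel, np.zeros(1))
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_zero_kernel_outputs_bias(self, rng):
        x = rng.normal(size=(7, 9, 3))
        out = pc.conv2d_same(x, np.zeros((3, 3, 3, 2)), np.array([1.5, -2.0]))
        np.testing.assert_array_equal(out[..., 0], np.full((7, 9), 1.5))
        np.testing.assert_array_equal(out[..., 1], np.full((7, 9), -2.0))

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_matches_brute_force_oracle(self, rng, conv_oracle, k):
        for _ in range(5):
            c_in, c_out = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            x = rng.normal(size=(int(rng.integers(5, 13)),
                                 int(rng.integers(5, 13)), c_in))
            kernel = rng.normal(size=(k, k, c_in, c_out))
            bias = rng.normal(size=c_out)
            np.testing.assert_allclose(
                pc.conv2d_same(x, kernel, bias),
                conv_oracle(x, kernel, bias),
                atol=1e-6,
            )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pc.conv2d_same(rng.normal(size=(8, 8, 2)),
                           rng.normal(size=(3, 3, 3, 1)), np.zeros(1))
        with pytest.raises(ValueError):
            pc.conv2d_same(rng.normal(size=(8, 8, 2)),
                           rng.normal(size=(3, 3, 2, 4)), np.zeros(3))


class TestForward:
    def test_zero_weights_give_constant_output_bias(self, rng):
        params = pc.NetworkParams(
            W1=np.zeros((3, 3, 1, 2)), W2=np.zeros((3, 3, 2, 2)),
            W3=np.zeros((3, 3, 2, 1)), B1=np.zeros(2), B2=np.zeros(2),
            B3=np.array([0.7]),
        )
        out = pc.forward(rng.normal(size=(12, 9)), params)
        np.testing.assert_allclose(out, 0.7, atol=1e-12)

    @pytest.mark.parametrize("shape", [(17, 23), (64, 64), (128, 96)])
    @pytest.mark.parametrize("k", [4, 5])
    def test_same_padding_preserves_shape(self, rng, shape, k):
        params = pc.NetworkParams.initialize(kernel_size=k, channels=4, seed=0)
        out = pc.forward(rng.uniform(size=shape), params)
        assert out.shape == shape

    def test_matches_oracle_composition(self, rng, conv_oracle, tiny_params):
        img = rng.uniform(size=(16, 16))
        p = tiny_params
        g1 = np.maximum(conv_oracle(img[:, :, None], p.W1, p.B1), 0)
        g2 = np.maximum(conv_oracle(g1, p.W2, p.B2), 0)
        expected = conv_oracle(g2, p.W3, p.B3)[:, :, 0]
        np.testing.assert_allclose(pc.forward(img, p), expected, atol=1e-5)

    def test_last_layer_has_no_nonlinearity(self):
        # with zero weights and a negative reconstruction bias the output
        # must stay negative; a trailing relu would clamp it to zero
        params = pc.NetworkParams(
            W1=np.zeros((3, 3, 1, 2)), W2=np.zeros((3, 3, 2, 2)),
            W3=np.zeros((3, 3, 2, 1)), B1=np.zeros(2), B2=np.zeros(2),
            B3=np.array([-1.0]),
        )
        assert np.all(pc.forward(np.ones((8, 8)), params) == -1.0)


class TestMseLoss:
    def test_identical_pairs_give_zero(self, rng):
        imgs = [rng.uniform(size=(5, 5)) for _ in range(3)]
        assert pc.mse_loss(imgs, [im.copy() for im in imgs]) == 0.0

    def test_constant_offset_closed_form(self):
        out = [np.full((3, 3), 2.0)]
        tgt = [np.zeros((3, 3))]
        assert pc.mse_loss(out, tgt) == pytest.approx(36.0)  # 9 pixels * 2^2
        assert pc.mse_loss(out, tgt, reduction="per_pixel_mean") == pytest.approx(4.0)

    def test_invariant_under_pair_permutation(self, rng):
        outs = [rng.uniform(size=(6, 6)) for _ in range(4)]
        tgts = [rng.uniform(size=(6, 6)) for _ in range(4)]
        perm = [2, 0, 3, 1]
        assert pc.mse_loss(outs, tgts) == pytest.approx(
            pc.mse_loss([outs[i] for i in perm], [tgts[i] for i in perm])
        )

    def test_empty_or_mismatched_rejected(self, rng):
        with pytest.raises(ValueError):
            pc.mse_loss([], [])
        with pytest.raises(ValueError):
            pc.mse_loss([rng.uniform(size=(4, 4))], [rng.uniform(size=(5, 5))])


class TestArchitecture:
    def test_default_parameter_count(self):
        params = pc.NetworkParams.initialize()
        k, C = 5, 64
        closed_form = k * k * 1 * C + C + k * k * C * C + C + k * k * C * 1 + 1
        assert params.n_parameters == closed_form == 105_729

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ValueError):
            pc.NetworkParams(
                W1=np.zeros((5, 5, 1, 8)), W2=np.zeros((5, 5, 8, 8)),
                W3=np.zeros((5, 5, 8, 1)), B1=np.zeros(4),  # wrong bias length
                B2=np.zeros(8), B3=np.zeros(1),
            )


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        base = pc.NetworkParams.initialize(kernel_size=3, channels=2,
                                           init_std=0.1, seed=5)
        # lift biases so no pre-activation sits on the ReLU kink, where
        # central differences are not informative about the subgradient
        params = pc.NetworkParams(
            W1=base.W1, W2=base.W2, W3=base.W3,
            B1=base.B1 + 0.2, B2=base.B2 + 0.2, B3=base.B3,
        )
        x = rng.uniform(size=(2, 8, 8))
        t = rng.uniform(size=(2, 8, 8))
        _, grads = cnn._loss_and_grads(params, x, t)
        names = ("W1", "W2", "W3", "B1", "B2", "B3")

        def loss_at(vals):
            return cnn._loss_and_grads(pc.NetworkParams(**vals), x, t)[0]

        eps = 1e-6
        worst = 0.0
        for name in names:
            arr = getattr(params, name)
            flat_idx = rng.choice(arr.size, size=min(arr.size, 12), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)
                vals = {n: getattr(params, n).copy() for n in names}
                vals[name][idx] += eps
                up = loss_at(vals)
                vals[name][idx] -= 2 * eps
                down = loss_at(vals)
                fd = (up - down) / (2 * eps)
                g = grads[name][idx]
                worst = max(worst, abs(fd - g) / max(abs(fd), abs(g), 1e-8))
        assert worst < 1e-4


class TestTraining:
    tiny = dict(kernel_size=3, channels=2, batch_size=4)

    def test_identity_task_reduces_loss(self):
        pairs = [(img.pixels, img.pixels)
                 for img in (pc.generate_vessel_phantom(16, 16, 2, seed=s)
                             for s in range(4))]
        config = pc.TrainingConfig(learning_rate=1e-4, n_epochs=200, **self.tiny)
        _, history = pc.train(pairs, config)
        assert history[-1] < history[0]

    def test_training_is_deterministic(self):
        pairs = pc.make_training_dataset(4, (16, 16), seed=2)
        config = pc.TrainingConfig(learning_rate=1e-4, n_epochs=10, **self.tiny)
        p1, h1 = pc.train(pairs, config)
        p2, h2 = pc.train(pairs, config)
        assert h1.losses == h2.losses
        np.testing.assert_array_equal(p1.W2, p2.W2)

    def test_full_batch_plain_gd_loss_monotone(self):
        pairs = pc.make_training_dataset(4, (16, 16), seed=3)
        config = pc.TrainingConfig(
            learning_rate=1e-6, n_epochs=40, kernel_size=3, channels=2,
            batch_size=4, optimizer="plain_gd",
        )
        _, history = pc.train(pairs, config)
        diffs = np.diff(history.losses)
        assert np.all(diffs <= 1e-7)

    def test_divergence_reports_epoch(self):
        pairs = pc.make_training_dataset(4, (16, 16), seed=4)
        config = pc.TrainingConfig(learning_rate=10.0, n_epochs=50, **self.tiny)
        with pytest.raises(pc.TrainingDivergedError) as err:
            pc.train(pairs, config)
        assert err.value.epoch >= 0

    def test_batch_size_larger_than_dataset_rejected(self):
        pairs = pc.make_training_dataset(2, (16, 16), seed=5)
        with pytest.raises(ValueError):
            pc.train(pairs, pc.TrainingConfig(batch_size=8, kernel_size=3,
                                              channels=2))

    def test_end_to_end_training_improves_heldout_mse(self):
        """The full loop learns to reduce corruption error on held-out pairs
        (the restoration claim, measured as image MSE)."""
        pairs = pc.make_training_dataset(40, (32, 32), seed=77)
        tr, te = pairs[:32], pairs[32:]
        config = pc.TrainingConfig(
            learning_rate=2e-6, n_epochs=150, batch_size=16, channels=8,
            kernel_size=5, seed=1, optimizer="momentum_gd",
            init_scheme="identity",
        )
        params, history = pc.train(tr, config)
        assert history[-1] < history[0]
        corrupted_mse = np.mean([
            np.mean((p.corrupted.pixels - p.clean.pixels) ** 2) for p in te
        ])
        corrected_mse = np.mean([
            np.mean((pc.correct_image(p.corrupted, params).pixels
                     - p.clean.pixels) ** 2)
            for p in te
        ])
        assert corrected_mse < corrupted_mse


class TestCorrectImage:
    def test_all_zero_image_is_noop(self, tiny_params):
        img = pc.MAPImage(pixels=np.zeros((16, 16)))
        out = pc.correct_image(img, tiny_params)
        assert isinstance(out, pc.MAPImage)
        np.testing.assert_array_equal(out.pixels, 0.0)

    def test_output_bounded_by_input_peak(self, rng, tiny_params):
        img = pc.MAPImage(pixels=rng.uniform(0, 3.7, size=(20, 20)))
        out = pc.correct_image(img, tiny_params)
        assert out.pixels.min() >= 0.0
        assert out.pixels.max() <= 3.7 + 1e-9

    def test_type_preserved(self, small_phantom, tiny_params):
        assert isinstance(pc.correct_image(small_phantom, tiny_params),
                          pc.PhantomImage)


class TestCheckpointIO:
    def test_round_trip_with_config_sidecar(self, tmp_path):
        params = pc.NetworkParams.initialize(kernel_size=3, channels=4, seed=8)
        config = pc.TrainingConfig(kernel_size=3, channels=4, n_epochs=5)
        path = tmp_path / "model.h5"
        pc.save_checkpoint(path, params, config)
        back = pc.load_checkpoint(path)
        for name in ("W1", "W2", "W3", "B1", "B2", "B3"):
            np.testing.assert_array_equal(getattr(back, name),
                                          getattr(params, name))
        assert cnn.load_training_config(path) == config
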