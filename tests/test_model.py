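import numpy as np
import pytest

from egps import nn
from egps.linknet import LinkNet, ModelConfig, init_model, load_checkpoint, predict_probability_mask, save_checkpoint
from egps.train import bce_loss

SMALL = ModelConfig(out_channels=3, base_width=8)
TINY = ModelConfig(out_channels=2, base_width=4)


def _conv_params(cout, cin, k, bias=False):
    return cout * cin * k * k + (cout if bias else 0)


def _bn_params(c):
    return 2 * c


def _basic_block_params(cin, cout, stride):
    n = _conv_params(cout, cin, 3) + _bn_params(cout)
    n += _conv_params(cout, cout, 3) + _bn_params(cout)
    if stride != 1 or cin != cout:
        n += _conv_params(cout, cin, 1) + _bn_params(cout)
    return n


def _decoder_params(cin, cout):
    mid = cin // 4
    return (
        _conv_params(mid, cin, 1)
        + _bn_params(mid)
        + _conv_params(mid, mid, 3)  # transposed conv has the same weight count
        + _bn_params(mid)
        + _conv_params(cout, mid, 1)
        + _bn_params(cout)
    )


def expected_param_count(cfg: ModelConfig) -> int:
    """Independent layer-by-layer tally of learnable parameters."""
    w = cfg.base_width
    w1, w2, w3, w4 = cfg.encoder_stage_widths
    total = _conv_params(w, cfg.in_channels, 7) + _bn_params(w)  # stem
    for cin, cout, stride in [(w, w1, 1), (w1, w2, 2), (w2, w3, 2), (w3, w4, 2)]:
        total += _basic_block_params(cin, cout, stride)
        total += _basic_block_params(cout, cout, 1)
    for cin, cout in [(w4, w3), (w3, w2), (w2, w1), (w1, w1)]:
        total += _decoder_params(cin, cout)
    total += _conv_params(w // 2, w1, 3) + _bn_params(w // 2)  # head transposed conv
    total += _conv_params(w // 2, w // 2, 3) + _bn_params(w // 2)
    total += _conv_params(cfg.out_channels, w // 2, 2, bias=True)
    return total


class TestConstruction:
    def test_output_shape_matches_input(self, rng):
        model = init_model(SMALL, seed=0)
        x = rng.normal(size=(1, 3, 128, 128)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (1, 3, 128, 128)

    def test_same_seed_identical_parameters(self):
        a = init_model(SMALL, seed=3)
        b = init_model(SMALL, seed=3)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_non_divisible_input_rejected_with_hint(self, rng):
        model = init_model(TINY, seed=0)
        with pytest.raises(ValueError, match="multiple of 32"):
            model.forward(rng.normal(size=(1, 3, 100, 100)).astype(np.float32))

    def test_invalid_width_chain_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(base_width=6)
        with pytest.raises(ValueError):
            ModelConfig(base_width=8, encoder_stage_widths=(8, 16, 32))

    def test_parameter_count_matches_independent_tally(self):
        for cfg in (TINY, SMALL):
            assert init_model(cfg, seed=0).n_params() == expected_param_count(cfg)


class TestForward:
    def test_batch_order_preserved_and_duplicates_identical(self, rng):
        model = init_model(TINY, seed=1)
        x = rng.normal(size=(2, 3, 32, 32)).astype(np.float32)
        batch = np.stack([x[0], x[1], x[0]])
        out = model.forward(batch)
        np.testing.assert_array_equal(out[0], out[2])
        np.testing.assert_allclose(out[0], model.forward(x)[0], atol=1e-5)

    def test_zero_input_gives_finite_output(self):
        model = init_model(SMALL, seed=2)
        out = model.forward(np.zeros((1, 3, 64, 64), dtype=np.float32))
        assert np.isfinite(out).all()

    def test_inference_deterministic(self, rng):
        model = init_model(TINY, seed=4)
        x = rng.normal(size=(1, 3, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))


class TestProbabilityHead:
    def test_sigmoid_range(self, rng):
        model = init_model(TINY, seed=5)
        p = predict_probability_mask(model, rng.normal(size=(32, 32, 3)))
        assert p.shape == (2, 32, 32)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_zero_logits_sigmoid_is_half(self):
        model = init_model(TINY, seed=6)
        final = model.head.layers[-1]
        final.w.data[...] = 0.0
        final.b.data[...] = 0.0
        p = predict_probability_mask(model, np.zeros((32, 32, 3), dtype=np.float32))
        np.testing.assert_allclose(p, 0.5, atol=1e-7)

    def test_zero_logits_softmax_is_uniform(self):
        cfg = ModelConfig(out_channels=3, base_width=4, activation_head="softmax")
        model = init_model(cfg, seed=6)
        final = model.head.layers[-1]
        final.w.data[...] = 0.0
        final.b.data[...] = 0.0
        p = predict_probability_mask(model, np.zeros((32, 32, 3), dtype=np.float32))
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-7)
        sums = model.activate(model.forward(np.zeros((1, 3, 32, 32), dtype=np.float32))).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)


class TestGradients:
    def test_all_parameters_receive_gradient(self, rng):
        model = init_model(TINY, seed=7)
        x = rng.normal(size=(2, 3, 32, 32)).astype(np.float32)
        t = (rng.random((2, 2, 32, 32)) < 0.5).astype(np.uint8)
        logits = model.forward(x, training=True)
        p = model.activate(logits)
        model.backward(((p - t) / t.size).astype(np.float32))
        dead = [p_.name for p_ in model.params() if not np.abs(p_.grad).max() > 0]
        assert dead == []

    def test_gradients_match_finite_differences(self, rng):
        """Backward pass equals central finite differences (float64)."""
        model = init_model(TINY, seed=8)
        for p in model.params():
            p.data = p.data.astype(np.float64)
            p.grad = np.zeros_like(p.data)
        for bn in model._bn_layers():
            bn.update_stats = False
        x = rng.normal(size=(2, 3, 32, 32))
        t = (rng.random((2, 2, 32, 32)) < 0.5).astype(np.uint8)

        def loss_value():
            return bce_loss(model.activate(model.forward(x, training=True)), t)

        probs = model.activate(model.forward(x, training=True))
        model.backward((probs - t.astype(np.float64)) / t.size)
        params = model.params()
        check_rng = np.random.default_rng(99)
        for pi in check_rng.choice(len(params), size=10, replace=False):
            p = params[pi]
            flat = p.data.ravel()
            i = int(check_rng.integers(flat.size))
            eps, orig = 1e-6, flat[i]
            flat[i] = orig + eps
            lp = loss_value()
            flat[i] = orig - eps
            lm = loss_value()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad.ravel()[i]
            assert abs(num - ana) <= 1e-6 + 1e-3 * (abs(num) + abs(ana)), p.name


class TestTranslationBehavior:
    def test_delta_response_shifts_with_input(self, rng):
        """Shifting a delta texture by 32 px shifts the interior response."""
        model = init_model(TINY, seed=9)
        h, w, shift = 64, 256, 32
        base = np.zeros((1, 3, h, w), dtype=np.float32)
        a = base.copy()
        a[0, :, h // 2, 96] = 5.0
        b = base.copy()
        b[0, :, h // 2, 96 + shift] = 5.0
        ra = model.forward(a) - model.forward(base)
        rb = model.forward(b) - model.forward(base)
        # compare responses in a central window around each delta
        wa = ra[0, :, :, 96 - 16 : 96 + 16]
        wb = rb[0, :, :, 96 + shift - 16 : 96 + shift + 16]
        corr = np.corrcoef(wa.ravel(), wb.ravel())[0, 1]
        assert corr > 0.99


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        model = init_model(TINY, seed=10)
        x = rng.normal(size=(1, 3, 32, 32)).astype(np.float32)
        ref = model.forward(x)
        path = tmp_path / "model.ckpt"
        save_checkpoint(
            path, model, meta={"schedule": [8, 32]}, arrays={"ref_channel_0": np.arange(5.0)}
        )
        loaded, meta, extras = load_checkpoint(path)
        assert meta["schedule"] == [8, 32]
        np.testing.assert_array_equal(extras["ref_channel_0"], np.arange(5.0))
        np.testing.assert_array_equal(loaded.forward(x), ref)
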