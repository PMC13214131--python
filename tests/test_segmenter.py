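"""Hybrid segmenter: attention correctness, loss algebra, training and
inference contracts.  The heavyweight accuracy run lives in the acceptance
suite; here the desk model is exercised at tiny scale."""

from __future__ import annotations

import numpy as np
import pytest

from sinusct.core import Volume
from sinusct.nn import Tensor, softmax
from sinusct.phantoms import PhantomSpec, cohort_specs, generate_phantom
from sinusct.preprocess import normalize_minmax, sanitize
from sinusct.segmenter import (DICE_SMOOTH, SegConfig, TrainOpts,
                               WindowAttention, build_segmenter,
                               composite_loss, desk_seg_config,
                               predict_mask, train_segmenter,
                               window_attention)


def dense_attention_oracle(x: np.ndarray, attn: WindowAttention) -> np.ndarray:
    """Plain multi-head attention over *all* tokens, from the module weights."""
    n, X, Y, Z, C = x.shape
    t = x.reshape(n, -1, C)
    qkv = t @ attn.qkv.weight.data + attn.qkv.bias.data
    h = attn.heads
    hd = C // h
    T = t.shape[1]
    qkv = qkv.reshape(n, T, 3, h, hd).transpose(2, 0, 3, 1, 4)
    q, k, v = qkv[0], qkv[1], qkv[2]
    a = (q @ np.swapaxes(k, -1, -2)) / np.sqrt(hd)
    a = a - a.max(axis=-1, keepdims=True)
    e = np.exp(a)
    a = e / e.sum(axis=-1, keepdims=True)
    out = (a @ v).transpose(0, 2, 1, 3).reshape(n, T, C)
    out = out @ attn.proj.weight.data + attn.proj.bias.data
    return out.reshape(n, X, Y, Z, C)


class TestWindowAttention:
    @pytest.mark.parametrize("heads", [1, 2, 4])
    def test_window_covering_grid_equals_dense_attention(self, heads, rng):
        attn = WindowAttention(8, (4, 4, 4), heads, (0, 0, 0),
                               np.random.default_rng(heads))
        x = rng.normal(size=(2, 4, 4, 4, 8)).astype(np.float32)
        out = window_attention(attn, Tensor(x)).numpy()
        assert np.abs(out - dense_attention_oracle(x, attn)).max() < 1e-5

    def test_unshifted_windows_are_independent(self, rng):
        """An impulse confined to one window must not perturb the other."""
        attn = WindowAttention(4, (2, 2, 2), 2, (0, 0, 0),
                               np.random.default_rng(0))
        base = np.zeros((1, 4, 2, 2, 4), np.float32)
        out0 = attn(Tensor(base)).numpy()
        impulse = base.copy()
        impulse[0, 0, 0, 0, :] = 5.0  # lives in the first 2x2x2 window
        out1 = attn(Tensor(impulse)).numpy()
        assert np.abs(out1[0, 2:] - out0[0, 2:]).max() < 1e-6
        assert np.abs(out1[0, :2] - out0[0, :2]).max() > 1e-3

    def test_shifted_windows_mask_out_wrapped_tokens(self, rng):
        """With a cyclic shift, tokens from opposite grid ends share a window
        but must not attend to each other."""
        attn = WindowAttention(4, (2, 1, 1), 1, (1, 0, 0),
                               np.random.default_rng(3))
        base = np.zeros((1, 4, 1, 1, 4), np.float32)
        out0 = attn(Tensor(base)).numpy()
        impulse = base.copy()
        impulse[0, 0] = 7.0  # wraps around into the window holding x=3
        out1 = attn(Tensor(impulse)).numpy()
        # token x=3 is grouped with the wrapped x=0 token; masking keeps it clean
        assert np.abs(out1[0, 3] - out0[0, 3]).max() < 1e-6

    def test_output_preserves_shape_with_padding(self, rng):
        attn = WindowAttention(6, (3, 3, 3), 2, (1, 1, 1),
                               np.random.default_rng(1))
        x = rng.normal(size=(1, 5, 4, 7, 6)).astype(np.float32)
        assert attn(Tensor(x)).shape == x.shape

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            WindowAttention(6, (2, 2, 2), 4, (0, 0, 0), np.random.default_rng(0))


class TestBuild:
    def test_forward_shape_contract(self, rng):
        cfg = desk_seg_config()
        model = build_segmenter(cfg, seed=0)
        x = rng.random((1, 1, 48, 48, 48)).astype(np.float32)
        logits = model(Tensor(x))
        assert logits.shape == (1, 5, 48, 48, 48)
        probs = softmax(logits, axis=1).numpy()
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-5

    def test_seeded_init_identical(self):
        a = build_segmenter(desk_seg_config(), seed=7)
        b = build_segmenter(desk_seg_config(), seed=7)
        assert all(np.array_equal(p.data, q.data)
                   for p, q in zip(a.parameters(), b.parameters()))

    def test_variant_parameter_ordering(self):
        full = build_segmenter(desk_seg_config("full"), seed=0).num_parameters()
        cnn = build_segmenter(desk_seg_config("cnn_only"), seed=0).num_parameters()
        trans = build_segmenter(desk_seg_config("transformer_only"), seed=0).num_parameters()
        assert cnn < full
        assert trans < full

    def test_reference_profile_constructs(self):
        from sinusct.segmenter import reference_seg_config

        cfg = reference_seg_config()
        cfg.validate()
        model = build_segmenter(cfg, seed=0)
        assert model.num_parameters() > \
            build_segmenter(desk_seg_config(), seed=0).num_parameters()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SegConfig(embed_dim=10, heads=(3, 3, 3, 3)).validate()
        with pytest.raises(ValueError):
            SegConfig(num_classes=1).validate()
        with pytest.raises(ValueError):
            SegConfig(in_shape=(50, 48, 48), patch_size=4).validate()


class TestCompositeLoss:
    def test_one_hot_prediction_zeroes_dice_component(self):
        target = np.array([[[[1, 2]]]])
        onehot = np.moveaxis(np.eye(5, dtype=np.float32)[target], -1, 1)
        loss = composite_loss(Tensor(onehot), target, dice_weight=1.0,
                              ce_weight=0.0)
        assert loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_uniform_binary_ce_is_ln2(self):
        probs = Tensor(np.array([0.5, 0.5], np.float32).reshape(1, 2, 1, 1, 1))
        loss = composite_loss(probs, np.ones((1, 1, 1, 1), np.int64),
                              dice_weight=0.0, ce_weight=1.0)
        assert loss.item() == pytest.approx(np.log(2), rel=1e-5)

    def test_two_voxel_worked_case_matches_hand_formula(self):
        # 2 voxels, 2 classes; p(class1) = (0.3, 0.8), target = (0, 1)
        p1 = np.array([0.3, 0.8], np.float32)
        probs = np.stack([1 - p1, p1]).reshape(1, 2, 2, 1, 1)
        target = np.array([0, 1]).reshape(1, 2, 1, 1)
        got = composite_loss(Tensor(probs), target, 0.5, 0.5).item()
        # hand evaluation: soft dice for class 1, mean CE over both voxels
        inter, psum, gsum = 0.8, 1.1, 1.0
        dice = (2 * inter + DICE_SMOOTH) / (psum + gsum + DICE_SMOOTH)
        ce = -(np.log(0.7) + np.log(0.8)) / 2
        assert got == pytest.approx(0.5 * (1 - dice) + 0.5 * ce, rel=1e-5)

    def test_dice_term_permutation_invariant(self, rng):
        probs = rng.random((1, 3, 2, 2, 2)).astype(np.float32)
        probs /= probs.sum(axis=1, keepdims=True)
        target = rng.integers(0, 3, (1, 2, 2, 2))
        perm = rng.permutation(8)
        flat_p = probs.reshape(1, 3, 8)[:, :, perm].reshape(1, 3, 2, 2, 2)
        flat_t = target.reshape(1, 8)[:, perm].reshape(1, 2, 2, 2)
        a = composite_loss(Tensor(probs), target, 1.0, 0.0).item()
        b = composite_loss(Tensor(flat_p), flat_t, 1.0, 0.0).item()
        assert a == pytest.approx(b, rel=1e-6)

    def test_ce_decreases_as_mass_moves_to_target(self):
        target = np.zeros((1, 1, 1, 1), np.int64)
        vals = []
        for p in (0.4, 0.6, 0.9):
            probs = np.array([p, 1 - p], np.float32).reshape(1, 2, 1, 1, 1)
            vals.append(composite_loss(Tensor(probs), target, 0.0, 1.0).item())
        assert vals[0] > vals[1] > vals[2]

    def test_label_out_of_range_rejected(self):
        probs = Tensor(np.full((1, 2, 1, 1, 1), 0.5, np.float32))
        with pytest.raises(ValueError):
            composite_loss(probs, np.array([[[[5]]]]), 0.5, 0.5)


def _tiny_samples(n, seed, shape=(48, 48, 48)):
    samples = []
    for sp in cohort_specs(n, PhantomSpec(grid_shape=shape), 0.0, seed=seed):
        s = generate_phantom(sp)
        v = normalize_minmax(sanitize(s.volume))
        samples.append((v.grid, s.labels.grid))
    return samples


class TestTraining:
    def test_pseudo_weight_zero_leaves_parameters_unchanged(self):
        samples = [(v, m, True) for v, m in _tiny_samples(2, 31)]
        model = build_segmenter(desk_seg_config(), seed=1)
        before = [p.data.copy() for p in model.parameters()]
        model, _ = train_segmenter(model, samples,
                                   TrainOpts(epochs=1, pseudo_label_weight=0.0,
                                             seed=1))
        assert all(np.array_equal(a, p.data)
                   for a, p in zip(before, model.parameters()))

    def test_empty_manifest_rejected(self):
        model = build_segmenter(desk_seg_config(), seed=0)
        with pytest.raises(ValueError):
            train_segmenter(model, [], TrainOpts(epochs=1))

    def test_seeded_runs_reproduce_loss_history(self):
        samples = _tiny_samples(2, 32)
        hists = []
        for _ in range(2):
            model = build_segmenter(desk_seg_config(), seed=3)
            _, h = train_segmenter(model, samples,
                                   TrainOpts(lr=1e-3, epochs=2, seed=3))
            hists.append(h)
        assert np.allclose(hists[0], hists[1], atol=1e-6)


class TestPredict:
    def test_probabilities_sum_to_one_and_eval_deterministic(self):
        model = build_segmenter(desk_seg_config(), seed=0)
        sp = cohort_specs(1, PhantomSpec(grid_shape=(48, 48, 48)), 0.0, seed=9)[0]
        s = generate_phantom(sp)
        v = normalize_minmax(sanitize(s.volume))
        a = predict_mask(model, v)
        b = predict_mask(model, v)
        assert np.abs(a.probs.sum(axis=0) - 1).max() < 1e-5
        assert np.array_equal(a.labels.grid, b.labels.grid)
        assert np.array_equal(a.labels.grid, a.probs.argmax(axis=0))

    def test_unnormalized_input_rejected(self):
        model = build_segmenter(desk_seg_config(), seed=0)
        v = Volume(np.zeros((48, 48, 48), np.float32), (1, 1, 1), "HU")
        with pytest.raises(ValueError):
            predict_mask(model, v)

    def test_sliding_window_tiles_larger_volumes(self):
        model = build_segmenter(desk_seg_config(), seed=0)
        v = Volume(np.random.default_rng(0).random((60, 48, 48)).astype(np.float32),
                   (1, 1, 1), "normalized")
        pred = predict_mask(model, v)
        assert pred.probs.shape == (5, 60, 48, 48)
        assert np.abs(pred.probs.sum(axis=0) - 1).max() < 1e-5
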