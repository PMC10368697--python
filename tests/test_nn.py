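"""Network engine: gradient checks against finite differences, architecture
contracts, loss identities, tiled inference."""

import numpy as np
import pytest

from skelpatch.core import ImageVolume
from skelpatch.nn import (
    LossConfig,
    NetworkSpec,
    Prediction,
    Tensor,
    build_model,
    compute_loss,
    multitask_loss,
    predict_volume,
    soft_dice_loss,
    tversky_focal_loss,
)
from skelpatch.nn import tensor as T
from skelpatch.skeleton import SkeletonVoxelSet


def _numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f()
        x[i] = x0 - eps
        fm = f()
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
    return g


def _check(make_loss, params, tol=2e-2):
    for p in params:
        p.grad = None
    make_loss().backward()
    for p in params:
        ng = _numeric_grad(lambda: make_loss().item(), p.data)
        scale = np.abs(ng).max() + 1e-6
        assert np.abs(p.grad - ng).max() / scale < tol


class TestGradients:
    """Every hand-written backward pass vs central finite differences."""

    @pytest.fixture()
    def x(self, rng):
        return Tensor(rng.standard_normal((2, 4, 4, 4, 3)).astype(np.float32), requires_grad=True)

    def test_conv3d(self, rng, x):
        w = Tensor(0.3 * rng.standard_normal((3, 3, 3, 3, 2)).astype(np.float32), requires_grad=True)
        b = Tensor(rng.standard_normal(2).astype(np.float32), requires_grad=True)
        _check(lambda: (T.conv3d(x, w, b) ** 2).sum(), [x, w, b])

    def test_conv1x1(self, rng, x):
        w = Tensor(rng.standard_normal((1, 1, 1, 3, 2)).astype(np.float32), requires_grad=True)
        _check(lambda: (T.conv3d(x, w) ** 2).sum(), [x, w])

    def test_maxpool(self, x):
        _check(lambda: (T.maxpool2(x) ** 2).sum(), [x])

    def test_upsample(self, rng, x):
        mult = Tensor(rng.standard_normal((2, 8, 8, 8, 3)).astype(np.float32))
        _check(lambda: (T.upsample2(x) * mult).sum(), [x])

    def test_batchnorm(self, rng, x):
        g = Tensor(rng.standard_normal(3).astype(np.float32), requires_grad=True)
        b = Tensor(rng.standard_normal(3).astype(np.float32), requires_grad=True)
        rm, rv = np.zeros(3, np.float32), np.ones(3, np.float32)
        _check(lambda: (T.batchnorm(x, g, b, rm.copy(), rv.copy(), True) ** 3).sum(), [x, g, b])

    def test_prelu(self, rng, x):
        a = Tensor(np.array([0.2, 0.3, 0.1], np.float32), requires_grad=True)
        _check(lambda: (T.prelu(x, a) ** 2).sum(), [x, a])

    def test_softmax_matmul(self, rng):
        m = Tensor(rng.standard_normal((4, 5)).astype(np.float32), requires_grad=True)
        w = Tensor(rng.standard_normal((5, 3)).astype(np.float32), requires_grad=True)
        _check(lambda: (T.softmax(T.matmul(m, w), axis=-1) ** 2).sum(), [m, w])

    def test_loss_terms(self, rng):
        p = Tensor(rng.uniform(0.05, 0.95, (2, 4, 4, 4, 1)).astype(np.float32), requires_grad=True)
        g = Tensor((rng.uniform(0, 1, (2, 4, 4, 4, 1)) > 0.7).astype(np.float32))
        _check(lambda: soft_dice_loss(p, g), [p])
        _check(lambda: tversky_focal_loss(p, g, 0.3, 0.7, 4 / 3), [p])


class TestArchitecture:
    def test_paper_scale_conv_count_is_23(self):
        model = build_model(NetworkSpec(depth=4, base_channels=2, block_style="plain"))
        assert model.conv_layer_count() == 23

    def test_forward_shapes(self):
        spec = NetworkSpec(depth=2, base_channels=4, aux_tap_levels=("bridge", "mid"))
        model = build_model(spec, seed=0).eval()
        x = Tensor(np.zeros((2, 16, 16, 16, 1), np.float32))
        seg, aux = model(x)
        assert seg.shape == (2, 16, 16, 16, 1)
        assert len(aux) == 2
        for a in aux:
            assert a.shape == (2, 1)
            assert 0 <= a.data.min() and a.data.max() <= 1
        assert 0 <= seg.data.min() and seg.data.max() <= 1

    def test_indivisible_input_rejected(self):
        model = build_model(NetworkSpec(depth=3, base_channels=2))
        with pytest.raises(ValueError, match="divisible"):
            model(Tensor(np.zeros((1, 12, 12, 12, 1), np.float32)))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        from skelpatch.nn import load_model, save_model

        spec = NetworkSpec(depth=2, base_channels=4, aux_tap_levels=("bridge",))
        model = build_model(spec, seed=3).eval()
        x = Tensor(rng.standard_normal((1, 8, 8, 8, 1)).astype(np.float32))
        seg, _ = model(x)
        save_model(model, tmp_path / "ckpt.npz", seed=3)
        back = load_model(tmp_path / "ckpt.npz")
        seg2, _ = back(x)
        assert back.spec == spec
        assert np.array_equal(seg.data, seg2.data)

    def test_seeded_init_checksum(self):
        spec = NetworkSpec(depth=2, base_channels=4)
        a = build_model(spec, seed=5)
        b = build_model(spec, seed=5)
        c = build_model(spec, seed=6)
        assert a.checksum() == b.checksum()
        assert a.checksum() != c.checksum()

    def test_gradient_flows_through_seg_and_aux_paths(self, rng):
        spec = NetworkSpec(depth=2, base_channels=4, aux_tap_levels=("bridge",))
        model = build_model(spec, seed=0)
        x = Tensor(rng.standard_normal((2, 8, 8, 8, 1)).astype(np.float32))
        mask = Tensor((rng.uniform(0, 1, (2, 8, 8, 8, 1)) > 0.9).astype(np.float32))
        labels = Tensor(np.array([[1.0], [1.0]], np.float32))
        seg, aux = model(x)
        total, _ = multitask_loss(seg, aux, mask, labels, LossConfig())
        model.zero_grad()
        total.backward()
        enc_grads = [np.abs(p.grad).sum() for p in model.enc0.parameters() if p.grad is not None]
        assert enc_grads and all(np.isfinite(g) for g in enc_grads)
        assert sum(enc_grads) > 0
        head_grads = [np.abs(p.grad).sum() for p in model.aux_bridge.parameters()]
        assert sum(head_grads) > 0

    def test_residual_and_attention_forward_backward(self, rng):
        spec = NetworkSpec(
            depth=2, base_channels=4, block_style="residual", attention=True,
            aux_tap_levels=("bridge",),
        )
        model = build_model(spec, seed=1)
        x = Tensor(rng.standard_normal((1, 8, 8, 8, 1)).astype(np.float32))
        seg, aux = model(x)
        total, _ = multitask_loss(
            seg, aux, Tensor(np.zeros((1, 8, 8, 8, 1), np.float32)),
            Tensor(np.zeros((1, 1), np.float32)), LossConfig(),
        )
        model.zero_grad()
        total.backward()
        assert np.isfinite(total.item())


class TestLosses:
    def test_tversky_half_half_equals_dice(self, rng):
        p = Tensor(rng.uniform(0, 1, (3, 4, 4, 4, 1)).astype(np.float32))
        g = Tensor((rng.uniform(0, 1, (3, 4, 4, 4, 1)) > 0.6).astype(np.float32))
        lhs = tversky_focal_loss(p, g, 0.5, 0.5, 1.0).item()
        rhs = soft_dice_loss(p, g).item()
        assert abs(lhs - rhs) < 1e-6

    def test_minimum_at_perfect_prediction(self):
        g = np.zeros((1, 4, 4, 4, 1), np.float32)
        g[0, 1:3, 1:3, 1:3, 0] = 1
        total, terms = compute_loss(g[0, ..., 0], g[0, ..., 0], 1, aux_probability=1.0)
        assert terms["dice"] < 1e-3
        assert terms["aux_bce"] < 1e-4
        assert total < 0.01

    def test_terms_match_direct_summation_oracle(self, rng):
        cfg = LossConfig(tversky_alpha=0.3, tversky_beta=0.7, focal_gamma=4 / 3)
        p = rng.uniform(0.01, 0.99, (4, 4, 4)).astype(np.float32)
        g = (rng.uniform(0, 1, (4, 4, 4)) > 0.6).astype(np.float32)
        _, terms = compute_loss(p, g, int(g.any()), cfg)
        # straightforward summation oracle (smooth = 1 convention)
        s = 1.0
        tp = float((p * g).sum())
        fp = float((p * (1 - g)).sum())
        fn = float(((1 - p) * g).sum())
        dice_o = 1 - (tp + s) / (tp + 0.5 * fp + 0.5 * fn + s)
        tv_o = (1 - (tp + s) / (tp + 0.3 * fp + 0.7 * fn + s)) ** (4 / 3)
        eps = 1e-6
        pc = p * (1 - 2 * eps) + eps
        ce_o = float(-(g * np.log(pc) + (1 - g) * np.log(1 - pc)).mean())
        assert abs(terms["dice"] - dice_o) < 1e-6
        assert abs(terms["tversky_focal"] - tv_o) < 1e-6
        assert abs(terms["cross_entropy"] - ce_o) < 1e-6

    def test_loss_nonnegative(self, rng):
        for _ in range(10):
            p = rng.uniform(0, 1, (4, 4, 4)).astype(np.float32)
            g = (rng.uniform(0, 1, (4, 4, 4)) > 0.5).astype(np.float32)
            total, _ = compute_loss(p, g, int(g.any()), aux_probability=rng.uniform())
            assert total >= 0

    def test_aux_disabled_zeroes_term(self, rng):
        p = rng.uniform(0, 1, (4, 4, 4)).astype(np.float32)
        g = (rng.uniform(0, 1, (4, 4, 4)) > 0.5).astype(np.float32)
        cfg = LossConfig(aux_enabled=False)
        _, terms = compute_loss(p, g, int(g.any()), cfg, aux_probability=0.7)
        assert terms["aux_bce"] == 0.0

    def test_label_mask_mismatch_rejected(self):
        g = np.zeros((4, 4, 4), np.float32)
        g[0, 0, 0] = 1
        with pytest.raises(ValueError, match="inconsistent"):
            compute_loss(g, g, 0)


class TestTiledInference:
    @pytest.fixture()
    def volume(self, rng):
        return ImageVolume(rng.standard_normal((24, 24, 24)).astype(np.float32), (1, 1, 1))

    @pytest.fixture()
    def skeleton(self):
        coords = np.array([[6, 6, 6], [6, 6, 18], [18, 18, 18]])
        return SkeletonVoxelSet(coords, (24, 24, 24))

    def test_constant_model_covers_tile_union(self, volume, skeleton):
        pred = predict_volume(
            None, volume, skeleton, patch_size=(8, 8, 8), stride=8,
            forward=lambda b: np.ones_like(b),
        )
        m = pred.mask().astype_bool()
        # covered voxels get probability 1; everything else stays 0
        assert m.any()
        assert pred.seg_probability[~m].max() == 0.0
        assert pred.seg_probability[m].min() == 1.0

    def test_empty_skeleton_warns_and_zeroes(self, volume):
        empty = SkeletonVoxelSet(np.empty((0, 3), int), (24, 24, 24))
        with pytest.warns(UserWarning, match="empty skeleton"):
            pred = predict_volume(None, volume, empty, forward=lambda b: np.ones_like(b))
        assert pred.seg_probability.max() == 0.0

    def test_overlap_average_matches_accumulator_oracle(self, volume):
        """Two overlapping patches with distinct constant outputs: the
        averaged probability equals an explicit accumulate/count oracle."""
        coords = np.array([[4, 4, 4], [4, 4, 8]])
        skel = SkeletonVoxelSet(coords, (24, 24, 24))
        values = iter([0.2, 0.8])

        def forward(batch):
            return np.stack([np.full(batch.shape[1:], next(values), np.float32) for _ in batch])

        pred = predict_volume(None, volume, skel, patch_size=(8, 8, 8), stride=4,
                              batch_size=1, forward=forward)
        acc = np.zeros((24, 24, 24))
        cnt = np.zeros((24, 24, 24))
        for origin, v in zip([(0, 0, 0), (0, 0, 4)], [0.2, 0.8]):
            sl = tuple(slice(o, o + 8) for o in origin)
            acc[sl] += v
            cnt[sl] += 1
        oracle = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
        assert np.allclose(pred.seg_probability, oracle, atol=1e-6)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError, match="probabilities"):
            Prediction(np.full((4, 4, 4), 1.5))
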