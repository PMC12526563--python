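"""LSCSHN head structure and the loss suite (printed formulation)."""

import numpy as np
import pytest

from falsseg import autograd as ag
from falsseg.autograd import Tensor
from falsseg.lscshn import (
    LSCSHN,
    HeadConfig,
    Proto,
    SegmentHead,
    assemble_instance_masks,
    bbox_regression_loss,
    classification_loss,
    distribution_focal_loss,
    segmentation_loss,
)

RNG = np.random.default_rng(5)


def feats(n=1, size=640):
    return [
        Tensor(RNG.normal(0, 1, (n, c, size // s, size // s)).astype(np.float32))
        for c, s in ((64, 8), (128, 16), (256, 32))
    ]


class TestSharedStack:
    def test_shared_weights_are_the_same_objects(self):
        head = LSCSHN()
        # one stack: the 3x3 tensors used for P3/P4/P5 are literally identical
        assert len(head.share_conv) == 2
        f = feats(size=160)
        out = head(f)
        # gradients from all three scales accumulate into the single tensors
        loss = sum((t ** 2).sum() for t in out["box"][1:])
        loss = loss + (out["box"][0] ** 2).sum()
        loss.backward()
        for sc in head.share_conv:
            assert sc.conv.weight.grad is not None
            assert np.abs(sc.conv.weight.grad).max() > 0

    def test_shared_gradient_equals_sum_of_per_scale_gradients(self):
        head = LSCSHN()
        f = feats(size=160)
        enhanced = head.shared_feature_stack(f)
        (sum((e ** 2).sum() for e in enhanced[1:]) + (enhanced[0] ** 2).sum()).backward()
        total = head.share_conv[0].conv.weight.grad.copy()
        per_scale = np.zeros_like(total)
        # rerun each scale alone through the same weights with fresh grads
        for idx in range(3):
            for p in head.parameters():
                p.grad = None
            y = head.compress[idx](f[idx])
            for sc in head.share_conv:
                y = sc(y)
            (y ** 2).sum().backward()
            per_scale += head.share_conv[0].conv.weight.grad
        np.testing.assert_allclose(total, per_scale, rtol=1e-4, atol=1e-5)

    def test_spatial_sizes_preserved(self):
        out = LSCSHN()(feats(size=640))
        sizes = [t.shape[2] for t in out["box"]]
        assert sizes == [80, 40, 20]

    def test_adding_fourth_scale_adds_no_shared_parameters(self):
        h3 = LSCSHN(ch=(64, 128, 256))
        h4 = LSCSHN(ch=(64, 128, 256, 256))
        delta = h4.fused_param_count() - h3.fused_param_count()
        cfg = h3.cfg
        compressor = 256 * cfg.hidden_width + 2 * cfg.hidden_width
        c4 = max(64 // 4, cfg.num_mask_coeffs)
        mask_tower = (256 * c4 + 2 * c4) + (9 * c4 * c4 + 2 * c4) + (
            c4 * cfg.num_mask_coeffs + cfg.num_mask_coeffs
        )
        scale_param = 1
        assert delta == compressor + mask_tower + scale_param


class TestDetectionHeads:
    def test_theta_one_passes_logits_through(self):
        head = LSCSHN()
        f = feats(size=160)
        enhanced = head.shared_feature_stack(f)
        raw = head.conv_reg(enhanced[0])
        scaled = head.scales[0](raw)
        np.testing.assert_array_equal(raw.data, scaled.data)

    def test_output_channel_counts(self):
        out = LSCSHN()(feats(size=160))
        assert out["box"][0].shape[1] == 4 * 16 == 64
        assert out["cls"][0].shape[1] == 3
        assert out["mc"][0].shape[1] == 32

    def test_per_scale_thetas_diverge_under_asymmetric_loss(self):
        head = LSCSHN()
        opt = ag.SGD(head.parameters(), lr=0.1, momentum=0.0)
        out = head(feats(size=160))
        # loss touches only two scales, with different magnitudes
        loss = (out["box"][0] ** 2).sum() * 3.0 + (out["box"][2] ** 2).sum() * 0.1
        opt.zero_grad()
        loss.backward()
        opt.step()
        thetas = [float(s.theta.data) for s in head.scales]
        assert thetas[0] != thetas[1] and thetas[0] != thetas[2]


class TestProtoAndMasks:
    def test_prototypes_at_stride4(self):
        cfg = HeadConfig()
        p3 = Tensor(RNG.normal(0, 1, (1, 64, 80, 80)).astype(np.float32))
        protos = Proto(64, cfg.proto_channels, cfg.num_mask_coeffs)(p3)
        assert protos.shape == (1, 32, 160, 160)  # 640 input -> stride 4

    def test_gradient_reaches_proto_from_mask_path(self):
        head = LSCSHN()
        out = head(feats(size=160))
        (out["proto"] ** 2).sum().backward()
        assert head.proto.cv1.conv.weight.grad is not None

    def test_zero_coeffs_give_half_everywhere(self):
        protos = RNG.normal(0, 1, (8, 16, 16)).astype(np.float32)
        m = assemble_instance_masks(protos, np.zeros(8, np.float32))
        np.testing.assert_allclose(m, 0.5, atol=1e-7)

    def test_saturated_single_prototype(self):
        disk = np.zeros((1, 16, 16), np.float32)
        disk[0, 4:12, 4:12] = 10.0
        m = assemble_instance_masks(disk, np.ones(1, np.float32))
        assert m[8, 8] > 0.99 and m[0, 0] == 0.5

    def test_linear_combination_matches_dot_product_oracle(self):
        protos = RNG.normal(0, 1, (6, 5, 5)).astype(np.float32)
        coeffs = RNG.normal(0, 1, (3, 6)).astype(np.float32)
        got = assemble_instance_masks(protos, coeffs)
        for i in range(3):
            want = np.zeros((5, 5))
            for k in range(6):
                want += coeffs[i, k] * protos[k]
            np.testing.assert_allclose(got[i], 1 / (1 + np.exp(-want)), atol=1e-5)


class TestPrintedLosses:
    def test_bbox_loss_examples(self):
        assert bbox_regression_loss([0, 0, 10, 10], [0, 0, 10, 10]) == 0.0
        assert bbox_regression_loss([0, 0, 10, 10], [1, 0, 10, 12]) == 5.0

    def test_bbox_loss_translation_invariant(self):
        gt = np.array([3.0, 4.0, 10.0, 12.0])
        pr = np.array([2.0, 5.0, 11.0, 12.5])
        assert bbox_regression_loss(gt, pr) == pytest.approx(
            bbox_regression_loss(gt + 7.0, pr + 7.0)
        )

    def test_classification_loss_examples(self):
        assert classification_loss([0, 1, 0], [0.0, 1.0, 0.0]) == pytest.approx(0.0, abs=1e-6)
        got = classification_loss([1, 0, 0], [1 / 3, 1 / 3, 1 / 3])
        assert got == pytest.approx(np.log(3), abs=1e-6)

    def test_classification_loss_matches_literal_sum(self):
        y = np.eye(3)[RNG.integers(0, 3, 10)]
        p = RNG.dirichlet(np.ones(3), 10)
        want = 0.0
        for o in range(10):
            for c in range(3):
                want -= y[o, c] * np.log(np.clip(p[o, c], 1e-7, 1 - 1e-7))
        assert classification_loss(y, p) == pytest.approx(want, rel=1e-9)

    def test_dfl_integer_target_one_hot(self):
        logits = np.full(16, -10.0)
        logits[7] = 10.0
        assert distribution_focal_loss(logits, 7.0) == pytest.approx(0.0, abs=1e-6)

    def test_dfl_bracketing_weights(self):
        from falsseg.lscshn import dfl_target_distribution
        q = dfl_target_distribution(2.7, 16)
        assert q[2] == pytest.approx(0.3) and q[3] == pytest.approx(0.7)
        assert q.sum() == pytest.approx(1.0)

    def test_dfl_matches_literal_double_sum(self):
        logits = RNG.normal(0, 1, 16)
        t = 5.3
        p = np.exp(logits - logits.max())
        p /= p.sum()
        q = np.zeros(16)
        q[5], q[6] = 0.7, 0.3
        want = -(np.log(p) * q).sum()
        assert distribution_focal_loss(logits, t) == pytest.approx(want, rel=1e-9)

    def test_dfl_out_of_range_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="clamping"):
            distribution_focal_loss(np.zeros(16), 99.0)

    def test_seg_loss_perfect_mask_is_zero(self):
        m = (RNG.random((8, 8)) > 0.5).astype(float)
        assert segmentation_loss(m, m) == pytest.approx(0.0, abs=1e-5)

    def test_seg_loss_closed_form_half_prediction(self):
        n = 64
        m = np.ones((8, 8))
        p = np.full((8, 8), 0.5)
        bce = np.log(2)
        dice = 1 - (2 * 0.5 * n + 1.0) / (0.5 * n + n + 1.0)
        assert segmentation_loss(p, m) == pytest.approx(bce + dice, rel=1e-6)

    def test_dice_term_bounded(self):
        for _ in range(10):
            p = RNG.random((6, 6))
            m = (RNG.random((6, 6)) > 0.5).astype(float)
            bce_plus_dice = segmentation_loss(p, m)
            p_clip = np.clip(p, 1e-7, 1 - 1e-7)
            bce = -(m * np.log(p_clip) + (1 - m) * np.log(1 - p_clip)).mean()
            dice = bce_plus_dice - bce
            assert -1e-9 <= dice <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            segmentation_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestHeadsShareOutputSchema:
    def test_same_keys_and_shapes(self):
        f = feats(size=160)
        out_a = SegmentHead(cfg=HeadConfig(num_mask_coeffs=32))(f)
        out_b = LSCSHN()(f)
        assert out_a.keys() == out_b.keys()
        for k in ("box", "cls"):
            for a, b in zip(out_a[k], out_b[k]):
                assert a.shape == b.shape
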