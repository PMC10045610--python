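"""Detector assembly: loss decomposition, zero-offset start, train/infer."""

import numpy as np
import pytest

from lesionnas.autodiff import Tensor
from lesionnas.detector import (
    DetectionRecord,
    DetectorConfig,
    build_detector,
    compute_loss,
    decode_boxes,
    encode_boxes,
    nms,
    train,
)
from lesionnas.fpn_paths import PathKind
from lesionnas.supernet import SubnetCode

from conftest import make_detection_dataset

TINY = dict(seed=0, anchor_scales=(2.0, 3.17, 5.04))


def identity_code(dag):
    return SubnetCode.from_dict(
        dag.edges,
        {**dict.fromkeys(dag.edges, PathKind.NULL),
         ("P", "O"): PathKind.SKIP},
    )


@pytest.fixture(scope="module")
def tiny_detector():
    det = build_detector(DetectorConfig.tiny(**TINY), "supernet")
    return det, identity_code(det.dag)


class TestConfig:
    def test_defaults_mirror_study_settings(self):
        cfg = DetectorConfig()
        assert (cfg.fpn_channels, cfg.head_channels) == (112, 112)
        assert cfg.fc_dim == 1024 and cfg.n_nodes == 5
        assert cfg.mu == pytest.approx(0.11)
        assert (cfg.lr, cfg.batch_size, cfg.epochs) == (0.001, 4, 30)
        assert cfg.deformable_stages == (3, 4, 5)

    def test_validation(self):
        with pytest.raises(ValueError):
            DetectorConfig(backbone="vgg")
        with pytest.raises(ValueError):
            DetectorConfig(mu=-0.1)

    def test_yaml_round_trip(self, tmp_path):
        cfg = DetectorConfig.tiny(**TINY)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        loaded = DetectorConfig.from_yaml(tmp_path / "cfg.yaml")
        assert loaded == cfg


class TestBoxCodec:
    def test_encode_decode_round_trip(self, rng):
        anchors = np.stack(
            [rng.uniform(0, 20, 8), rng.uniform(0, 20, 8),
             rng.uniform(25, 40, 8), rng.uniform(25, 40, 8)], axis=1
        )
        gts = anchors + rng.uniform(-3, 3, size=anchors.shape)
        gts[:, 2:] = np.maximum(gts[:, 2:], gts[:, :2] + 1)
        decoded = decode_boxes(anchors, encode_boxes(anchors, gts))
        assert np.allclose(decoded, gts, atol=1e-9)

    def test_nms_deduplicates_identical_boxes(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10], [30, 30, 40, 40.0]])
        scores = np.array([0.9, 0.8, 0.7])
        assert nms(boxes, scores, 0.5) == [0, 2]


class TestComputeLoss:
    def test_perfect_predictions_zero_weights(self):
        logits = Tensor([[10.0, -10.0], [-10.0, 10.0]])
        breakdown = compute_loss(
            [(logits, [0, 1])], [(Tensor(np.zeros((1, 4))), np.zeros((1, 4)))],
            mu=0.11, l1_params=[],
        )
        assert breakdown.total == pytest.approx(0.0, abs=1e-8)

    def test_mu_zero_drops_regulariser(self, rng):
        logits = Tensor(rng.normal(size=(3, 2)), requires_grad=True)
        w = Tensor(rng.normal(size=5), requires_grad=True)
        breakdown = compute_loss([(logits, [0, 1, 0])], [], mu=0.0, l1_params=[w])
        assert breakdown.total == breakdown.l_cls + breakdown.l_loc

    def test_unit_weights_give_mu_times_one(self):
        w = Tensor(np.ones(4), requires_grad=True)
        breakdown = compute_loss([], [], mu=0.11, l1_params=[w])
        assert breakdown.l1_reg == pytest.approx(1.0)
        assert breakdown.total == pytest.approx(0.11)

    def test_decomposition_identity_is_exact(self, rng):
        logits = Tensor(rng.normal(size=(4, 2)), requires_grad=True)
        pred = Tensor(rng.normal(size=(2, 4)), requires_grad=True)
        w = Tensor(rng.normal(size=7), requires_grad=True)
        b = compute_loss(
            [(logits, [0, 1, 1, 0])], [(pred, rng.normal(size=(2, 4)))],
            mu=0.11, l1_params=[w],
        )
        assert b.total == b.l_cls + b.l_loc + b.mu * b.l1_reg  # bitwise


class TestForward:
    def test_smoke_forward_returns_finite_records(self, tiny_detector):
        det, code = tiny_detector
        image = np.random.default_rng(0).uniform(0, 1, size=(64, 64))
        records = det.infer(image, score_threshold=0.0, code=code)
        for r in records:
            assert np.all(np.isfinite(r.box)) and 0.0 <= r.score <= 1.0
            x0, y0, x1, y1 = r.box
            assert 0 <= x0 < x1 <= 64 and 0 <= y0 < y1 <= 64

    def test_threshold_above_one_empty(self, tiny_detector):
        det, code = tiny_detector
        image = np.zeros((64, 64))
        assert det.infer(image, score_threshold=1.01, code=code) == []

    def test_image_size_contract(self, tiny_detector):
        det, code = tiny_detector
        with pytest.raises(ValueError):
            det.pyramid(np.zeros((50, 50)), code)

    def test_zero_offset_start_equals_plain_conv_twin(self, tiny_detector):
        """At init all offsets are zero, so deformable == regular forward."""
        det, code = tiny_detector
        image = np.random.default_rng(1).uniform(0, 1, size=(64, 64))
        deform_out = det.pyramid(image, code)
        layers = [stage[1] for stage in det.backbone.stages.values()]
        flags = [l.deformable for l in layers]
        try:
            for l in layers:
                l.deformable = False  # same weights, plain sampling
            plain_out = det.pyramid(image, code)
        finally:
            for l, f in zip(layers, flags):
                l.deformable = f
        for i in (2, 3, 4, 5):
            assert np.allclose(deform_out[i].array, plain_out[i].array)

    def test_roi_head_shape_contract(self, tiny_detector):
        det, code = tiny_detector
        image = np.random.default_rng(2).uniform(0, 1, size=(64, 64))
        pyr = det.pyramid(image, code)
        rois = np.array([[4.0, 4.0, 24.0, 28.0], [10.0, 2.0, 50.0, 60.0]])
        feats = det._roi_features(pyr, rois)
        bh, bw = det.config.roi_bins
        assert feats.shape == (2, det.config.fpn_channels * bh * bw)
        cls_logits, reg = det._head(feats)
        assert cls_logits.shape == (2, det.config.num_classes + 1)
        assert reg.shape == (2, 4)


class TestLossContracts:
    def test_loss_finite_and_decomposed(self, tiny_detector, tiny_dataset):
        det, code = tiny_detector
        loss = det.loss_on_batch(
            tiny_dataset[:2], code=code, rng=np.random.default_rng(0)
        )
        assert np.isfinite(loss.total) and loss.total >= 0
        assert loss.total == loss.l_cls + loss.l_loc + loss.mu * loss.l1_reg
        assert loss.mu == pytest.approx(0.11)

    def test_loss_deterministic_given_rng(self, tiny_detector, tiny_dataset):
        det, code = tiny_detector
        a = det.loss_on_batch(tiny_dataset[:2], code=code,
                              rng=np.random.default_rng(3))
        b = det.loss_on_batch(tiny_dataset[:2], code=code,
                              rng=np.random.default_rng(3))
        assert a.total == b.total

    def test_empty_batch_rejected(self, tiny_detector):
        det, code = tiny_detector
        with pytest.raises(ValueError):
            det.loss_on_batch([], code=code)

    def test_lesion_free_image_still_trains(self, tiny_detector):
        det, code = tiny_detector
        image = np.random.default_rng(4).uniform(0, 1, size=(64, 64))
        loss = det.loss_on_batch([(image, [])], code=code,
                                 rng=np.random.default_rng(0))
        assert np.isfinite(loss.total)


class TestTraining:
    def test_empty_training_set_rejected(self, tiny_detector):
        det, code = tiny_detector
        with pytest.raises(ValueError):
            train(det, [], np.random.default_rng(0), steps=1, code=code)

    def test_curve_length_and_decomposition_per_step(self, tiny_dataset):
        det = build_detector(DetectorConfig.tiny(**TINY), "supernet")
        code = identity_code(det.dag)
        curve = train(det, tiny_dataset[:4], np.random.default_rng(0),
                      steps=5, lr=0.01, batch_size=2, code=code)
        assert len(curve) == 5
        for step in curve:
            assert step.total == step.l_cls + step.l_loc + step.mu * step.l1_reg

    def test_same_seed_identical_curves(self, tiny_dataset):
        curves = []
        for _ in range(2):
            det = build_detector(DetectorConfig.tiny(**TINY), "supernet")
            code = identity_code(det.dag)
            curve = train(det, tiny_dataset[:4], np.random.default_rng(9),
                          steps=4, lr=0.01, batch_size=2, code=code)
            curves.append([c.total for c in curve])
        assert curves[0] == curves[1]

    def test_overfit_smoke_loss_drops(self, tiny_dataset):
        """A few hundred steps on 10 images cut the loss to < 20%."""
        det = build_detector(DetectorConfig.tiny(**TINY), "supernet")
        code = SubnetCode.from_dict(
            det.dag.edges,
            {("P", "X1"): PathKind.TOP_DOWN, ("P", "O"): PathKind.SKIP,
             ("X1", "O"): PathKind.SKIP},
        )
        curve = train(det, tiny_dataset, np.random.default_rng(7), steps=300,
                      lr=0.05, batch_size=2, code=code, augment_data=False)
        start = np.mean([c.total for c in curve[:10]])
        end = np.mean([c.total for c in curve[-10:]])
        assert end < 0.2 * start


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_detector, tmp_path):
        det, code = tiny_detector
        path = tmp_path / "weights.npz"
        det.save_weights(path)
        other = build_detector(DetectorConfig.tiny(seed=123, anchor_scales=(2.0, 3.17, 5.04)), "supernet")
        image = np.random.default_rng(5).uniform(0, 1, size=(64, 64))
        before = other.pyramid(image, code)[2].array.copy()
        other.load_weights(path)
        after = other.pyramid(image, code)[2].array
        assert not np.allclose(before, after)
        assert np.allclose(after, det.pyramid(image, code)[2].array)


def test_detection_record_validation():
    with pytest.raises(ValueError):
        DetectionRecord(box=(5, 5, 5, 10), score=0.5)


def test_resnet50_shape_construction():
    """The full-scale backbone builds with the documented stage widths."""
    cfg = DetectorConfig(backbone="resnet50", fpn_channels=8, head_channels=8,
                         fc_dim=16, n_nodes=1)
    det = build_detector(cfg, "supernet")
    assert det.backbone.out_channels == {2: 256, 3: 512, 4: 1024, 5: 2048}
    blocks = det.backbone.stages
    assert [len(blocks[s]) for s in (2, 3, 4, 5)] == [3, 4, 6, 3]
    deformable = [b.conv3.deformable for b in blocks[4]]
    assert all(deformable)
    assert not any(b.conv3.deformable for b in blocks[2])
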