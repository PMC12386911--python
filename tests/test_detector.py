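"""Detector assembly, target assignment, loss composition, decoding and
checkpointing."""

import dataclasses

import numpy as np
import pytest

from crowndetect.boxes import AxisBox, SDIoUParams
from crowndetect.detector import (DetectorConfig, TrainConfig, assign_targets,
                                  build_detector, compute_loss, letterbox,
                                  load_checkpoint, nms, predict,
                                  save_checkpoint, unletterbox_box)
from crowndetect.nn import SGD, Tensor

TINY = DetectorConfig(input_size=64, base_channels=(4, 8, 12, 16, 20))


def rand_image(rng, size):
    return (rng.random((size, size, 3)) * 255).astype(np.uint8)


class TestBuild:
    def test_three_level_stride_arithmetic(self):
        cfg = DetectorConfig(input_size=640)
        model = build_detector(cfg, seed=0)
        model.eval()
        preds = model(Tensor(np.zeros((1, 3, 640, 640), dtype=np.float32)))
        assert [p.shape[2:] for p in preds] == [(80, 80), (40, 40), (20, 20)]
        assert all(p.shape[1] == 4 + cfg.n_classes for p in preds)

    def test_width_multiple_scales_parameters(self):
        full = sum(p.data.size for p in build_detector(TINY, 0).parameters())
        half = sum(p.data.size for p in build_detector(
            dataclasses.replace(TINY, width_multiple=0.5), 0).parameters())
        assert half < full

    def test_input_size_must_match_stride(self):
        with pytest.raises(ValueError):
            DetectorConfig(input_size=100)

    def test_eval_forward_deterministic(self):
        model = build_detector(TINY, seed=3)
        model.eval()
        x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64),
                                                   dtype=np.float32))
        np.testing.assert_array_equal(model(x)[0].data, model(x)[0].data)

    @pytest.mark.parametrize("use_strip,use_caa,use_sdiou", [
        (s, c, d) for s in (True, False) for c in (True, False)
        for d in (True, False)
    ])
    def test_ablation_toggles_build_and_train_one_step(self, use_strip,
                                                       use_caa, use_sdiou):
        cfg = dataclasses.replace(TINY, use_strip=use_strip, use_caa=use_caa,
                                  use_sdiou=use_sdiou)
        model = build_detector(cfg, seed=1)
        rng = np.random.default_rng(0)
        x = Tensor(rng.random((2, 3, 64, 64), dtype=np.float32))
        tgts = [assign_targets([AxisBox(32, 32, 20, 20)], [0], cfg)
                for _ in range(2)]
        loss, comps = compute_loss(model(x), tgts, cfg)
        opt = SGD(model.parameters(), lr=0.01, momentum=0.8)
        opt.zero_grad()
        loss.backward()
        opt.step()
        assert np.isfinite(loss.item())

    def test_one_step_touches_every_parameter_group(self):
        model = build_detector(TINY, seed=2)
        rng = np.random.default_rng(1)
        x = Tensor(rng.random((2, 3, 64, 64), dtype=np.float32))
        tgts = [assign_targets([AxisBox(20, 20, 16, 16), AxisBox(50, 50, 30, 40)],
                               [0, 1], TINY) for _ in range(2)]
        loss, _ = compute_loss(model(x), tgts, TINY)
        loss.backward()
        missing = [n for n, p in model.named_parameters() if p.grad is None]
        assert missing == []


class TestAssignment:
    def test_centered_box_claims_cells_at_fine_stride(self):
        cfg = TINY
        tg = assign_targets([AxisBox(32, 32, 24, 24)], [0], cfg)
        assert len(tg[0]["gy"]) >= 1            # stride 8 level
        assert all(len(t["gy"]) == 0 for t in tg[1:])

    def test_empty_truth_all_background(self):
        tg = assign_targets([], [], TINY)
        assert all(len(t["gy"]) == 0 for t in tg)

    def test_disjoint_boxes_claim_disjoint_cells(self):
        """Assigned cell sets agree with brute-force center-in-region
        enumeration and never overlap for disjoint boxes."""
        cfg = TINY
        b1, b2 = AxisBox(16, 16, 12, 12), AxisBox(48, 48, 12, 12)
        tg = assign_targets([b1, b2], [0, 1], cfg)
        for li, stride in enumerate(cfg.strides):
            cells = list(zip(tg[li]["gy"].tolist(), tg[li]["gx"].tolist(),
                             tg[li]["cls"].tolist()))
            seen = {(gy, gx) for gy, gx, _ in cells}
            assert len(seen) == len(cells)
            # brute force: every cell whose center is in a central half
            # must be assigned to that box's class
            n = cfg.input_size // stride
            for gy in range(n):
                for gx in range(n):
                    cxc = (gx + 0.5) * stride
                    cyc = (gy + 0.5) * stride
                    for box, cls in ((b1, 0), (b2, 1)):
                        inside = (abs(cxc - box.cx) <= box.w / 4
                                  and abs(cyc - box.cy) <= box.h / 4)
                        if inside and li == 0:   # both boxes sit at stride 8
                            assert (gy, gx, cls) in cells

    def test_out_of_frame_box_clipped(self):
        tg = assign_targets([AxisBox(2, 2, 20, 20)], [0], TINY)
        total = sum(len(t["gy"]) for t in tg)
        assert total >= 1
        for t in tg:
            for cx, cy, w, h in t["boxes"]:
                assert cx - w / 2 >= -1e-9 and cy - h / 2 >= -1e-9


class TestLoss:
    def _perfect_setup(self):
        """Predictions whose decoded boxes coincide with the target."""
        cfg = TINY
        box = AxisBox(32, 32, 16, 16)
        tgts = [assign_targets([box], [0], cfg)]
        preds = []
        for li, s in enumerate(cfg.strides):
            n = cfg.input_size // s
            p = np.zeros((1, 4 + cfg.n_classes, n, n), dtype=np.float32)
            p[:, 4:] = -20.0                     # background everywhere
            lvl = tgts[0][li]
            for j in range(len(lvl["gy"])):
                gy, gx = lvl["gy"][j], lvl["gx"][j]
                cx, cy, w, h = lvl["boxes"][j]
                tx = (cx / s - gx + 0.5) / 2.0   # invert the decode transform
                ty = (cy / s - gy + 0.5) / 2.0
                p[0, 0, gy, gx] = np.log(tx / (1 - tx))
                p[0, 1, gy, gx] = np.log(ty / (1 - ty))
                p[0, 2, gy, gx] = np.log(w / s)
                p[0, 3, gy, gx] = np.log(h / s)
                p[0, 4 + lvl["cls"][j], gy, gx] = 20.0
            preds.append(Tensor(p))
        return cfg, preds, tgts

    def test_box_component_zero_at_perfect_prediction(self):
        cfg, preds, tgts = self._perfect_setup()
        _, comps = compute_loss(preds, tgts, cfg)
        assert comps["box"] == pytest.approx(0.0, abs=1e-5)
        assert comps["cls"] == pytest.approx(0.0, abs=1e-6)

    def test_box_weight_linearity(self):
        rng = np.random.default_rng(0)
        cfg = TINY
        model = build_detector(cfg, seed=0)
        model.eval()
        x = Tensor(rng.random((1, 3, 64, 64), dtype=np.float32))
        tgts = [assign_targets([AxisBox(32, 32, 16, 16)], [0], cfg)]
        preds = model(x)
        _, c1 = compute_loss(preds, tgts, cfg)
        cfg2 = dataclasses.replace(cfg, box_loss_weight=2 * cfg.box_loss_weight)
        t1, _ = compute_loss(preds, tgts, cfg)
        t2, _ = compute_loss(model(x), tgts, cfg2)
        delta = t2.item() - t1.item()
        assert delta == pytest.approx(cfg.box_loss_weight * c1["box"], rel=1e-5)

    def test_no_assigned_cells_classification_only(self):
        cfg = TINY
        model = build_detector(cfg, seed=0)
        model.eval()
        x = Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
        total, comps = compute_loss(model(x), [assign_targets([], [], cfg)], cfg)
        assert comps["box"] == 0.0
        assert comps["cls"] > 0.0
        assert np.isfinite(total.item())

    def test_plain_iou_toggle_changes_box_loss(self):
        rng = np.random.default_rng(0)
        cfg = TINY
        model = build_detector(cfg, seed=0)
        model.eval()
        x = Tensor(rng.random((1, 3, 64, 64), dtype=np.float32))
        tgts = [assign_targets([AxisBox(20, 40, 10, 14)], [1], cfg)]
        _, with_sdiou = compute_loss(model(x), tgts, cfg)
        cfg_iou = dataclasses.replace(cfg, use_sdiou=False)
        _, with_iou = compute_loss(model(x), tgts, cfg_iou)
        assert with_sdiou["box"] != pytest.approx(with_iou["box"])


class TestDecoding:
    def test_letterbox_roundtrip_within_one_pixel(self):
        rng = np.random.default_rng(0)
        img = rand_image(rng, 100)[:80]          # 80 x 100 non-square
        _, scale, pad = letterbox(img, 64)
        box = AxisBox(40, 30, 22, 16)
        fwd = AxisBox(box.cx * scale + pad[0], box.cy * scale + pad[1],
                      box.w * scale, box.h * scale)
        back = unletterbox_box(fwd, scale, pad)
        assert abs(back.cx - box.cx) <= 1.0
        assert abs(back.cy - box.cy) <= 1.0
        assert abs(back.w - box.w) <= 1.0
        assert abs(back.h - box.h) <= 1.0

    def test_letterbox_output_shape_and_range(self):
        rng = np.random.default_rng(1)
        chw, scale, pad = letterbox(rand_image(rng, 100), 64)
        assert chw.shape == (3, 64, 64)
        assert 0.0 <= chw.min() and chw.max() <= 1.0

    def test_nms_keeps_one_of_identical_boxes(self):
        boxes = [AxisBox(10, 10, 8, 8), AxisBox(10, 10, 8, 8)]
        assert nms(boxes, [0.9, 0.8], 0.45) == [0]

    def test_nms_keeps_distant_boxes(self):
        boxes = [AxisBox(10, 10, 8, 8), AxisBox(50, 50, 8, 8)]
        assert sorted(nms(boxes, [0.9, 0.8], 0.45)) == [0, 1]

    def test_conf_threshold_one_gives_empty_output(self):
        cfg = dataclasses.replace(TINY, conf_threshold=1.0)
        model = build_detector(cfg, seed=0)
        rng = np.random.default_rng(2)
        assert predict(rand_image(rng, 64), model, cfg) == []

    def test_detections_clipped_to_image(self):
        cfg = dataclasses.replace(TINY, conf_threshold=0.01)
        model = build_detector(cfg, seed=5)
        rng = np.random.default_rng(3)
        img = rand_image(rng, 96)
        for d in predict(img, model, cfg):
            x1, y1, x2, y2 = d.box.corners
            assert x1 >= 0 and y1 >= 0 and x2 <= 96 and y2 <= 96
            assert 0.0 <= d.confidence <= 1.0


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        cfg = TINY
        model = build_detector(cfg, seed=4)
        model.eval()
        rng = np.random.default_rng(0)
        img = rand_image(rng, 64)
        path = tmp_path / "model.npz"
        save_checkpoint(model, cfg, path, {"epoch": 3})
        model2, cfg2, extra = load_checkpoint(path)
        assert extra["epoch"] == 3
        assert cfg2 == cfg
        ecfg = dataclasses.replace(cfg, conf_threshold=0.01)
        d1 = predict(img, model, ecfg)
        d2 = predict(img, model2, ecfg)
        assert len(d1) == len(d2)
        for a, b in zip(d1, d2):
            assert a.confidence == pytest.approx(b.confidence, abs=1e-7)

    def test_version_guard(self, tmp_path):
        import json
        path = tmp_path / "bad.npz"
        meta = {"version": 99, "config": {}, "extra": {}}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(),
                                              dtype=np.uint8))
        with pytest.raises(ValueError, match="version"):
            load_checkpoint(path)


class TestTrainConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(momentum=1.0)
        # study regime defaults
        tc = TrainConfig()
        assert (tc.learning_rate, tc.batch_size, tc.epochs, tc.momentum) == \
            (0.01, 16, 300, 0.8)
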