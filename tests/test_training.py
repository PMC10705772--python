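"""Augmentation consistency, anchor assignment, losses, and the train loop."""

import dataclasses

import numpy as np
import pytest

from psaseg.augment import AugmentationSpec, augment_sample
from psaseg.cocoio import mask_bbox
from psaseg.model import AnchorSet, box_iou_matrix, encode_boxes
from psaseg.nn import Tensor
from psaseg.synth import SceneRecord, SynthConfig, generate_scene
from psaseg.train import (TrainConfig, assign_targets, compute_losses,
                          mine_hard_negatives, train_loop)


@pytest.fixture(scope="module")
def scene():
    return generate_scene(SynthConfig(image_size=(64, 128), instance_range=(1, 2),
                                      blob_radius_range=(10, 16),
                                      occluder_probability=0.0), 7)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def test_zero_probability_pipeline_is_bitwise_identity(scene):
    out = augment_sample(scene, AugmentationSpec().zeroed(), 0)
    np.testing.assert_array_equal(out.image, scene.image)
    for a, b in zip(out.masks, scene.masks):
        np.testing.assert_array_equal(a, b)
    np.testing.assert_array_equal(out.boxes, scene.boxes)


def test_geometric_transform_keeps_tight_box_invariant(scene):
    spec = AugmentationSpec().zeroed()
    spec = dataclasses.replace(spec, p_shift_scale_rotate=1.0)
    for seed in range(10):
        out = augment_sample(scene, spec, seed)
        assert not np.array_equal(out.image, scene.image)
        for m, b, a in zip(out.masks, out.boxes, out.areas):
            np.testing.assert_array_equal(mask_bbox(m), b)
            assert int(m.sum()) == int(a)


def test_jpeg_compression_changes_pixels_but_not_geometry(scene):
    spec = dataclasses.replace(AugmentationSpec().zeroed(), p_jpeg=1.0)
    out = augment_sample(scene, spec, 3)
    assert out.image.shape == scene.image.shape
    assert not np.array_equal(out.image, scene.image)
    for a, b in zip(out.masks, scene.masks):
        np.testing.assert_array_equal(a, b)


def test_every_photometric_op_produces_valid_uint8(scene):
    for field in ("p_brightness_contrast", "p_rgb_shift", "p_hsv_shift",
                  "p_channel_shuffle", "p_median_blur"):
        spec = dataclasses.replace(AugmentationSpec().zeroed(), **{field: 1.0})
        out = augment_sample(scene, spec, 11)
        assert out.image.dtype == np.uint8
        assert out.image.shape == scene.image.shape


# ---------------------------------------------------------------------------
# Target assignment
# ---------------------------------------------------------------------------

def _grid_anchors(n=20, rng=None):
    rng = rng or np.random.default_rng(0)
    boxes = np.stack([rng.uniform(10, 110, n), rng.uniform(10, 50, n),
                      rng.uniform(8, 30, n), rng.uniform(8, 30, n)], axis=1)
    return AnchorSet(boxes=boxes, level_sizes=[(1, n)], num_per_cell=1)


def test_anchor_identical_to_gt_is_positive():
    a = AnchorSet(boxes=np.array([[20.0, 20.0, 10.0, 10.0]]),
                  level_sizes=[(1, 1)], num_per_cell=1)
    labels, matched = assign_targets(a, np.array([[15.0, 15.0, 25.0, 25.0]]))
    assert labels[0] == 1 and matched[0] == 0


def test_anchor_in_iou_band_is_ignored_unless_forced():
    # two anchors on one gt: the better one is force-matched, the other
    # (IoU 0.45, between 0.4 and 0.5) stays ignored
    gt = np.array([[0.0, 0.0, 20.0, 20.0]])
    a = AnchorSet(boxes=np.array([[10.0, 10.0, 20.0, 20.0],
                                  [10.0, 10.0 + 7.6, 20.0, 20.0]]),
                  level_sizes=[(1, 2)], num_per_cell=1)
    iou = box_iou_matrix(a.corner_form(), gt)
    assert 0.4 < iou[1, 0] < 0.5
    labels, _ = assign_targets(a, gt)
    assert labels[0] == 1 and labels[1] == -1


def test_empty_ground_truth_makes_all_anchors_negative():
    labels, matched = assign_targets(_grid_anchors(), np.zeros((0, 4)))
    assert (labels == 0).all() and (matched == -1).all()


def test_assignment_matches_brute_force_oracle_50_seeds():
    for seed in range(50):
        rng = np.random.default_rng(1000 + seed)
        anchors = _grid_anchors(20, rng)
        g = int(rng.integers(1, 4))
        x1 = rng.uniform(0, 90, g); y1 = rng.uniform(0, 40, g)
        gt = np.stack([x1, y1, x1 + rng.uniform(10, 40, g),
                       y1 + rng.uniform(10, 30, g)], axis=1)
        labels, matched = assign_targets(anchors, gt)
        # oracle: all-pairs IoU with plain loops
        corners = anchors.corner_form()
        want = np.full(20, -1)
        wmatch = np.zeros(20, dtype=int)
        for i in range(20):
            best, bg = 0.0, 0
            for j in range(g):
                xx1 = max(corners[i, 0], gt[j, 0]); yy1 = max(corners[i, 1], gt[j, 1])
                xx2 = min(corners[i, 2], gt[j, 2]); yy2 = min(corners[i, 3], gt[j, 3])
                inter = max(xx2 - xx1, 0) * max(yy2 - yy1, 0)
                ua = ((corners[i, 2] - corners[i, 0]) * (corners[i, 3] - corners[i, 1])
                      + (gt[j, 2] - gt[j, 0]) * (gt[j, 3] - gt[j, 1]) - inter)
                v = inter / ua
                if v > best:
                    best, bg = v, j
            want[i] = 1 if best >= 0.5 else (0 if best < 0.4 else -1)
            wmatch[i] = bg
        claimed = []
        for j in range(g):
            ious = [0.0] * 20
            for i in range(20):
                xx1 = max(corners[i, 0], gt[j, 0]); yy1 = max(corners[i, 1], gt[j, 1])
                xx2 = min(corners[i, 2], gt[j, 2]); yy2 = min(corners[i, 3], gt[j, 3])
                inter = max(xx2 - xx1, 0) * max(yy2 - yy1, 0)
                ua = ((corners[i, 2] - corners[i, 0]) * (corners[i, 3] - corners[i, 1])
                      + (gt[j, 2] - gt[j, 0]) * (gt[j, 3] - gt[j, 1]) - inter)
                ious[i] = inter / ua
            for b in sorted(range(20), key=lambda i: -ious[i]):
                if b not in claimed:
                    want[b] = 1
                    wmatch[b] = j
                    claimed.append(b)
                    break
        np.testing.assert_array_equal(labels, want)
        pos = np.flatnonzero(want == 1)
        np.testing.assert_array_equal(matched[pos], wmatch[pos])
        # every gt has at least one positive
        assert set(range(g)) <= set(matched[pos].tolist())


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _toy_out_and_record(perfect: bool):
    h, w, hp, wp = 32, 32, 8, 8
    mask = np.zeros((h, w), np.uint8)
    mask[8:24, 8:24] = 1
    rec = SceneRecord(image=np.zeros((h, w, 3), np.uint8), masks=[mask],
                      boxes=np.array([[8.0, 8.0, 24.0, 24.0]]),
                      areas=np.array([256]), instance_ids=[1])
    anchors = AnchorSet(boxes=np.array([[16.0, 16.0, 16.0, 16.0],
                                        [4.0, 4.0, 6.0, 6.0],
                                        [28.0, 28.0, 6.0, 6.0]]),
                        level_sizes=[(1, 3)], num_per_cell=1)
    big = 20.0
    if perfect:
        cls = np.array([[0.0, big], [big, 0.0], [big, 0.0]])
        box = np.zeros((3, 4))
        box[0] = encode_boxes(rec.boxes, anchors.boxes[:1])[0]
        coef = np.array([[1.0], [0.0], [0.0]])
        proto = np.where(mask[::4, ::4] > 0, big, -big)[None]
    else:
        cls = np.zeros((3, 2))
        box = np.zeros((3, 4))
        coef = np.zeros((3, 1))
        proto = np.zeros((1, hp, wp))
    out = dict(cls=Tensor(cls), box=Tensor(box), coef=Tensor(coef),
               protos=Tensor(proto[None][0][None]), anchors=anchors,
               image_size=(h, w))
    # protos tensor must be (N,k,hp,wp)
    out["protos"] = Tensor(proto[None])
    out["cls"] = Tensor(cls[None])
    out["box"] = Tensor(box[None])
    out["coef"] = Tensor(coef[None])
    return out, rec


def test_perfect_predictions_give_near_zero_total_loss():
    out, rec = _toy_out_and_record(perfect=True)
    losses = compute_losses(out, [rec], TrainConfig())
    assert float(losses["total"].data) < 0.01


def test_losses_nonnegative_and_finite_for_uniform_outputs():
    out, rec = _toy_out_and_record(perfect=False)
    losses = compute_losses(out, [rec], TrainConfig())
    for t in losses.values():
        v = float(t.data)
        assert np.isfinite(v) and v >= 0
    # uniform two-class logits: each selected anchor contributes ln 2
    npos, nsel = 1, 1 + 2          # one positive, OHEM keeps both negatives
    np.testing.assert_allclose(float(losses["cls"].data),
                               nsel * np.log(2) / npos, rtol=1e-5)


def test_hard_negative_mining_matches_sort_oracle():
    logits = np.array([[0.0, 5.0],    # high bg loss
                       [3.0, 0.0],    # low bg loss
                       [0.0, 1.0],    # medium
                       [0.0, 9.0]])   # highest
    neg = np.array([0, 1, 2, 3])
    got = mine_hard_negatives(logits, neg, 2)
    # oracle: sort by -log softmax(bg) descending
    losses = [-(l[0] - np.log(np.exp(l[0]) + np.exp(l[1]))) for l in logits]
    want = np.argsort([-v for v in losses], kind="stable")[:2]
    np.testing.assert_array_equal(np.sort(got), np.sort(neg[want]))
    assert set(got) == {0, 3}


# ---------------------------------------------------------------------------
# Train loop
# ---------------------------------------------------------------------------

def _small_setup(lr=0.01, epochs=2, **kw):
    from psaseg.config import build_model, tiny_experiment
    cfg = tiny_experiment(seed=3, epochs=epochs, lr=lr)
    cfg.train = dataclasses.replace(cfg.train, **kw)
    from psaseg.synth import tiny_scene_set
    return build_model(cfg), cfg, tiny_scene_set(4, seed=3)


def test_zero_learning_rate_leaves_weights_unchanged():
    model, cfg, scenes = _small_setup(lr=0.0, epochs=2, weight_decay=0.0)
    before = [p.data.copy() for p in model.parameters()]
    train_loop(scenes, model, cfg.train)
    for b, p in zip(before, model.parameters()):
        np.testing.assert_array_equal(b, p.data)


def test_same_seed_gives_identical_loss_logs():
    model1, cfg, scenes = _small_setup(epochs=3)
    _, log1 = train_loop(scenes, model1, cfg.train)
    model2, cfg2, scenes2 = _small_setup(epochs=3)
    _, log2 = train_loop(scenes2, model2, cfg2.train)
    assert log1 == log2


def test_nonfinite_loss_aborts_with_diagnostic():
    model, cfg, scenes = _small_setup(epochs=1)
    model.protonet.final.w.data[:] = np.nan
    with pytest.raises(RuntimeError, match="non-finite"):
        train_loop(scenes, model, cfg.train)


def test_empty_dataset_rejected(tiny_model_and_cfg):
    model, cfg = tiny_model_and_cfg
    with pytest.raises(ValueError, match="empty"):
        train_loop([], model, cfg.train)


def test_negative_threshold_must_stay_below_positive():
    with pytest.raises(ValueError, match="below"):
        TrainConfig(pos_iou=0.4, neg_iou=0.5)
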