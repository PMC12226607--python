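"""Segmentation contract: class weights, weighted CE, confidence maps,
Dice scoring and head expansion."""

import numpy as np
import pytest
from scipy.special import log_softmax as sp_log_softmax

from replayseg.segmentation import (AnnotatedImage, ClassRegistry,
                                    SegmentationNet, class_frequency_weights,
                                    dice_score, predict_with_confidence,
                                    seg_forward, weighted_cross_entropy,
                                    load_segmenter, save_segmenter, SegOutputs)


def _item(mask, class_id, hw=8):
    img = np.zeros((hw, hw, 3))
    return AnnotatedImage(image=img, class_id=class_id, mask=mask)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def test_registry_rejects_overlap_and_reserved_ids():
    with pytest.raises(ValueError):
        ClassRegistry([{1, 2, 3}, {3, 4}])
    with pytest.raises(ValueError):
        ClassRegistry([{0, 1}])
    with pytest.raises(ValueError):
        ClassRegistry([{1}, {255}])
    reg = ClassRegistry([{1, 2, 3}, {4, 5}])
    assert reg.known_classes(0) == [1, 2, 3]
    assert reg.known_classes(1) == [1, 2, 3, 4, 5]


# ---------------------------------------------------------------------------
# Class-frequency weights
# ---------------------------------------------------------------------------

def test_equal_pixel_counts_give_equal_unit_weights():
    full = np.ones((8, 8), dtype=bool)
    reg = ClassRegistry([{1, 2}])
    w = class_frequency_weights([_item(full, 1), _item(full, 2)], reg)
    assert w[1] == pytest.approx(w[2])
    assert w[1] == pytest.approx(1.0)


def test_inverse_frequency_ratio():
    reg = ClassRegistry([{1, 2}])
    m1 = np.zeros((30, 30), dtype=bool)
    m1[:27, :30] = True            # 810 px for class 1
    m2 = np.zeros((30, 30), dtype=bool)
    m2[:3, :30] = True             # 90 px for class 2 -> 9x fewer
    w = class_frequency_weights([_item(m1, 1, 30), _item(m2, 2, 30)], reg)
    assert w[2] / w[1] == pytest.approx(9.0, rel=0.02)


def test_single_class_dataset_normalizes_to_one():
    reg = ClassRegistry([{1}])
    full = np.ones((8, 8), dtype=bool)
    w = class_frequency_weights([_item(full, 1)], reg)
    assert w[1] == pytest.approx(1.0)


def test_absent_class_gets_max_weight(caplog):
    reg = ClassRegistry([{1, 2}])
    m = np.zeros((8, 8), dtype=bool)
    m[:2] = True
    with caplog.at_level("INFO"):
        w = class_frequency_weights([_item(m, 1)], reg)
    present_max = max(w[0], w[1])
    assert w[2] == present_max
    assert "absent" in caplog.text


# ---------------------------------------------------------------------------
# Weighted cross-entropy
# ---------------------------------------------------------------------------

def test_uniform_logits_two_channels_give_ln2():
    logits = np.zeros((4, 4, 2))
    labels = np.zeros((4, 4), dtype=int)
    assert weighted_cross_entropy(logits, labels, np.ones(2)) == pytest.approx(
        np.log(2), abs=1e-6)


def test_perfect_prediction_drives_loss_to_zero():
    logits = np.zeros((4, 4, 2))
    logits[..., 1] = 50.0
    labels = np.ones((4, 4), dtype=int)
    assert weighted_cross_entropy(logits, labels, np.ones(2)) < 1e-8


def test_all_ignored_pixels_give_zero_with_warning(caplog):
    logits = np.zeros((2, 2, 3))
    labels = np.full((2, 2), 255)
    with caplog.at_level("WARNING"):
        assert weighted_cross_entropy(logits, labels, np.ones(3)) == 0.0
    assert "ignored" in caplog.text


def test_uniform_weights_match_unweighted_oracle(rng):
    """With unit weights the loss equals the plain mean cross-entropy
    computed independently via scipy's log_softmax."""
    logits = rng.normal(size=(6, 5, 4))
    labels = rng.integers(0, 4, size=(6, 5))
    labels[0, 0] = 255
    got = weighted_cross_entropy(logits, labels, np.ones(4))
    lp = sp_log_softmax(logits, axis=2)
    keep = labels != 255
    expected = -lp[keep, labels[keep]].mean()
    assert got == pytest.approx(expected, rel=1e-5)


def test_weight_scaling_is_linear(rng):
    logits = rng.normal(size=(4, 4, 3))
    labels = rng.integers(0, 3, size=(4, 4))
    base = weighted_cross_entropy(logits, labels, np.ones(3))
    double = weighted_cross_entropy(logits, labels, 2 * np.ones(3))
    assert double == pytest.approx(2 * base, rel=1e-5)


def test_out_of_range_label_rejected():
    with pytest.raises(ValueError):
        weighted_cross_entropy(np.zeros((2, 2, 2)), np.full((2, 2), 5), np.ones(2))


# ---------------------------------------------------------------------------
# Confidence maps
# ---------------------------------------------------------------------------

def _outputs(logits, class_ids):
    return SegOutputs(logits=logits, embeddings=[], encoder_feature=np.zeros(1),
                      class_ids=class_ids)


def test_two_channel_confidence_closed_form():
    logits = np.zeros((1, 1, 2))
    logits[0, 0] = [10.0, 0.0]
    labels, conf = predict_with_confidence(_outputs(logits, [0, 1]))
    assert labels[0, 0] == 0
    assert conf[0, 0] == pytest.approx(1 / (1 + np.exp(-10)), abs=1e-9)


def test_uniform_logits_confidence_is_reciprocal_channels():
    k = 4
    labels, conf = predict_with_confidence(_outputs(np.zeros((2, 2, k)),
                                                    [0, 1, 2, 3]))
    assert np.allclose(conf, 1 / k)
    assert np.all(labels == 0)  # ties break toward the lowest channel


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,g,expected", [
    ("identical", None, 1.0),
    ("disjoint", None, 0.0),
    ("overlap2of4", None, 0.5),
])
def test_dice_closed_forms(p, g, expected):
    a = np.zeros((4, 4), dtype=bool)
    b = np.zeros((4, 4), dtype=bool)
    if p == "identical":
        a[:2] = b[:2] = True
    elif p == "disjoint":
        a[:1] = True
        b[3:] = True
    else:
        a[0, :4] = True          # |P| = 4
        b[0, 2:] = b[1, :2] = True  # |G| = 4, overlap 2
    assert dice_score(a, b) == expected


def test_dice_empty_conventions():
    empty = np.zeros((3, 3), dtype=bool)
    some = ~empty
    assert dice_score(empty, empty) == 1.0
    assert dice_score(some, empty) == 0.0
    assert dice_score(empty, some) == 0.0


def test_dice_symmetry_and_permutation_invariance(rng):
    a = rng.random((5, 5)) > 0.5
    b = rng.random((5, 5)) > 0.5
    assert dice_score(a, b) == dice_score(b, a)
    perm = rng.permutation(25)
    ap = a.reshape(25)[perm].reshape(5, 5)
    bp = b.reshape(25)[perm].reshape(5, 5)
    assert dice_score(ap, bp) == pytest.approx(dice_score(a, b))


def test_dice_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        dice_score(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


# ---------------------------------------------------------------------------
# Model contract
# ---------------------------------------------------------------------------

def test_seg_forward_contract(rng):
    model = SegmentationNet([1, 2, 3], width=8, seed=0)
    img = rng.uniform(-1, 1, (16, 16, 3))
    out1 = seg_forward(model, img)
    out2 = seg_forward(model, img)
    assert out1.logits.shape == (16, 16, 4)
    assert len(out1.embeddings) == 3
    assert out1.encoder_feature.shape == (16,)
    assert np.array_equal(out1.logits, out2.logits)  # eval determinism
    with pytest.raises(ValueError):
        seg_forward(model, rng.uniform(-1, 1, (16, 16, 1)))


def test_head_expansion_preserves_old_logits(rng):
    model = SegmentationNet([1, 2, 3], width=8, seed=1)
    img = rng.uniform(-1, 1, (16, 16, 3))
    before = seg_forward(model, img).logits
    old_w = model.head.w.data.copy()
    model.expand_head([4, 5], rng=np.random.default_rng(0))
    after = seg_forward(model, img).logits
    assert after.shape[2] == before.shape[2] + 2
    assert np.array_equal(after[..., :4], before)
    assert np.array_equal(model.head.w.data[:4], old_w)
    with pytest.raises(ValueError):
        model.expand_head([5])  # already known


def test_segmenter_checkpoint_round_trip(tmp_path, rng):
    model = SegmentationNet([1, 2], width=8, seed=2)
    img = rng.uniform(-1, 1, (16, 16, 3))
    save_segmenter(model, tmp_path / "seg.npz")
    model2 = load_segmenter(tmp_path / "seg.npz")
    assert model2.known_classes == [1, 2]
    assert np.allclose(seg_forward(model, img).logits,
                       seg_forward(model2, img).logits)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp


@settings(deadline=None, derandomize=True, max_examples=30)
@given(hnp.arrays(bool, (6, 6)), hnp.arrays(bool, (6, 6)))
def test_dice_bounds_and_symmetry_property(a, b):
    d = dice_score(a, b)
    assert 0.0 <= d <= 1.0
    assert d == dice_score(b, a)
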