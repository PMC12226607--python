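"""Segmentation model contract, losses and Dice scoring under the
binary-annotation regime.

Each training image carries a pixel mask for exactly one "most prominent"
class; other visible structures are unlabeled. The model outputs per-class
logits (background channel 0 plus every class known so far), an ordered list
of intermediate embeddings used for feature distillation, and one pooled
encoder feature per image used for contrastive learning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from ._engine import Conv2d, Module, Tensor, avg_pool2, concat, log_softmax, \
    upsample_nearest2

logger = logging.getLogger(__name__)

BACKGROUND_ID = 0
IGNORE_ID = 255

__all__ = [
    "BACKGROUND_ID", "IGNORE_ID",
    "AnnotatedImage", "ClassRegistry", "SegOutputs", "SegmentationNet",
    "class_frequency_weights", "weighted_cross_entropy", "seg_forward",
    "predict_with_confidence", "dice_score",
    "save_segmenter", "load_segmenter",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnnotatedImage:
    """One image with the binary mask of its single annotated class."""

    image: np.ndarray          # H×W×C in [-1, 1]
    class_id: int              # >= 1
    mask: np.ndarray           # H×W bool

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.class_id < 1:
            raise ValueError("class_id must be >= 1")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask shape must match image spatial shape")


@dataclasses.dataclass(frozen=True)
class ClassRegistry:
    """Ordered disjoint class-id sets, one per incremental step.

    Background is id 0 and the ignore label 255; neither may appear in a
    step set.
    """

    steps: tuple[frozenset[int], ...]

    def __init__(self, steps):
        object.__setattr__(self, "steps", tuple(frozenset(s) for s in steps))
        seen: set[int] = set()
        for s in self.steps:
            if not s:
                raise ValueError("each step must introduce at least one class")
            if s & seen:
                raise ValueError(f"class sets must be pairwise disjoint; overlap {sorted(s & seen)}")
            if BACKGROUND_ID in s or IGNORE_ID in s:
                raise ValueError("step sets may not contain the background or ignore id")
            seen |= s

    @property
    def num_steps(self) -> int:
        return len(self.steps)

    def classes_at_step(self, t: int) -> list[int]:
        return sorted(self.steps[t])

    def known_classes(self, t: int) -> list[int]:
        out: set[int] = set()
        for s in self.steps[: t + 1]:
            out |= s
        return sorted(out)

    def all_classes(self) -> list[int]:
        return self.known_classes(self.num_steps - 1)


@dataclasses.dataclass
class SegOutputs:
    """Dense logits plus the features used by distillation and contrast."""

    logits: np.ndarray                 # H×W×(K_known+1)
    embeddings: list[np.ndarray]       # ordered per the distillation layer set
    encoder_feature: np.ndarray        # pooled vector z
    class_ids: list[int]               # channel order: [0] + known classes


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class SegmentationNet(Module):
    """Compact encoder-decoder with a dilated-convolution context block.

    The context block (two dilated 3×3 convolutions) stands in for atrous
    spatial pyramid pooling at desk scale; the output contract (logits,
    embedding list, pooled feature) is backbone-agnostic. Channel 0 of the
    logits is background; channel k>0 corresponds to ``known_classes[k-1]``.

    The distillation layer set L is (encoder feature, context-block output,
    logits).
    """

    def __init__(self, known_classes: list[int], channels: int = 3,
                 width: int = 16, seed: int = 0):
        if len(set(known_classes)) != len(known_classes):
            raise ValueError("known_classes must be unique")
        rng = np.random.default_rng(seed)
        w = width
        self.known_classes = list(known_classes)
        self.channels = channels
        self.width = width
        self.seed = seed
        self.enc1 = Conv2d(channels, w, 3, rng)
        self.enc2 = Conv2d(w, w, 3, rng)
        self.enc3 = Conv2d(w, 2 * w, 3, rng)
        self.ctx1 = Conv2d(2 * w, 2 * w, 3, rng, dilation=2)
        self.ctx2 = Conv2d(2 * w, 2 * w, 3, rng, dilation=2)
        self.dec1 = Conv2d(2 * w, w, 3, rng)
        self.head = Conv2d(w, 1 + len(known_classes), 1, rng)
        self._head_rng = rng

    @property
    def num_channels(self) -> int:
        return 1 + len(self.known_classes)

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor], Tensor]:
        """NCHW batch -> (logits, [e_enc, e_ctx, logits], z)."""
        h = self.enc1(x).relu()
        h = self.enc2(h).relu()
        h = avg_pool2(h)
        e_enc = self.enc3(h).relu()
        c = self.ctx1(e_enc).relu()
        e_ctx = self.ctx2(c).relu()
        d = self.dec1(upsample_nearest2(e_ctx)).relu()
        logits = self.head(d)
        z = e_enc.mean(axis=(2, 3))
        return logits, [e_enc, e_ctx, logits], z

    def expand_head(self, new_classes: list[int], rng: np.random.Generator | None = None,
                    init_scale: float = 1e-3) -> None:
        """Add output channels for new classes; old-channel parameters are
        kept bit-identical."""
        overlap = set(new_classes) & set(self.known_classes)
        if overlap:
            raise ValueError(f"classes already known: {sorted(overlap)}")
        rng = rng or self._head_rng
        k_new = len(new_classes)
        old_w, old_b = self.head.w.data, self.head.b.data
        new_w = np.concatenate(
            [old_w, rng.normal(0.0, init_scale,
                               size=(k_new,) + old_w.shape[1:]).astype(old_w.dtype)])
        new_b = np.concatenate([old_b, np.zeros(k_new, dtype=old_b.dtype)])
        self.head.w = Tensor(new_w, requires_grad=True)
        self.head.b = Tensor(new_b, requires_grad=True)
        self.known_classes = self.known_classes + list(new_classes)

    def snapshot(self) -> "SegmentationNet":
        """Deep, frozen-by-convention copy (used as the previous model)."""
        clone = SegmentationNet(self.known_classes, self.channels, self.width,
                                self.seed)
        clone.load_state_arrays([a.copy() for a in self.state_arrays()])
        return clone

    def label_of_channel(self, k: int) -> int:
        return BACKGROUND_ID if k == 0 else self.known_classes[k - 1]

    def channel_of_class(self, class_id: int) -> int:
        return 0 if class_id == BACKGROUND_ID else 1 + self.known_classes.index(class_id)


def _image_to_nchw(image: np.ndarray) -> np.ndarray:
    return np.transpose(np.asarray(image, dtype=np.float32), (2, 0, 1))[None]


def seg_forward(model: SegmentationNet, image: np.ndarray) -> SegOutputs:
    """Evaluate the model on one H×W×C image (no gradients kept)."""
    if image.ndim != 3 or image.shape[2] != model.channels:
        raise ValueError(f"expected H×W×{model.channels} image, got {image.shape}")
    logits, embs, z = model.forward(Tensor(_image_to_nchw(image)))
    return SegOutputs(
        logits=np.transpose(logits.data[0], (1, 2, 0)).astype(np.float64),
        embeddings=[e.data[0].astype(np.float64) for e in embs],
        encoder_feature=z.data[0].astype(np.float64),
        class_ids=[BACKGROUND_ID] + list(model.known_classes),
    )


# ---------------------------------------------------------------------------
# Losses and metrics
# ---------------------------------------------------------------------------

def class_frequency_weights(dataset: list[AnnotatedImage], registry: ClassRegistry,
                            classes: list[int] | None = None,
                            eps_f: float = 1.0) -> dict[int, float]:
    """Inverse-pixel-frequency class weights, normalised to mean 1 over the
    classes present in the dataset.

    Pixels outside an image's mask count toward background. Classes in
    ``classes`` that never occur receive the maximum computed weight.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    classes = classes if classes is not None else registry.all_classes()
    counts: dict[int, float] = {BACKGROUND_ID: 0.0}
    for c in classes:
        counts.setdefault(c, 0.0)
    for item in dataset:
        fg = float(item.mask.sum())
        counts[item.class_id] = counts.get(item.class_id, 0.0) + fg
        counts[BACKGROUND_ID] += item.mask.size - fg
    raw = {c: 1.0 / (counts[c] + eps_f) for c in counts}
    present = [c for c in counts if counts[c] > 0]
    norm = np.mean([raw[c] for c in present])
    weights = {c: raw[c] / norm for c in counts}
    max_w = max(weights[c] for c in present)
    for c in counts:
        if counts[c] == 0:
            logger.info("class %d absent from dataset; assigned max weight %.4g", c, max_w)
            weights[c] = max_w
    return weights


def _wce_tensor(logits: Tensor, labels: np.ndarray, weight_vec: np.ndarray) -> Tensor:
    """Weighted CE on an NCHW logits tensor; labels are channel indices
    (N,H,W) with IGNORE_ID skipped. Mean over non-ignored pixels."""
    n, k, h, w = logits.data.shape
    logp = log_softmax(logits, axis=1)
    flat = logp.reshape(n, k, h * w)
    labels = labels.reshape(n, h * w)
    keep = labels != IGNORE_ID
    if not keep.any():
        logger.warning("weighted cross-entropy: every pixel ignored; loss is 0")
        return Tensor(np.zeros(()))
    ni, pi = np.nonzero(keep)
    li = labels[ni, pi]
    if li.max() >= k:
        raise ValueError(f"label {li.max()} out of range for {k} channels")
    picked = flat[ni, li, pi]
    wts = Tensor(weight_vec[li].astype(np.float32))
    return (picked * wts * -1.0).sum() * (1.0 / len(li))


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           weights: np.ndarray) -> float:
    """Class-frequency-weighted cross-entropy on one H×W×K logit map.

    ``labels`` holds channel indices in {0..K-1} or IGNORE_ID; ``weights``
    is the per-channel weight vector. Returns the mean over non-ignored
    pixels of weight_label * (-log softmax(logits)_label).
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    h, w, k = logits.shape
    if labels.shape != (h, w):
        raise ValueError("labels shape must match logits spatial shape")
    t = _wce_tensor(Tensor(np.transpose(logits, (2, 0, 1))[None].astype(np.float32)),
                    labels[None], np.asarray(weights, dtype=np.float64))
    return float(t.data)


def predict_with_confidence(outputs: SegOutputs) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel argmax class-id map and its softmax probability.

    Ties break toward the lowest channel index (hence background first).
    Returns class ids (not channel indices).
    """
    logits = outputs.logits
    m = logits.max(axis=2, keepdims=True)
    p = np.exp(logits - m)
    p /= p.sum(axis=2, keepdims=True)
    chan = logits.argmax(axis=2)
    conf = np.take_along_axis(p, chan[..., None], axis=2)[..., 0]
    ids = np.asarray(outputs.class_ids)
    return ids[chan], conf


def dice_score(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """2|P∩G| / (|P|+|G|); 1.0 when both masks are empty, 0.0 when exactly
    one is."""
    pred_mask = np.asarray(pred_mask).astype(bool)
    gt_mask = np.asarray(gt_mask).astype(bool)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("mask shapes must match")
    p, g = pred_mask.sum(), gt_mask.sum()
    if p + g == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred_mask, gt_mask).sum() / (p + g))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_segmenter(model: SegmentationNet, path: str | Path) -> None:
    meta = {"known_classes": model.known_classes, "channels": model.channels,
            "width": model.width, "seed": model.seed}
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_segmenter(path: str | Path) -> SegmentationNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        params = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
    model = SegmentationNet(meta["known_classes"], meta["channels"],
                            meta["width"], meta["seed"])
    model.load_state_arrays(params)
    return model
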