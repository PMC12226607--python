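"""Synthetic surgical-like scene generator.

Emulates the binary-annotation regime of laparoscopic anatomy datasets at
desk scale: K visually distinct organ-like structures rendered as textured
superellipse blobs over a low-frequency background, one binary mask per
image covering only its designated "most prominent" class, roughly equal
image counts per class, and class-incremental splits in which new classes
arrive on disjoint images. Distractor blobs of other classes may appear
unannotated, which is what makes pseudo-labeling matter.
"""

from __future__ import annotations

import colorsys
import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import AnnotatedImage, ClassRegistry

__all__ = ["SceneSpec", "sample_scene", "build_dataset", "make_incremental_splits",
           "default_spec"]


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Appearance and layout parameters of the synthetic scenes."""

    n_classes: int = 5
    height: int = 32
    width: int = 32
    images_per_class: int = 60
    blob_radius: tuple[float, float] = (3.0, 7.0)   # semi-axis range, px
    blobs_per_class: tuple[int, int] = (1, 2)
    texture_amplitude: float = 0.08
    background_amplitude: float = 0.15
    distractors: bool = True
    max_distractors: int = 2
    fg_bounds: tuple[float, float] = (0.02, 0.5)
    saturation: float = 0.85

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.height < 16 or self.width < 16:
            raise ValueError("scene size must be at least 16x16")

    def palette(self) -> np.ndarray:
        """Per-class base colors in [-1, 1], evenly spaced hues (pairwise
        distinct by construction)."""
        cols = []
        for c in range(self.n_classes):
            h = c / self.n_classes
            v = 0.75 + 0.2 * ((c % 2) * 2 - 1) * 0.5
            rgb = colorsys.hsv_to_rgb(h, self.saturation, v)
            cols.append([2.0 * x - 1.0 for x in rgb])
        return np.asarray(cols)


def default_spec() -> SceneSpec:
    return SceneSpec()


def _superellipse_mask(h: int, w: int, cx: float, cy: float, a: float, b: float,
                       theta: float, p: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (np.abs(u / a) ** p + np.abs(v / b) ** p) <= 1.0


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, size=(4, 4, 3))
    zoom = (spec.height / 4, spec.width / 4, 1)
    field = ndimage.zoom(coarse, zoom, order=1)
    field = ndimage.gaussian_filter(field, sigma=(1.5, 1.5, 0))
    return -0.35 + spec.background_amplitude * field


def _paint_blob(img: np.ndarray, mask: np.ndarray, color: np.ndarray,
                spec: SceneSpec, rng: np.random.Generator,
                cx: float, cy: float, a: float, b: float) -> None:
    h, w, _ = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    shade = 1.0 - 0.35 * np.clip(r2, 0, 1)
    tex = rng.normal(0.0, spec.texture_amplitude, size=(h, w, 3))
    vals = color[None, None, :] * shade[:, :, None] + tex
    img[mask] = np.clip(vals, -1.0, 1.0)[mask]


def _random_blob(spec: SceneSpec, rng: np.random.Generator):
    h, w = spec.height, spec.width
    a = rng.uniform(*spec.blob_radius)
    b = rng.uniform(*spec.blob_radius)
    cx = rng.uniform(0.2 * w, 0.8 * w)
    cy = rng.uniform(0.2 * h, 0.8 * h)
    theta = rng.uniform(0, np.pi)
    p = rng.uniform(1.6, 3.0)
    return cx, cy, a, b, theta, p


def sample_scene(spec: SceneSpec, class_id: int,
                 rng: np.random.Generator) -> AnnotatedImage:
    """Render one scene whose mask covers exactly the designated-class blobs.

    Distractor blobs of other classes (0..max_distractors, unannotated) are
    drawn first so the designated class stays most prominent. Resamples
    until the mask's foreground fraction lies inside ``spec.fg_bounds``.
    """
    if not (1 <= class_id <= spec.n_classes):
        raise ValueError(f"class_id must be in 1..{spec.n_classes}")
    palette = spec.palette()
    h, w = spec.height, spec.width
    for _ in range(64):
        img = _background(spec, rng)
        if spec.distractors and spec.n_classes > 1:
            n_d = rng.integers(0, spec.max_distractors + 1)
            others = [c for c in range(1, spec.n_classes + 1) if c != class_id]
            for _ in range(n_d):
                d = int(rng.choice(others))
                cx, cy, a, b, theta, p = _random_blob(spec, rng)
                m = _superellipse_mask(h, w, cx, cy, a, b, theta, p)
                _paint_blob(img, m, palette[d - 1], spec, rng, cx, cy, a, b)
        mask = np.zeros((h, w), dtype=bool)
        n_blobs = rng.integers(spec.blobs_per_class[0], spec.blobs_per_class[1] + 1)
        for _ in range(n_blobs):
            cx, cy, a, b, theta, p = _random_blob(spec, rng)
            m = _superellipse_mask(h, w, cx, cy, a, b, theta, p)
            _paint_blob(img, m, palette[class_id - 1], spec, rng, cx, cy, a, b)
            mask |= m
        frac = mask.mean()
        if spec.fg_bounds[0] <= frac <= spec.fg_bounds[1]:
            return AnnotatedImage(image=np.clip(img, -1, 1), class_id=class_id,
                                  mask=mask)
    raise RuntimeError("could not render a scene within the foreground bounds")


def build_dataset(spec: SceneSpec, images_per_class: int | None = None,
                  rng_seed: int = 0,
                  split_fracs: tuple[float, float, float] = (0.7, 0.1, 0.2)
                  ) -> tuple[list[AnnotatedImage], pd.DataFrame]:
    """Balanced dataset of K * images_per_class scenes plus its manifest.

    The manifest rows carry logical image/mask paths (materialised only when
    the dataset is written to disk), the annotated class, and a per-class
    train/val/test split.
    """
    ipc = spec.images_per_class if images_per_class is None else images_per_class
    if ipc < 1:
        raise ValueError("images_per_class must be >= 1")
    ss = np.random.SeedSequence([rng_seed, 0x5CE&0xFFFF])
    rows = []
    items: list[AnnotatedImage] = []
    for class_id in range(1, spec.n_classes + 1):
        rng = np.random.default_rng(ss.generate_state(spec.n_classes + 1)[class_id] >> 1)
        n_train = int(round(split_fracs[0] * ipc))
        n_val = int(round(split_fracs[1] * ipc))
        for i in range(ipc):
            item = sample_scene(spec, class_id, rng)
            split = ("train" if i < n_train
                     else "val" if i < n_train + n_val else "test")
            rows.append({
                "image_path": f"images/c{class_id:02d}_{i:04d}.png",
                "mask_path": f"masks/c{class_id:02d}_{i:04d}.png",
                "class_id": class_id,
                "split": split,
            })
            items.append(item)
    manifest = pd.DataFrame(rows)
    return items, manifest


def make_incremental_splits(manifest: pd.DataFrame, registry: ClassRegistry
                            ) -> dict[int, pd.DataFrame]:
    """Assign manifest rows to incremental steps by annotated class.

    Step t keeps only images annotated with a step-t class, so images are
    disjoint across steps by construction (the clinical constraint: new
    categories arrive on separate images).
    """
    present = set(manifest["class_id"].unique())
    wanted = set(registry.all_classes())
    if not wanted <= present:
        raise ValueError(f"registry classes missing from manifest: {sorted(wanted - present)}")
    out: dict[int, pd.DataFrame] = {}
    for t in range(registry.num_steps):
        step_classes = set(registry.classes_at_step(t))
        sub = manifest[manifest["class_id"].isin(step_classes)].copy()
        sub["step"] = t
        out[t] = sub.reset_index(drop=False).rename(columns={"index": "row"})
    return out
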