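"""Dataset and replay-set persistence: PNG images, 0/255 PNG masks, CSV
manifests and JSON provenance sidecars.

Images live in [-1, 1] in memory and are stored as 8-bit PNG; loaders
rescale with v/127.5 - 1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .diffusion import ReplaySet
from .segmentation import AnnotatedImage

__all__ = ["image_to_uint8", "uint8_to_image", "write_dataset", "load_dataset",
           "write_replay_set", "load_replay_set"]

MANIFEST_COLUMNS = ["image_path", "mask_path", "class_id", "split"]


def image_to_uint8(image: np.ndarray) -> np.ndarray:
    return np.clip((np.asarray(image) + 1.0) * 127.5, 0, 255).round().astype(np.uint8)


def uint8_to_image(arr: np.ndarray) -> np.ndarray:
    return np.asarray(arr, dtype=np.float64) / 127.5 - 1.0


def write_dataset(items: list[AnnotatedImage], manifest: pd.DataFrame,
                  out_dir: str | Path) -> Path:
    """Materialise a dataset: PNGs at the manifest's paths plus
    ``manifest.csv``. Returns the manifest path."""
    out = Path(out_dir)
    if len(items) != len(manifest):
        raise ValueError("items and manifest must have equal length")
    for item, row in zip(items, manifest.itertuples(index=False)):
        img_path = out / row.image_path
        msk_path = out / row.mask_path
        img_path.parent.mkdir(parents=True, exist_ok=True)
        msk_path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(image_to_uint8(item.image)).save(img_path)
        Image.fromarray((item.mask.astype(np.uint8) * 255)).save(msk_path)
    mpath = out / "manifest.csv"
    manifest.to_csv(mpath, index=False)
    return mpath


def load_dataset(manifest_path: str | Path,
                 split: str | None = None) -> tuple[list[AnnotatedImage], pd.DataFrame]:
    """Read a manifest and its PNGs back; optionally filter one split."""
    mpath = Path(manifest_path)
    manifest = pd.read_csv(mpath)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing column(s) {missing}")
    if split is not None:
        manifest = manifest[manifest["split"] == split].reset_index(drop=True)
    root = mpath.parent
    items = []
    for row in manifest.itertuples(index=False):
        img = uint8_to_image(np.asarray(Image.open(root / row.image_path)))
        msk = np.asarray(Image.open(root / row.mask_path)) > 127
        items.append(AnnotatedImage(image=img, class_id=int(row.class_id), mask=msk))
    return items, manifest


def write_replay_set(replay: ReplaySet, out_dir: str | Path) -> Path:
    """PNG images plus a JSON provenance sidecar; returns the sidecar path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, im in enumerate(replay.images):
        name = f"replay_{i:05d}.png"
        Image.fromarray(image_to_uint8(im)).save(out / name)
        names.append(name)
    sidecar = out / "provenance.json"
    sidecar.write_text(json.dumps({
        "checkpoint_id": replay.checkpoint_id, "seed": replay.seed,
        "S": replay.S, "n": len(replay.images), "images": names}, indent=2))
    return sidecar


def load_replay_set(dir_path: str | Path) -> ReplaySet:
    d = Path(dir_path)
    meta = json.loads((d / "provenance.json").read_text())
    images = [uint8_to_image(np.asarray(Image.open(d / n)))
              for n in meta["images"]]
    return ReplaySet(images=images, checkpoint_id=meta["checkpoint_id"],
                     seed=meta["seed"], S=meta["S"])
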