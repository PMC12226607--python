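"""Per-class Dice evaluation and table-style aggregation.

Under the binary-annotation regime a class is evaluated only on the test
images annotated with it: the model's predicted mask for that class is
compared against the image's binary ground truth, and the per-class score
is the mean over those images. Group summaries report the arithmetic mean
and the population (N-divisor) standard deviation across the member
classes' scores.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .segmentation import (AnnotatedImage, ClassRegistry, SegmentationNet,
                           dice_score, predict_with_confidence, seg_forward)

__all__ = ["evaluate_split", "aggregate_group_means", "StepReport",
           "make_step_report", "write_report", "read_report", "format_table"]


def evaluate_split(model: SegmentationNet, test_set: list[AnnotatedImage],
                   registry: ClassRegistry) -> dict[int, float]:
    """Mean Dice per class over the test images annotated with that class.

    Classes without any test image are absent from the result (not scored
    0). Deterministic for a fixed checkpoint.
    """
    by_class: dict[int, list[float]] = {}
    known = set(model.known_classes)
    for item in test_set:
        if item.class_id not in known:
            continue
        if hasattr(model, "predict_labels"):   # any model honoring the contract
            labels = model.predict_labels(item.image)
        else:
            labels, _ = predict_with_confidence(seg_forward(model, item.image))
        pred_mask = labels == item.class_id
        by_class.setdefault(item.class_id, []).append(
            dice_score(pred_mask, item.mask))
    return {c: float(np.mean(v)) for c, v in sorted(by_class.items())}


def aggregate_group_means(per_class: dict[int, float],
                          groups: dict[str, list[int]],
                          ddof: int = 0) -> dict[str, tuple[float, float]]:
    """Arithmetic mean and standard deviation of per-class scores for each
    named class group (``ddof=0``: population deviation)."""
    out: dict[str, tuple[float, float]] = {}
    for name, members in groups.items():
        missing = [c for c in members if c not in per_class]
        if missing:
            raise ValueError(f"group '{name}' missing class(es) {missing}")
        vals = np.asarray([per_class[c] for c in members], dtype=np.float64)
        sd = 0.0 if len(vals) == 1 and ddof > 0 else float(np.std(vals, ddof=ddof))
        out[name] = (float(vals.mean()), sd)
    return out


@dataclasses.dataclass
class StepReport:
    """Per-class Dice with grouped summaries for one step of one method."""

    step: int
    method: str
    per_class_dice: dict[int, float]
    group_means: dict[str, tuple[float, float]]

    def to_json_dict(self) -> dict:
        return {
            "step": self.step,
            "method": self.method,
            "per_class_dice": {str(k): v for k, v in self.per_class_dice.items()},
            "group_means": {k: list(v) for k, v in self.group_means.items()},
        }

    @staticmethod
    def from_json_dict(d: dict) -> "StepReport":
        return StepReport(
            step=int(d["step"]), method=str(d["method"]),
            per_class_dice={int(k): float(v) for k, v in d["per_class_dice"].items()},
            group_means={k: (float(v[0]), float(v[1]))
                         for k, v in d["group_means"].items()},
        )


def make_step_report(model: SegmentationNet, test_set: list[AnnotatedImage],
                     registry: ClassRegistry, step: int, method: str,
                     groups: dict[str, list[int]] | None = None) -> StepReport:
    per_class = evaluate_split(model, test_set, registry)
    if groups is None:
        groups = {f"step{t}": [c for c in registry.classes_at_step(t)
                               if c in per_class]
                  for t in range(registry.num_steps)
                  if any(c in per_class for c in registry.classes_at_step(t))}
        groups["all"] = sorted(per_class)
    return StepReport(step=step, method=method, per_class_dice=per_class,
                      group_means=aggregate_group_means(per_class, groups))


def format_table(reports: list[StepReport]) -> str:
    """Aligned text table: one row per (method, step), grouped means with a
    ±deviation column, rounded to 2 decimals for display."""
    names: list[str] = []
    for r in reports:
        for g in r.group_means:
            if g not in names:
                names.append(g)
    if "all" in names:   # overall column reads best last
        names.remove("all")
        names.append("all")
    head = f"{'method':<14}{'step':>5}" + "".join(f"{g:>16}" for g in names)
    lines = [head, "-" * len(head)]
    for r in reports:
        cells = []
        for g in names:
            if g in r.group_means:
                m, s = r.group_means[g]
                cells.append(f"{m:.2f} ±{s:.2f}".rjust(16))
            else:
                cells.append(" " * 16)
        lines.append(f"{r.method:<14}{r.step:>5}" + "".join(cells))
    return "\n".join(lines)


def write_report(reports: list[StepReport], path: str | Path) -> None:
    """Write a JSON report (full precision; lossless round trip) plus an
    aligned text table alongside it."""
    if not reports:
        raise ValueError("report list must be non-empty")
    path = Path(path)
    payload = {"schema": "replayseg-report-v1",
               "reports": [r.to_json_dict() for r in reports]}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    path.with_suffix(".txt").write_text(format_table(reports) + "\n")


def read_report(path: str | Path) -> list[StepReport]:
    payload = json.loads(Path(path).read_text())
    return [StepReport.from_json_dict(d) for d in payload["reports"]]
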