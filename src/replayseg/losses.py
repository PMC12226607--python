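"""The three-part incremental objective.

During an incremental step the trainable current model is regularised
against a frozen snapshot of its predecessor in three ways:

* **Feature distillation** — a layer-weighted sum of Euclidean distances
  between the two models' embeddings (dense alignment across intermediate
  layers and logits).
* **Contrastive feature discrimination** — an InfoNCE-style loss whose
  positive pair is the two models' pooled features of the same real image
  and whose negatives are the current image's feature against a generated
  (replay) image's features under both models.
* **Pseudo-label merging** — ground truth takes precedence inside the
  annotated mask; elsewhere the previous model's prediction is kept where
  its confidence clears a threshold, and remaining pixels are ignored.

The overall objective is the unweighted sum of the segmentation,
distillation and contrastive terms; at the initial step only the
segmentation term applies.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._engine import Linear, Module, Tensor, l2_normalize
from .segmentation import (AnnotatedImage, ClassRegistry, IGNORE_ID,
                           SegOutputs, predict_with_confidence)

__all__ = [
    "kd_loss", "ProjectionHead", "project", "FeatureBundle",
    "contrastive_loss", "pseudo_label_merge", "overall_loss",
]


# ---------------------------------------------------------------------------
# Distillation
# ---------------------------------------------------------------------------

def kd_loss(prev_embeddings: list[np.ndarray], curr_embeddings: list[np.ndarray],
            omega, squared: bool = False) -> float:
    """Layer-weighted sum of Euclidean distances between embedding lists.

    ``omega`` is a sequence of nonnegative layer weights aligned with the
    embedding lists. With ``squared=True`` the squared distance is used
    instead of the plain norm.
    """
    omega = list(omega.values()) if isinstance(omega, dict) else list(omega)
    if len(prev_embeddings) != len(curr_embeddings) or len(omega) != len(prev_embeddings):
        raise ValueError("embedding lists and omega must have equal length")
    total = 0.0
    for w, ep, ec in zip(omega, prev_embeddings, curr_embeddings):
        ep, ec = np.asarray(ep, dtype=np.float64), np.asarray(ec, dtype=np.float64)
        if ep.shape != ec.shape:
            raise ValueError(f"embedding shape mismatch {ep.shape} vs {ec.shape}")
        if w < 0:
            raise ValueError("layer weights must be nonnegative")
        d = np.linalg.norm((ep - ec).ravel())
        total += w * (d * d if squared else d)
    return float(total)


def kd_loss_tensor(prev_embeddings: list[np.ndarray], curr_embeddings: list[Tensor],
                   omega, squared: bool = False, normalize: bool = True,
                   eps: float = 1e-12) -> Tensor:
    """Differentiable batch version: per layer, the per-image Euclidean
    distance averaged over the batch (so the loss scale is batch-size
    invariant), then the omega-weighted sum over layers.

    With ``normalize=True`` (the trainer's default) each layer's distance is
    divided by the square root of its element count, i.e. the RMS per-element
    distance. This keeps the distillation gradient on the same scale as the
    cross-entropy term regardless of feature-map size; the plain Euclidean
    form is :func:`kd_loss`.
    """
    omega = list(omega.values()) if isinstance(omega, dict) else list(omega)
    total = None
    for w, ep, ec in zip(omega, prev_embeddings, curr_embeddings):
        n = ec.data.shape[0]
        diff = ec - Tensor(np.asarray(ep, dtype=np.float32))
        sq = (diff ** 2.0).reshape(n, -1).sum(axis=1)
        if normalize:
            sq = sq * (1.0 / (ec.data.size / n))
        term = (sq if squared else (sq + eps) ** 0.5).mean() * float(w)
        total = term if total is None else total + term
    return total


# ---------------------------------------------------------------------------
# Projection head and contrastive loss
# ---------------------------------------------------------------------------

class ProjectionHead(Module):
    """Two affine layers with a ReLU between; outputs are L2-normalised so
    dot products are cosines."""

    def __init__(self, in_dim: int, hidden_dim: int = 64, out_dim: int = 64,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.fc1 = Linear(in_dim, hidden_dim, rng)
        self.fc2 = Linear(hidden_dim, out_dim, rng)

    def forward(self, z: Tensor) -> Tensor:
        return l2_normalize(self.fc2(self.fc1(z).relu()), axis=1)


def project(head: ProjectionHead, z: np.ndarray) -> np.ndarray:
    """Project one feature vector to the unit-norm contrastive space."""
    z = np.asarray(z, dtype=np.float32)
    if z.shape != (head.in_dim,):
        raise ValueError(f"expected feature of dimension {head.in_dim}, got {z.shape}")
    return head.forward(Tensor(z[None])).data[0].astype(np.float64)


@dataclasses.dataclass
class FeatureBundle:
    """Features of one real and one generated image under both models."""

    z_t: np.ndarray      # real image, current model
    z_tm1: np.ndarray    # real image, previous model
    zp_t: np.ndarray     # generated image, current model
    zp_tm1: np.ndarray   # generated image, previous model
    tau: float = 0.1

    def __post_init__(self):
        dims = {np.asarray(v).shape for v in (self.z_t, self.z_tm1, self.zp_t, self.zp_tm1)}
        if len(dims) > 1:
            raise ValueError("all features must share one dimensionality")
        if self.tau <= 0:
            raise ValueError("temperature tau must be positive")


def _nce_from_sims(pos: float, negs: list[float], tau: float) -> float:
    logits = np.array([pos] + list(negs)) / tau
    m = logits.max()
    return float(m + np.log(np.exp(logits - m).sum()) - logits[0])


def contrastive_loss(bundle: FeatureBundle, head: ProjectionHead) -> float:
    """InfoNCE for one positive pair (real image under both models) against
    the two generated-image negatives."""
    p_t = project(head, bundle.z_t)
    p_tm1 = project(head, bundle.z_tm1)
    pp_t = project(head, bundle.zp_t)
    pp_tm1 = project(head, bundle.zp_tm1)
    pos = float(p_t @ p_tm1)
    negs = [float(p_t @ pp_t), float(p_t @ pp_tm1)]
    return _nce_from_sims(pos, negs, bundle.tau)


def contrastive_loss_tensor(p_t: Tensor, p_tm1: Tensor, pp_t: Tensor,
                            pp_tm1: Tensor, tau: float) -> Tensor:
    """Differentiable batch version on already-projected (n, d) tensors:
    per-row InfoNCE, averaged over the batch."""
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    inv = 1.0 / tau
    pos = (p_t * p_tm1).sum(axis=1) * inv
    n1 = (p_t * pp_t).sum(axis=1) * inv
    n2 = (p_t * pp_tm1).sum(axis=1) * inv
    # log-sum-exp over the three similarity logits, stabilised by the max
    m = np.maximum.reduce([pos.data, n1.data, n2.data])
    mt = Tensor(m)
    lse = ((pos - mt).exp() + (n1 - mt).exp() + (n2 - mt).exp()).log() + mt
    return (lse - pos).mean()


# ---------------------------------------------------------------------------
# Pseudo-labels and the overall objective
# ---------------------------------------------------------------------------

def pseudo_label_merge(prev_model_outputs: SegOutputs,
                       gt: AnnotatedImage | None,
                       threshold: float,
                       registry: ClassRegistry) -> np.ndarray:
    """Merge previous-model pseudo-labels with current ground truth.

    Pixels inside the ground-truth mask carry the annotated class (ground
    truth takes precedence). Elsewhere the previous model's argmax label is
    kept where its confidence reaches ``threshold`` (background included);
    remaining pixels get the ignore id. With ``gt=None`` (generated images)
    the map is purely thresholded pseudo-labels.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    known = set(prev_model_outputs.class_ids)
    if not known <= set(registry.all_classes()) | {0}:
        raise ValueError("previous model knows classes outside the registry")
    labels, conf = predict_with_confidence(prev_model_outputs)
    out = np.where(conf >= threshold, labels, IGNORE_ID).astype(np.int64)
    if gt is not None:
        out[gt.mask] = gt.class_id
    return out


def overall_loss(seg_term: float, kd_term: float, cl_term: float, t: int,
                 multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Sum of the three terms at incremental steps; only the segmentation
    term at the initial step (t = 0)."""
    if t < 0:
        raise ValueError("step index must be >= 0")
    for v in (seg_term, kd_term, cl_term):
        if v < 0:
            raise ValueError("loss terms must be nonnegative")
    if t == 0:
        return float(multipliers[0] * seg_term)
    a, b, c = multipliers
    return float(a * seg_term + b * kd_term + c * cl_term)
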