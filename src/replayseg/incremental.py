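"""Orchestration of the T+1-step class-incremental protocol.

The initial step trains the segmenter on the first class set with weighted
cross-entropy only, and trains the diffusion generator on the same images.
Each incremental step then freezes the previous segmenter, expands the
classification head for the new classes, mixes the step's real images with
diffusion-generated replay images, labels both via pseudo-label merging,
and optimises the sum of segmentation, distillation and contrastive terms.

:class:`IncrementalSegmenter` wraps the procedure as an sklearn-style
estimator (``fit`` for the initial step, ``fit_step`` per increment,
``predict`` for label maps).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from sklearn.base import BaseEstimator

from ._engine import SGD, Tensor
from .diffusion import (DiffusionTrainConfig, NoisePredictorNet, NoiseSchedule,
                        ReplaySet, build_linear_schedule, fit_diffusion,
                        generate_replay_set)
from .losses import (ProjectionHead, contrastive_loss_tensor, kd_loss_tensor,
                     pseudo_label_merge)
from .segmentation import (AnnotatedImage, BACKGROUND_ID, ClassRegistry,
                           IGNORE_ID, SegmentationNet, _wce_tensor,
                           class_frequency_weights, seg_forward)

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "IncrementalState", "run_initial_step",
           "run_incremental_step", "mix_batches", "IncrementalSegmenter"]


@dataclasses.dataclass
class TrainConfig:
    """Everything tunable about the protocol; defaults are desk scale."""

    epochs_initial: int = 24
    epochs_per_step: int = 16
    batch_size: int = 16
    lr: float = 1e-2
    momentum: float = 0.9
    grad_clip: float = 1.0
    width: int = 16
    # diffusion / replay
    train_diffusion: bool = True
    diffusion_steps: int = 60
    diffusion_epochs: int = 50
    diffusion_lr: float = 2e-3
    diffusion_width: int = 24
    replay_n: int = 64
    replay_ratio: float = 0.5
    regenerate_replay: bool = False
    # objective switches (the ablation arms toggle these)
    use_pseudo_labels: bool = True
    use_kd: bool = True
    use_replay: bool = True
    use_cl: bool = True
    kd_layer_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kd_squared: bool = False
    tau: float = 0.1
    confidence_threshold: float = 0.7
    loss_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)
    proj_hidden: int = 64
    proj_dim: int = 64
    recompute_pseudo_per_epoch: bool = False
    seed: int = 0

    def method_tag(self) -> str:
        if not (self.use_kd or self.use_replay or self.use_cl or self.use_pseudo_labels):
            return "fine-tune"
        tag = "kd" if self.use_kd else "ft"
        if self.use_replay:
            tag += "+dg"
        if self.use_cl:
            tag += "+cl"
        return tag


@dataclasses.dataclass
class IncrementalState:
    """Snapshot of the protocol after step t."""

    t: int
    registry: ClassRegistry
    curr_model: SegmentationNet
    prev_model: SegmentationNet | None = None
    diffusion_model: NoisePredictorNet | None = None
    sched: NoiseSchedule | None = None
    replay: ReplaySet | None = None
    head: ProjectionHead | None = None
    history: list[dict] = dataclasses.field(default_factory=list)


def _derive_seed(master: int, *path: int) -> int:
    return int(np.random.SeedSequence([master, *path]).generate_state(1)[0] >> 1)


def _stack_batch(items: list[AnnotatedImage] | list[np.ndarray]) -> np.ndarray:
    imgs = [it.image if isinstance(it, AnnotatedImage) else it for it in items]
    return np.stack([np.transpose(np.asarray(im, dtype=np.float32), (2, 0, 1))
                     for im in imgs])


def _gt_labels(item: AnnotatedImage, model: SegmentationNet) -> np.ndarray:
    """Pure fine-tuning labels: annotated class inside the mask, background
    elsewhere (channel indices)."""
    lab = np.zeros(item.mask.shape, dtype=np.int64)
    lab[item.mask] = model.channel_of_class(item.class_id)
    return lab


def _to_channel_labels(class_labels: np.ndarray, model: SegmentationNet) -> np.ndarray:
    """Map a class-id label map (with IGNORE_ID) to head channel indices."""
    out = np.full(class_labels.shape, IGNORE_ID, dtype=np.int64)
    out[class_labels == BACKGROUND_ID] = 0
    for k, c in enumerate(model.known_classes, start=1):
        out[class_labels == c] = k
    return out


def _weight_vector(weights: dict[int, float], model: SegmentationNet) -> np.ndarray:
    vec = np.ones(model.num_channels, dtype=np.float64)
    vec[0] = weights.get(BACKGROUND_ID, 1.0)
    for k, c in enumerate(model.known_classes, start=1):
        vec[k] = weights.get(c, 1.0)
    return vec


def run_initial_step(dataset_0: list[AnnotatedImage], registry: ClassRegistry,
                     config: TrainConfig | None = None) -> IncrementalState:
    """Train the step-0 segmenter (weighted CE only) and the diffusion
    generator on the same images; returns the state at t = 0."""
    config = config or TrainConfig()
    if len(dataset_0) == 0:
        raise ValueError("dataset must be non-empty")
    step0 = set(registry.classes_at_step(0))
    bad = {it.class_id for it in dataset_0} - step0
    if bad:
        raise ValueError(f"dataset contains non-step-0 classes: {sorted(bad)}")

    model = SegmentationNet(registry.classes_at_step(0),
                            channels=dataset_0[0].image.shape[2],
                            width=config.width,
                            seed=_derive_seed(config.seed, 0, 1))
    weights = class_frequency_weights(dataset_0, registry,
                                      classes=registry.classes_at_step(0))
    wvec = _weight_vector(weights, model)
    labels = np.stack([_gt_labels(it, model) for it in dataset_0])
    data = _stack_batch(dataset_0)
    trace = _train_segmenter(model, data, labels, wvec, config,
                             epochs=config.epochs_initial,
                             rng_seed=_derive_seed(config.seed, 0, 2))

    diff_model, sched = None, None
    if config.train_diffusion:
        sched = build_linear_schedule(config.diffusion_steps)
        diff_model = fit_diffusion(
            [it.image for it in dataset_0], sched,
            DiffusionTrainConfig(epochs=config.diffusion_epochs,
                                 batch_size=config.batch_size,
                                 lr=config.diffusion_lr,
                                 width=config.diffusion_width,
                                 seed=_derive_seed(config.seed, 0, 3)))
    return IncrementalState(t=0, registry=registry, curr_model=model,
                            diffusion_model=diff_model, sched=sched,
                            history=[{"step": 0, "seg_loss": trace}])


def _train_segmenter(model: SegmentationNet, data: np.ndarray,
                     labels: np.ndarray, wvec: np.ndarray, config: TrainConfig,
                     epochs: int, rng_seed: int) -> list[float]:
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(rng_seed)
    opt = SGD(model.parameters(), lr=config.lr, momentum=config.momentum,
              clip_norm=config.grad_clip)
    trace = []
    n = data.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, _, _ = model.forward(Tensor(data[idx]))
            loss = _wce_tensor(logits, labels[idx], wvec)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
    return trace


def mix_batches(real: list, replay: ReplaySet | None, batch_size: int,
                ratio: float, rng_seed: int) -> list[tuple[list[int], list[int]]]:
    """Index batches for one epoch: each batch takes ceil(ratio*batch_size)
    replay images (sampled uniformly with replacement) and fills the rest
    with real images; every real image appears exactly once per epoch."""
    if len(real) == 0:
        raise ValueError("real image set must be non-empty")
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must lie in [0, 1]")
    n_rep = math.ceil(ratio * batch_size)
    if n_rep > 0 and (replay is None or len(replay) == 0):
        raise ValueError("replay requested but no replay set supplied")
    n_real_per = max(1, batch_size - n_rep)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(real))
    batches = []
    for start in range(0, len(order), n_real_per):
        ridx = order[start:start + n_real_per].tolist()
        gidx = rng.integers(0, len(replay), size=n_rep).tolist() if n_rep else []
        batches.append((ridx, gidx))
    return batches


def _pseudo_labels_for(items, prev_model: SegmentationNet, gt_items,
                       threshold: float, registry: ClassRegistry,
                       curr_model: SegmentationNet) -> np.ndarray:
    out = []
    for img, gt in zip(items, gt_items):
        merged = pseudo_label_merge(seg_forward(prev_model, img), gt,
                                    threshold, registry)
        out.append(_to_channel_labels(merged, curr_model))
    return np.stack(out)


def run_incremental_step(state: IncrementalState,
                         dataset_t: list[AnnotatedImage],
                         config: TrainConfig | None = None) -> IncrementalState:
    """One incremental step: freeze the predecessor, expand the head, mix
    real and replay batches, and optimise the three-part objective."""
    config = config or TrainConfig()
    t = state.t + 1
    if t >= state.registry.num_steps:
        raise ValueError(f"registry defines only {state.registry.num_steps} steps")
    new_classes = state.registry.classes_at_step(t)
    known = set(state.curr_model.known_classes)
    ds_classes = {it.class_id for it in dataset_t}
    if ds_classes - set(new_classes):
        raise ValueError(f"dataset contains classes outside step {t}: "
                         f"{sorted(ds_classes - set(new_classes))}")
    if ds_classes & known:
        raise ValueError(f"dataset overlaps already-known classes: {sorted(ds_classes & known)}")
    if len(dataset_t) == 0:
        raise ValueError("dataset must be non-empty")

    prev = state.curr_model.snapshot()
    for p in prev.parameters():
        p.requires_grad = False
    curr = state.curr_model.snapshot()
    curr.expand_head(new_classes,
                     rng=np.random.default_rng(_derive_seed(config.seed, t, 1)))

    # replay set: generated once from the frozen diffusion model by default
    replay = state.replay
    if config.use_replay:
        if state.diffusion_model is None:
            raise ValueError("replay requested but no diffusion model in state")
        if replay is None or config.regenerate_replay:
            shape = dataset_t[0].image.shape
            replay = generate_replay_set(state.diffusion_model, state.sched,
                                         config.replay_n, shape,
                                         _derive_seed(config.seed, t, 2))

    # cached labels (class-id maps -> channel indices of the expanded head)
    if config.use_pseudo_labels:
        real_labels = _pseudo_labels_for([it.image for it in dataset_t], prev,
                                         dataset_t, config.confidence_threshold,
                                         state.registry, curr)
    else:
        real_labels = np.stack([_gt_labels(it, curr) for it in dataset_t])
    replay_labels = None
    if config.use_replay:
        replay_labels = _pseudo_labels_for(replay.images, prev,
                                           [None] * len(replay),
                                           config.confidence_threshold,
                                           state.registry, curr)

    weights = class_frequency_weights(dataset_t, state.registry,
                                      classes=curr.known_classes)
    wvec = _weight_vector(weights, curr)

    real_data = _stack_batch(dataset_t)
    replay_data = _stack_batch(replay.images) if config.use_replay else None

    head = state.head
    if config.use_cl and head is None:
        head = ProjectionHead(2 * config.width, config.proj_hidden,
                              config.proj_dim,
                              seed=_derive_seed(config.seed, t, 3))
    params = curr.parameters() + (head.parameters() if config.use_cl else [])
    opt = SGD(params, lr=config.lr, momentum=config.momentum,
              clip_norm=config.grad_clip)

    omega = list(config.kd_layer_weights)
    n_old = prev.num_channels
    trace = {"seg": [], "kd": [], "cl": [], "total": []}
    ratio = config.replay_ratio if config.use_replay else 0.0
    cl_rng = np.random.default_rng(_derive_seed(config.seed, t, 4))

    for epoch in range(config.epochs_per_step):
        batches = mix_batches(dataset_t, replay, config.batch_size, ratio,
                              _derive_seed(config.seed, t, 5, epoch))
        if config.recompute_pseudo_per_epoch and config.use_pseudo_labels:
            real_labels = _pseudo_labels_for([it.image for it in dataset_t],
                                             prev, dataset_t,
                                             config.confidence_threshold,
                                             state.registry, curr)
        ep = {k: [] for k in trace}
        for ridx, gidx in batches:
            n_real = len(ridx)
            x = real_data[ridx]
            labels = real_labels[ridx]
            if gidx:
                x = np.concatenate([x, replay_data[gidx]])
                labels = np.concatenate([labels, replay_labels[gidx]])
            logits, embs, z = curr.forward(Tensor(x))
            seg_loss = _wce_tensor(logits, labels, wvec)

            kd_term = None
            cl_term = None
            if config.use_kd or config.use_cl:
                p_logits, p_embs, p_z = prev.forward(Tensor(x))
            if config.use_kd:
                curr_embs = [embs[0], embs[1], embs[2][:, :n_old]]
                prev_embs = [p_embs[0].data, p_embs[1].data, p_embs[2].data]
                kd_term = kd_loss_tensor(prev_embs, curr_embs, omega,
                                         squared=config.kd_squared)
            if config.use_cl and gidx and n_real > 0:
                j = cl_rng.integers(0, len(gidx), size=n_real) + n_real
                proj_c = head.forward(z)
                proj_p = head.forward(Tensor(p_z.data))
                cl_term = contrastive_loss_tensor(
                    proj_c[np.arange(n_real)], proj_p[np.arange(n_real)],
                    proj_c[j], proj_p[j], config.tau)

            a, b, c = config.loss_multipliers
            total = seg_loss * a
            if kd_term is not None:
                total = total + kd_term * b
            if cl_term is not None:
                total = total + cl_term * c
            opt.zero_grad()
            total.backward()
            opt.step()
            ep["seg"].append(seg_loss.item())
            ep["kd"].append(kd_term.item() if kd_term is not None else 0.0)
            ep["cl"].append(cl_term.item() if cl_term is not None else 0.0)
            ep["total"].append(total.item())
        for k in trace:
            trace[k].append(float(np.mean(ep[k])))
        logger.info("step %d epoch %d seg=%.4f kd=%.4f cl=%.4f", t, epoch,
                    trace["seg"][-1], trace["kd"][-1], trace["cl"][-1])

    history = state.history + [{"step": t, "method": config.method_tag(),
                                **{f"{k}_loss": v for k, v in trace.items()}}]
    return IncrementalState(t=t, registry=state.registry, curr_model=curr,
                            prev_model=prev, diffusion_model=state.diffusion_model,
                            sched=state.sched, replay=replay, head=head,
                            history=history)


class IncrementalSegmenter(BaseEstimator):
    """Sklearn-style front end for the incremental protocol.

    ``fit(dataset_0, registry)`` runs the initial step; ``fit_step(dataset_t)``
    one increment; ``predict(images)`` returns per-pixel class-id maps from
    the current model. Fitted attributes: ``state_``, ``classes_``.
    """

    def __init__(self, *, epochs_initial: int = 24, epochs_per_step: int = 16,
                 batch_size: int = 16, lr: float = 1e-2, width: int = 16,
                 diffusion_steps: int = 60, diffusion_epochs: int = 50,
                 replay_n: int = 64, replay_ratio: float = 0.5,
                 use_pseudo_labels: bool = True, use_kd: bool = True,
                 use_replay: bool = True, use_cl: bool = True,
                 tau: float = 0.1, confidence_threshold: float = 0.7,
                 seed: int = 0):
        self.epochs_initial = epochs_initial
        self.epochs_per_step = epochs_per_step
        self.batch_size = batch_size
        self.lr = lr
        self.width = width
        self.diffusion_steps = diffusion_steps
        self.diffusion_epochs = diffusion_epochs
        self.replay_n = replay_n
        self.replay_ratio = replay_ratio
        self.use_pseudo_labels = use_pseudo_labels
        self.use_kd = use_kd
        self.use_replay = use_replay
        self.use_cl = use_cl
        self.tau = tau
        self.confidence_threshold = confidence_threshold
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs_initial=self.epochs_initial,
            epochs_per_step=self.epochs_per_step,
            batch_size=self.batch_size, lr=self.lr, width=self.width,
            train_diffusion=self.use_replay,
            diffusion_steps=self.diffusion_steps,
            diffusion_epochs=self.diffusion_epochs,
            replay_n=self.replay_n, replay_ratio=self.replay_ratio,
            use_pseudo_labels=self.use_pseudo_labels, use_kd=self.use_kd,
            use_replay=self.use_replay, use_cl=self.use_cl, tau=self.tau,
            confidence_threshold=self.confidence_threshold, seed=self.seed)

    def fit(self, dataset_0: list[AnnotatedImage], registry: ClassRegistry):
        self.state_ = run_initial_step(dataset_0, registry, self._config())
        self.classes_ = np.asarray(registry.classes_at_step(0))
        return self

    def fit_step(self, dataset_t: list[AnnotatedImage]):
        if not hasattr(self, "state_"):
            raise RuntimeError("call fit() before fit_step()")
        self.state_ = run_incremental_step(self.state_, dataset_t, self._config())
        self.classes_ = np.asarray(self.state_.curr_model.known_classes)
        return self

    def predict(self, images: list[np.ndarray]) -> list[np.ndarray]:
        from .segmentation import predict_with_confidence
        out = []
        for im in images:
            labels, _ = predict_with_confidence(seg_forward(self.state_.curr_model, im))
            out.append(labels)
        return out
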