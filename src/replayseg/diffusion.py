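"""Unconditional denoising diffusion (DDPM) for generative replay.

The generator is trained once on the initial step's images and frozen; its
samples stand in for inaccessible earlier-step data during incremental
training. Images are H×W×C arrays in [-1, 1]. Diffusion steps are indexed
s = 1..S; a variance schedule beta_s controls how much signal survives each
forward step, with alpha_s = 1 - beta_s and alpha_bar_s their running
product. Training minimises the mean squared discrepancy between injected
and predicted noise; sampling runs the learned reverse (ancestral) chain
from pure Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._engine import AdamW, Conv2d, Linear, Module, Tensor, avg_pool2, concat, \
    sinusoidal_embedding, upsample_nearest2

__all__ = [
    "NoiseSchedule",
    "build_linear_schedule",
    "forward_noise",
    "ddpm_training_loss",
    "reverse_step",
    "ancestral_sample",
    "NoisePredictorNet",
    "DiffusionTrainConfig",
    "fit_diffusion",
    "ReplaySet",
    "generate_replay_set",
    "save_predictor",
    "load_predictor",
]


# ---------------------------------------------------------------------------
# Noise schedule
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class NoiseSchedule:
    """Arrays governing the diffusion process, indexed by step s = 1..S.

    ``betas[s-1]`` is the variance added at step s; ``alpha_bars`` is the
    cumulative product of ``alphas``; ``sigmas`` the reverse-step standard
    deviations (sigma_s^2 = beta_s, with sigma_1 = 0 so the final reverse
    step is deterministic).
    """

    S: int
    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self):
        if self.S < 1:
            raise ValueError("S must be >= 1")
        for name in ("betas", "alphas", "alpha_bars", "sigmas"):
            arr = getattr(self, name)
            if arr.shape != (self.S,):
                raise ValueError(f"{name} must have shape ({self.S},)")
        if np.any(self.betas <= 0) or np.any(self.betas >= 1):
            raise ValueError("betas must lie strictly inside (0, 1)")
        if np.any(self.sigmas < 0):
            raise ValueError("sigmas must be nonnegative")


def build_linear_schedule(S: int, beta_start: float = 1e-4,
                          beta_end: float = 0.02) -> NoiseSchedule:
    """Linearly spaced variance schedule (the original-DDPM convention)."""
    if S < 1:
        raise ValueError("S must be a positive integer")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError("require 0 < beta_start <= beta_end < 1")
    betas = np.linspace(beta_start, beta_end, S, dtype=np.float64)
    alphas = 1.0 - betas
    alpha_bars = np.cumprod(alphas)
    sigmas = np.sqrt(betas)
    sigmas[0] = 0.0  # z = 0 at the final reverse step
    return NoiseSchedule(S=S, betas=betas, alphas=alphas,
                         alpha_bars=alpha_bars, sigmas=sigmas)


def _check_step(s: int, S: int) -> None:
    if not (1 <= s <= S):
        raise IndexError(f"diffusion step s={s} out of range 1..{S}")


def _check_shapes(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch among inputs: {sorted(shapes)}")


# ---------------------------------------------------------------------------
# Forward / reverse processes
# ---------------------------------------------------------------------------

def forward_noise(x0: np.ndarray, s: int, eps: np.ndarray,
                  sched: NoiseSchedule) -> np.ndarray:
    """Noise a clean image to step s: sqrt(abar_s) x0 + sqrt(1-abar_s) eps."""
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    _check_step(s, sched.S)
    _check_shapes(x0, eps)
    ab = sched.alpha_bars[s - 1]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def ddpm_training_loss(model, x0: np.ndarray, s: int, eps: np.ndarray,
                       sched: NoiseSchedule) -> float:
    """Noise-prediction objective: mean over elements of (eps - eps_hat)^2."""
    xs = forward_noise(x0, s, eps, sched)
    pred = np.asarray(model.predict(xs, s), dtype=np.float64)
    _check_shapes(pred, eps)
    return float(np.mean((eps - pred) ** 2))


def reverse_step(model, x_s: np.ndarray, s: int, sched: NoiseSchedule,
                 z: np.ndarray) -> np.ndarray:
    """One ancestral denoising step from x_s to x_{s-1}."""
    x_s = np.asarray(x_s, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    _check_step(s, sched.S)
    _check_shapes(x_s, z)
    if s == 1 and np.any(z != 0):
        raise ValueError("z must be all-zeros at the final reverse step (s=1)")
    eps_hat = np.asarray(model.predict(x_s, s), dtype=np.float64)
    _check_shapes(eps_hat, x_s)
    a = sched.alphas[s - 1]
    ab = sched.alpha_bars[s - 1]
    mean = (x_s - (1.0 - a) / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(a)
    return mean + sched.sigmas[s - 1] * z


def ancestral_sample(model, sched: NoiseSchedule, shape: tuple[int, int, int],
                     rng_seed: int) -> np.ndarray:
    """Draw one image by iterating reverse_step from s = S down to 1.

    Deterministic given ``rng_seed``: the initial noise image and every
    per-step z come from one ``numpy.random.Generator`` in a fixed order.
    """
    n_steps = getattr(model, "n_steps", None)
    if n_steps is not None and n_steps != sched.S:
        raise ValueError(f"model was configured for S={n_steps}, schedule has S={sched.S}")
    rng = np.random.default_rng(rng_seed)
    x = rng.standard_normal(shape)
    for s in range(sched.S, 0, -1):
        z = rng.standard_normal(shape) if s > 1 else np.zeros(shape)
        x = reverse_step(model, x, s, sched, z)
    return x


# ---------------------------------------------------------------------------
# Noise-prediction network
# ---------------------------------------------------------------------------

class NoisePredictorNet(Module):
    """Small two-level U-Net-style noise predictor with sinusoidal step
    embedding, sized for 16-64 px images.

    ``predict`` operates on a single H×W×C image; ``predict_batch`` on an
    N×C×H×W batch with per-image step indices (used by training and batched
    sampling).
    """

    def __init__(self, channels: int = 3, width: int = 16, emb_dim: int = 32,
                 n_steps: int | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = width
        self.channels = channels
        self.width = width
        self.emb_dim = emb_dim
        self.n_steps = n_steps
        self.seed = seed
        self.temb1 = Linear(emb_dim, 2 * emb_dim, rng)
        self.temb_e1 = Linear(2 * emb_dim, w, rng)
        self.temb_e2 = Linear(2 * emb_dim, 2 * w, rng)
        self.enc1a = Conv2d(channels, w, 3, rng)
        self.enc1b = Conv2d(w, w, 3, rng)
        self.enc2a = Conv2d(w, 2 * w, 3, rng)
        self.enc2b = Conv2d(2 * w, 2 * w, 3, rng)
        self.deca = Conv2d(3 * w, w, 3, rng)
        self.out = Conv2d(w, channels, 1, rng)
        # near-zero output head: the untrained net predicts ~no noise
        self.out.w.data *= 0.01

    def _forward(self, x: Tensor, s: np.ndarray) -> Tensor:
        n = x.data.shape[0]
        emb = Tensor(sinusoidal_embedding(s, self.emb_dim))
        emb = self.temb1(emb).relu()
        b1 = self.temb_e1(emb).reshape(n, self.width, 1, 1)
        b2 = self.temb_e2(emb).reshape(n, 2 * self.width, 1, 1)
        h1 = self.enc1a(x).relu()
        h1 = self.enc1b(h1 + b1).relu()
        h2 = avg_pool2(h1)
        h2 = self.enc2a(h2).relu()
        h2 = self.enc2b(h2 + b2).relu()
        u = upsample_nearest2(h2)
        d = self.deca(concat([u, h1], axis=1)).relu()
        return self.out(d)

    def predict_batch(self, x_nchw: np.ndarray, s: np.ndarray) -> np.ndarray:
        out = self._forward(Tensor(x_nchw.astype(np.float32)), np.asarray(s))
        return out.data

    def predict(self, x_hwc: np.ndarray, s: int) -> np.ndarray:
        x = np.asarray(x_hwc, dtype=np.float32)
        batch = np.transpose(x, (2, 0, 1))[None]
        out = self.predict_batch(batch, np.array([s]))
        return np.transpose(out[0], (1, 2, 0)).astype(np.float64)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DiffusionTrainConfig:
    epochs: int = 20
    batch_size: int = 16
    lr: float = 2e-3
    weight_decay: float = 1e-4
    width: int = 16
    seed: int = 0


def _to_nchw(images: list[np.ndarray]) -> np.ndarray:
    return np.stack([np.transpose(np.asarray(im, dtype=np.float32), (2, 0, 1))
                     for im in images])


def fit_diffusion(images: list[np.ndarray], sched: NoiseSchedule,
                  config: DiffusionTrainConfig | None = None) -> NoisePredictorNet:
    """Train a noise predictor on clean images; returns it with
    ``loss_history`` (per-epoch mean objective) attached."""
    config = config or DiffusionTrainConfig()
    if len(images) == 0:
        raise ValueError("training dataset must be non-empty")
    if config.epochs < 1:
        raise ValueError("epochs must be >= 1")
    data = _to_nchw(images)
    n, c = data.shape[0], data.shape[1]
    ss = np.random.SeedSequence([config.seed, 0x0D1F])
    net_seed, loop_seed = ss.generate_state(2) >> 1  # keep below 2^31
    model = NoisePredictorNet(channels=c, width=config.width,
                              n_steps=sched.S, seed=int(net_seed))
    rng = np.random.default_rng(int(loop_seed))
    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    sqrt_ab = np.sqrt(sched.alpha_bars).astype(np.float32)
    sqrt_1mab = np.sqrt(1.0 - sched.alpha_bars).astype(np.float32)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x0 = data[idx]
            s = rng.integers(1, sched.S + 1, size=len(idx))
            eps = rng.standard_normal(x0.shape).astype(np.float32)
            coef_a = sqrt_ab[s - 1][:, None, None, None]
            coef_b = sqrt_1mab[s - 1][:, None, None, None]
            xs = coef_a * x0 + coef_b * eps
            pred = model._forward(Tensor(xs), s)
            loss = ((pred - Tensor(eps)) ** 2.0).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    model.loss_history = history
    return model


# ---------------------------------------------------------------------------
# Replay sets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReplaySet:
    """N generated images plus the provenance needed to regenerate them."""

    images: list[np.ndarray]
    checkpoint_id: str
    seed: int
    S: int

    def __post_init__(self):
        if len(self.images) == 0:
            raise ValueError("replay set must contain at least one image")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError("all replay images must share one shape")

    def __len__(self) -> int:
        return len(self.images)


def _per_image_seeds(master_seed: int, n: int) -> list[int]:
    # child i <- SeedSequence(master).spawn order; folded below 2^31
    return [int(x) for x in
            (np.random.SeedSequence(master_seed).generate_state(n) >> 1)]


def generate_replay_set(model, sched: NoiseSchedule, N: int,
                        shape: tuple[int, int, int], rng_seed: int,
                        checkpoint_id: str = "in-memory") -> ReplaySet:
    """Draw N ancestral samples with per-image seeds derived from one master
    seed; batched over images for speed but bit-identical to N independent
    :func:`ancestral_sample` calls when the model supports batching."""
    if N < 1:
        raise ValueError("N must be a positive integer")
    n_steps = getattr(model, "n_steps", None)
    if n_steps is not None and n_steps != sched.S:
        raise ValueError(f"model was configured for S={n_steps}, schedule has S={sched.S}")
    seeds = _per_image_seeds(rng_seed, N)
    if hasattr(model, "predict_batch"):
        rngs = [np.random.default_rng(s) for s in seeds]
        x = np.stack([r.standard_normal(shape) for r in rngs])
        nchw = np.transpose(x, (0, 3, 1, 2))
        for s in range(sched.S, 0, -1):
            eps_hat = model.predict_batch(nchw.astype(np.float32),
                                          np.full(N, s))
            eps_hat = np.transpose(np.asarray(eps_hat, dtype=np.float64), (0, 2, 3, 1))
            a = sched.alphas[s - 1]
            ab = sched.alpha_bars[s - 1]
            x = (x - (1.0 - a) / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(a)
            if s > 1:
                z = np.stack([r.standard_normal(shape) for r in rngs])
                x = x + sched.sigmas[s - 1] * z
            nchw = np.transpose(x, (0, 3, 1, 2))
        images = [x[i] for i in range(N)]
    else:
        images = [ancestral_sample(model, sched, shape, s) for s in seeds]
    return ReplaySet(images=images, checkpoint_id=checkpoint_id,
                     seed=rng_seed, S=sched.S)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_predictor(model: NoisePredictorNet, sched: NoiseSchedule,
                   path: str | Path) -> None:
    """Self-describing checkpoint: parameters plus embedded schedule arrays."""
    meta = {"channels": model.channels, "width": model.width,
            "emb_dim": model.emb_dim, "n_steps": model.n_steps,
            "seed": model.seed}
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), betas=sched.betas, **arrays)


def load_predictor(path: str | Path) -> tuple[NoisePredictorNet, NoiseSchedule]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        betas = data["betas"]
        params = [data[f"param_{i}"] for i in range(len(data.files) - 2)]
    sched = build_linear_schedule(len(betas), float(betas[0]), float(betas[-1]))
    model = NoisePredictorNet(channels=meta["channels"], width=meta["width"],
                              emb_dim=meta["emb_dim"], n_steps=meta["n_steps"],
                              seed=meta["seed"])
    model.load_state_arrays(params)
    return model, sched
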