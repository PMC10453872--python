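"""Seeded semi-supervised DCGAN training loop and image generation.

Each minibatch takes one discriminator step and one generator step. The
discriminator step runs real and generated images through one forward pass
and combines three gradients at the softmax logits: push P(real) → 1 on
real inputs, P(real) → 0 on generated inputs, and cross-entropy toward the
true class on the labeled real inputs. The generator step then backprops
its adversarial objective through the (frozen) discriminator. Both networks
update with classical-momentum SGD.

Every iteration is recorded in a :class:`TrainingTrace`: discriminator /
generator scores (mean P(real) on the real and generated halves of the
batch — 0.5 for both marks the game's equilibrium) and every loss
component. All randomness derives from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..image import ImageTensor, RANGE_UNIT
from .layers import BatchNorm2d, Conv2d, ConvTranspose2d, Param, Sequential
from .losses import EPS, discriminator_loss, generator_loss, supervised_loss
from .nets import (
    DiscriminatorNet,
    GeneratorNet,
    build_discriminator,
    build_generator,
)

__all__ = [
    "TrainConfig",
    "TrainingTrace",
    "SGDM",
    "train_dcgan",
    "generate_images",
    "sample_latent",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of a training run.

    Defaults are the reference settings: SGDM with learning rate 0.01 and
    momentum 0.5, minibatch 64, N(0, 0.02²) weight init, length-100
    latents, saturating generator loss, validation every 50 iterations.
    """

    learning_rate: float = 0.01
    momentum: float = 0.5
    batch_size: int = 64
    epochs: int = 10
    init_std: float = 0.02
    seed: int = 0
    generator_loss_form: str = "saturating"
    latent_dim: int = 100
    n_classes: int = 2
    validation_every: int = 50

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.generator_loss_form not in ("saturating", "nonsaturating"):
            raise ValueError("generator_loss_form must be saturating|nonsaturating")


@dataclass
class TrainingTrace:
    """Per-iteration scores/losses and per-epoch validation accuracy."""

    d_score: list = field(default_factory=list)
    g_score: list = field(default_factory=list)
    d_loss: list = field(default_factory=list)
    d_real_loss: list = field(default_factory=list)
    d_fake_loss: list = field(default_factory=list)
    g_loss: list = field(default_factory=list)
    supervised_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)  # one entry per epoch
    val_history: list = field(default_factory=list)  # (iteration, accuracy)

    def __len__(self) -> int:
        return len(self.d_score)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self)),
                "d_score": self.d_score,
                "g_score": self.g_score,
                "d_loss": self.d_loss,
                "d_real_loss": self.d_real_loss,
                "d_fake_loss": self.d_fake_loss,
                "g_loss": self.g_loss,
                "supervised_loss": self.supervised_loss,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class SGDM:
    """Classical-momentum SGD over a list of :class:`Param` objects."""

    def __init__(self, params: list[Param], lr: float, momentum: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v


def sample_latent(n: int, latent_dim: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n latent vectors from the standard normal prior p_z."""
    return rng.standard_normal((n, latent_dim)).astype(np.float32)


def _as_nchw(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError("images must be a 4-D array")
    if x.shape[1:] == (64, 64, 3):
        x = x.transpose(0, 3, 1, 2)
    if x.shape[1:] != (3, 64, 64):
        raise ValueError(f"images must be 64×64×3, got {x.shape[1:]}")
    return np.ascontiguousarray(x)


def _onehot(idx: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((idx.size, k))
    out[np.arange(idx.size), idx] = 1.0
    return out


def _grad_neglog_preal(probs: np.ndarray, fake_idx: int) -> np.ndarray:
    """Per-row logit gradient of −log(1 − p_fake) = −log P(real).

    Written in its algebraically simplified (bounded) form: the naive
    chain-rule factor p_fake/(1 − p_fake) overflows once the discriminator
    saturates, whereas every entry of this form lies in [−1, 1].
    """
    pf = probs[:, fake_idx]
    s = np.clip(1.0 - pf, EPS, None)
    g = -probs * (pf / s)[:, None]
    g[:, fake_idx] = pf
    return g


def _set_bn_tracking(D: DiscriminatorNet, flag: bool) -> None:
    for layer in D.net.layers:
        if isinstance(layer, BatchNorm2d):
            layer.track_running = flag


def _accuracy(D: DiscriminatorNet, x: np.ndarray, y: np.ndarray,
              batch: int = 64) -> float:
    hits = 0
    for i in range(0, x.shape[0], batch):
        probs = D.forward(x[i : i + batch], train=False)
        pred = np.argmax(D.class_probs(probs), axis=1)
        hits += int(np.sum(pred == y[i : i + batch]))
    return hits / x.shape[0]


def train_dcgan(
    train_images: np.ndarray,
    train_labels: np.ndarray,
    unlabeled_mask: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> tuple[GeneratorNet, DiscriminatorNet, TrainingTrace]:
    """Train generator and discriminator; returns them with the trace.

    ``train_images`` must be preprocessed 64×64×3 images in [−1, 1]
    (HWC or CHW layout); ``train_labels`` holds class indices for every
    record, and ``unlabeled_mask`` marks records whose labels are withheld
    from the supervised term. The run is fully determined by ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    x_all = _as_nchw(train_images)
    y_all = np.asarray(train_labels, dtype=np.intp)
    n = x_all.shape[0]
    if y_all.shape != (n,):
        raise ValueError("train_labels must align with train_images")
    mask = (
        np.zeros(n, dtype=bool)
        if unlabeled_mask is None
        else np.asarray(unlabeled_mask, dtype=bool)
    )
    if mask.shape != (n,):
        raise ValueError("unlabeled_mask must align with train_images")
    if np.all(mask):
        raise ValueError("semi-supervised training needs at least one labeled record")
    if cfg.batch_size > n:
        raise ValueError("batch_size exceeds the training-set size")

    G = build_generator(cfg.latent_dim, seed=cfg.seed, init_std=cfg.init_std)
    D = build_discriminator(cfg.n_classes, seed=cfg.seed + 1, init_std=cfg.init_std)
    opt_g = SGDM(G.params(), cfg.learning_rate, cfg.momentum)
    opt_d = SGDM(D.params(), cfg.learning_rate, cfg.momentum)

    xv = _as_nchw(val_images) if val_images is not None else None
    yv = np.asarray(val_labels, dtype=np.intp) if val_labels is not None else None

    rng = np.random.default_rng([cfg.seed, 0x6A17])
    trace = TrainingTrace()
    fake_idx = D.fake_index
    k = cfg.n_classes + 1
    b = cfg.batch_size
    iters_per_epoch = n // b
    it = 0

    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for step in range(iters_per_epoch):
            idx = order[step * b : (step + 1) * b]
            x_real, y_real = x_all[idx], y_all[idx]
            labeled = ~mask[idx]

            # ---- discriminator step (generator held constant) ----
            # real and generated batches take separate forward passes so
            # each is normalized by its own batch statistics (and the
            # generator step below sees the same fake-batch statistics)
            z = sample_latent(b, cfg.latent_dim, rng)
            x_fake = G.forward(z, train=True)
            D.zero_grad()
            fake_onehot = np.zeros(k, dtype=np.float32)
            fake_onehot[fake_idx] = 1.0

            _set_bn_tracking(D, True)  # real batches define eval statistics
            p_r = D.forward(x_real, train=True)
            pf_r = p_r[:, fake_idx]
            # real batch: minimize −log(1 − p_fake) + supervised CE
            dlogits_r = _grad_neglog_preal(p_r, fake_idx).astype(np.float32) / b
            if np.any(labeled):
                sup_l = supervised_loss(p_r[labeled], y_real[labeled])
                dlogits_r[labeled] += (
                    (p_r[labeled] - _onehot(y_real[labeled], k)) / int(labeled.sum())
                ).astype(np.float32)
            else:
                sup_l = 0.0
            D.backward(dlogits_r)

            _set_bn_tracking(D, False)  # generated batches do not
            p_f = D.forward(x_fake, train=True)
            pf_f = p_f[:, fake_idx]
            # fake batch: minimize −log p_fake
            D.backward((p_f - fake_onehot[None, :]).astype(np.float32) / b)
            opt_d.step()
            d_loss, d_real_l, d_fake_l = discriminator_loss(1.0 - pf_r, 1.0 - pf_f)

            # ---- generator step (discriminator held constant) ----
            z = sample_latent(b, cfg.latent_dim, rng)
            G.zero_grad()
            D.zero_grad()  # gradients below are discarded for D
            x_fake = G.forward(z, train=True)
            probs_g = D.forward(x_fake, train=True)
            pf_g = probs_g[:, fake_idx]
            g_loss = generator_loss(1.0 - pf_g, cfg.generator_loss_form)
            if cfg.generator_loss_form == "saturating":
                dlog = (fake_onehot[None, :] - probs_g) / b
            else:
                dlog = _grad_neglog_preal(probs_g, fake_idx) / b
            G.backward(D.backward(dlog))
            opt_g.step()

            # scores share the loss functions' epsilon clamp so they stay
            # strictly inside (0, 1) even when the float32 softmax saturates
            trace.d_score.append(float(np.clip(np.mean(1.0 - pf_r), EPS, 1.0 - EPS)))
            trace.g_score.append(float(np.clip(np.mean(1.0 - pf_f), EPS, 1.0 - EPS)))
            trace.d_loss.append(d_loss)
            trace.d_real_loss.append(d_real_l)
            trace.d_fake_loss.append(d_fake_l)
            trace.g_loss.append(g_loss)
            trace.supervised_loss.append(float(sup_l))
            it += 1
            if (
                xv is not None
                and cfg.validation_every > 0
                and it % cfg.validation_every == 0
            ):
                trace.val_history.append((it, _accuracy(D, xv, yv)))
        if xv is not None:
            trace.val_accuracy.append(_accuracy(D, xv, yv))

    return G, D, trace


def generate_images(G: GeneratorNet, n: int, seed: int = 0) -> list[ImageTensor]:
    """Sample n images from the generator, rescaled from (−1,1) to [0,1]."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    out: list[ImageTensor] = []
    for i in range(0, n, 64):
        z = sample_latent(min(64, n - i), G.latent_dim, rng)
        x = G.forward(z, train=False)  # (B, 3, 64, 64) in (−1, 1)
        for img in x:
            out.append(
                ImageTensor((img.transpose(1, 2, 0) + 1.0) / 2.0, RANGE_UNIT, "RGB")
            )
    return out


# ----------------------------------------------------------------------
# checkpoints: weight arrays + config + normalization statistics
# ----------------------------------------------------------------------

def _state_arrays(net: Sequential) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    for i, layer in enumerate(net.layers):
        if isinstance(layer, (Conv2d, ConvTranspose2d)):
            state[f"{i}.W"] = layer.W.data
            if layer.b is not None:
                state[f"{i}.b"] = layer.b.data
        elif isinstance(layer, BatchNorm2d):
            state[f"{i}.gamma"] = layer.gamma.data
            state[f"{i}.beta"] = layer.beta.data
            state[f"{i}.running_mean"] = layer.running_mean
            state[f"{i}.running_var"] = layer.running_var
    return state


def _load_state(net: Sequential, state: dict[str, np.ndarray], prefix: str) -> None:
    for i, layer in enumerate(net.layers):
        if isinstance(layer, (Conv2d, ConvTranspose2d)):
            layer.W.data[...] = state[f"{prefix}{i}.W"]
            if layer.b is not None:
                layer.b.data[...] = state[f"{prefix}{i}.b"]
        elif isinstance(layer, BatchNorm2d):
            layer.gamma.data[...] = state[f"{prefix}{i}.gamma"]
            layer.beta.data[...] = state[f"{prefix}{i}.beta"]
            layer.running_mean[...] = state[f"{prefix}{i}.running_mean"]
            layer.running_var[...] = state[f"{prefix}{i}.running_var"]


def save_checkpoint(
    path: str | Path, G: GeneratorNet, D: DiscriminatorNet, cfg: TrainConfig
) -> None:
    """Write both networks + config to a single ``.npz`` container."""
    arrays = {f"g.{k}": v for k, v in _state_arrays(G.net).items()}
    arrays |= {f"d.{k}": v for k, v in _state_arrays(D.net).items()}
    arrays["meta"] = np.frombuffer(
        json.dumps(
            {"config": asdict(cfg), "latent_dim": G.latent_dim, "n_classes": D.n_classes}
        ).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **arrays)


def load_checkpoint(
    path: str | Path,
) -> tuple[GeneratorNet, DiscriminatorNet, TrainConfig]:
    """Rebuild the networks and config saved by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = {k: data[k] for k in data.files if k != "meta"}
    cfg = TrainConfig(**meta["config"])
    G = build_generator(meta["latent_dim"], seed=cfg.seed, init_std=cfg.init_std)
    D = build_discriminator(meta["n_classes"], seed=cfg.seed + 1, init_std=cfg.init_std)
    _load_state(G.net, state, "g.")
    _load_state(D.net, state, "d.")
    return G, D, cfg
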