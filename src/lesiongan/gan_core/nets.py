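"""Generator and discriminator constructors for the improved DCGAN.

Generator (5 fractional-stride stages, batch norm + ReLU, Tanh output):

    z (latent_dim) → 4×4×512 → 8×8×256 → 16×16×128 → 32×32×64 → 64×64×3

Discriminator (5 convolutional layers, LeakyReLU 0.2, softmax head):

    64×64×3 → 32×32×64 → 16×16×128 → 8×8×256 → 4×4×512 → N+1 units

The head's ``N+1`` units are the ``N`` real classes (benign, malignant)
plus one fake class; ``p_real = 1 − p_fake`` and class prediction
renormalizes the real-class probabilities. Convolution kernels are 4×4
with stride 2, padding 1 (stride 1, no padding at the ends of each tower).
All convolution weights are drawn from N(0, 0.02²); biases start at zero.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    LeakyReLU,
    Param,
    ReLU,
    Sequential,
    Tanh,
)

__all__ = [
    "GeneratorNet",
    "DiscriminatorNet",
    "build_generator",
    "build_discriminator",
    "init_weights",
]

GENERATOR_FEATURE_MAPS = (512, 256, 128, 64, 3)
GENERATOR_SPATIAL_SIZES = (4, 8, 16, 32, 64)
LEAKY_SLOPE = 0.2
DEFAULT_INIT_STD = 0.02


class GeneratorNet:
    """G(z; Wg): latent vector → 64×64×3 image in (−1, 1)."""

    def __init__(self, latent_dim: int, net: Sequential):
        self.latent_dim = latent_dim
        self.net = net

    def forward(self, z: np.ndarray, train: bool = True) -> np.ndarray:
        """Map latents (N, latent_dim) to images (N, 3, 64, 64)."""
        z = np.asarray(z, dtype=np.float32)
        if z.ndim != 2 or z.shape[1] != self.latent_dim:
            raise ValueError(f"expected latents of shape (N, {self.latent_dim})")
        return self.net.forward(z[:, :, None, None], train=train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)

    def stage_shapes(self, z: np.ndarray) -> list[tuple[int, ...]]:
        """Spatial shape after each fractional-stride stage (diagnostics)."""
        x = np.asarray(z, dtype=np.float32)[:, :, None, None]
        shapes = []
        for layer in self.net.layers:
            x = layer.forward(x, train=True)
            if isinstance(layer, (ReLU, Tanh)):
                shapes.append(x.shape[1:])
        return shapes

    def params(self) -> list[Param]:
        return self.net.params()

    def zero_grad(self) -> None:
        self.net.zero_grad()


class DiscriminatorNet:
    """D(x; Wd): image → N+1 class probabilities (real classes + fake)."""

    def __init__(self, n_classes: int, net: Sequential):
        self.n_classes = n_classes
        self.net = net

    @property
    def fake_index(self) -> int:
        return self.n_classes

    def logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:] != (3, 64, 64):
            raise ValueError("expected images of shape (N, 3, 64, 64)")
        out = self.net.forward(x, train=train)
        return out.reshape(out.shape[0], self.n_classes + 1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Softmax probabilities over {real classes…, fake}, rows sum to 1."""
        return softmax(self.logits(x, train=train))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(
            dlogits.reshape(dlogits.shape[0], self.n_classes + 1, 1, 1)
        )

    def p_real(self, probs: np.ndarray) -> np.ndarray:
        """P(input is real) = 1 − P(fake class)."""
        return 1.0 - probs[:, self.fake_index]

    def class_probs(self, probs: np.ndarray) -> np.ndarray:
        """Real-class probabilities renormalized to sum to 1."""
        real = probs[:, : self.n_classes]
        return real / np.clip(real.sum(axis=1, keepdims=True), 1e-12, None)

    def params(self) -> list[Param]:
        return self.net.params()

    def zero_grad(self) -> None:
        self.net.zero_grad()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def init_weights(net, seed: int, std: float = DEFAULT_INIT_STD):
    """Draw all convolution weights from N(0, std²); zero all biases.

    Batch-norm scale/shift keep their identity initialization (1, 0).
    Returns the network for chaining.
    """
    if std <= 0:
        raise ValueError("std must be positive")
    rng = np.random.default_rng(seed)
    layers = net.net.layers if hasattr(net, "net") else net.layers
    for layer in layers:
        if isinstance(layer, (Conv2d, ConvTranspose2d)):
            layer.W.data[...] = rng.normal(0.0, std, layer.W.data.shape).astype(
                layer.W.data.dtype
            )
            if layer.b is not None:
                layer.b.data.fill(0.0)
    return net


def build_generator(
    latent_dim: int = 100, seed: int = 0, init_std: float = DEFAULT_INIT_STD
) -> GeneratorNet:
    """Five-stage transposed-convolution generator, seeded initialization."""
    if latent_dim < 1:
        raise ValueError("latent_dim must be at least 1")
    net = Sequential(
        ConvTranspose2d(latent_dim, 512, 4, 1, 0),  # 1×1 → 4×4
        BatchNorm2d(512),
        ReLU(),
        ConvTranspose2d(512, 256, 4, 2, 1),  # 8×8
        BatchNorm2d(256),
        ReLU(),
        ConvTranspose2d(256, 128, 4, 2, 1),  # 16×16
        BatchNorm2d(128),
        ReLU(),
        ConvTranspose2d(128, 64, 4, 2, 1),  # 32×32
        BatchNorm2d(64),
        ReLU(),
        ConvTranspose2d(64, 3, 4, 2, 1),  # 64×64
        Tanh(),
    )
    return init_weights(GeneratorNet(latent_dim, net), seed, init_std)


def build_discriminator(
    n_classes: int = 2, seed: int = 0, init_std: float = DEFAULT_INIT_STD
) -> DiscriminatorNet:
    """Five-layer strided-convolution discriminator with N+1 softmax head."""
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    net = Sequential(
        Conv2d(3, 64, 4, 2, 1),  # 32×32
        LeakyReLU(LEAKY_SLOPE),
        Conv2d(64, 128, 4, 2, 1),  # 16×16
        BatchNorm2d(128),
        LeakyReLU(LEAKY_SLOPE),
        Conv2d(128, 256, 4, 2, 1),  # 8×8
        BatchNorm2d(256),
        LeakyReLU(LEAKY_SLOPE),
        Conv2d(256, 512, 4, 2, 1),  # 4×4
        BatchNorm2d(512),
        LeakyReLU(LEAKY_SLOPE),
        Conv2d(512, n_classes + 1, 4, 1, 0),  # 1×1 logits
    )
    return init_weights(DiscriminatorNet(n_classes, net), seed, init_std)
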