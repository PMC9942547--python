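"""Convolutional denoising autoencoder for ion images.

MSI ion images carry strong pixel-level intensity noise on top of the
spatial pattern of the underlying ion.  Before any similarity between
images is measured, each image ``x`` is passed through a small
convolutional autoencoder: an encoder ``E`` (two strided convolutions and
a linear map to a d-dimensional embedding ``z``) and a decoder ``D`` (a
linear map and two transposed convolutions with a sigmoid output), so that
the reconstruction ``x̃ = D(E(x))`` is a smoothed, denoised version of the
image bounded to [0, 1].  The autoencoder is trained on the images
themselves with the summed squared reconstruction error

    L_ae = Σ_i ‖x_i − x̃_i‖²

and the denoised images — not the raw ones — feed the clustering CNN.
"""

from __future__ import annotations

import json

import numpy as np

from . import _nn
from .data_model import IonImageStack

__all__ = [
    "ConvAutoencoder",
    "encode",
    "decode",
    "denoise",
    "reconstruction_loss",
    "pretrain",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


class ConvAutoencoder:
    """Denoiser state: encoder/decoder weights plus the architecture spec.

    Parameters
    ----------
    height, width
        Image grid size; must be divisible by 4 (two stride-2 stages).
    embed_dim
        Bottleneck dimension d (default 7).
    channels
        Channel widths of the two encoder convolutions.
    seed
        Initialization seed.
    """

    def __init__(self, height: int, width: int, embed_dim: int = 7,
                 channels: tuple[int, int] = (16, 32), seed: int = 0):
        if height % 4 or width % 4:
            raise ValueError("image height and width must be divisible by 4")
        rng = np.random.default_rng(seed)
        c1, c2 = channels
        h4, w4 = height // 4, width // 4
        self.height, self.width = height, width
        self.embed_dim = embed_dim
        self.channels = (c1, c2)
        self.encoder = _nn.Sequential(
            _nn.Conv2d(1, c1, 3, stride=2, pad=1, rng=rng),
            _nn.ReLU(),
            _nn.Conv2d(c1, c2, 3, stride=2, pad=1, rng=rng),
            _nn.ReLU(),
            _nn.Flatten(),
            _nn.Linear(c2 * h4 * w4, embed_dim, rng=rng),
        )
        self.decoder = _nn.Sequential(
            _nn.Linear(embed_dim, c2 * h4 * w4, rng=rng),
            _nn.ReLU(),
            _nn.Reshape((c2, h4, w4)),
            _nn.ConvTranspose2d(c2, c1, 3, stride=2, pad=1, output_pad=1, rng=rng),
            _nn.ReLU(),
            _nn.ConvTranspose2d(c1, 1, 3, stride=2, pad=1, output_pad=1, rng=rng),
            _nn.Sigmoid(),
        )
        self.pretrain_history: list[float] = []

    def params(self) -> list[_nn.Param]:
        return self.encoder.params() + self.decoder.params()

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        arch = {
            "height": self.height, "width": self.width,
            "embed_dim": self.embed_dim, "channels": list(self.channels),
        }
        arrays = {f"p{i}": p.val for i, p in enumerate(self.params())}
        bn_extra = {}
        np.savez(path, arch=np.bytes_(json.dumps(arch)), **arrays, **bn_extra)

    @classmethod
    def load(cls, path) -> "ConvAutoencoder":
        with np.load(path) as f:
            arch = json.loads(bytes(f["arch"]).decode())
            state = cls(arch["height"], arch["width"], arch["embed_dim"],
                        tuple(arch["channels"]))
            for i, p in enumerate(state.params()):
                p.val[...] = f[f"p{i}"]
        return state


def _as_images(x) -> np.ndarray:
    images = x.images if isinstance(x, IonImageStack) else np.asarray(x)
    if images.ndim != 3:
        raise ValueError(f"expected (n, h, w) images, got shape {images.shape}")
    return images.astype(np.float32)


def encode(state: ConvAutoencoder, images, batch: int = 256) -> np.ndarray:
    """Map images to their d-dimensional embeddings, deterministically."""
    x = _as_images(images)
    if x.shape[1:] != (state.height, state.width):
        raise ValueError(
            f"image grid {x.shape[1:]} does not match autoencoder "
            f"({state.height}, {state.width})"
        )
    out = [state.encoder.forward(x[i:i + batch, None], train=False)
           for i in range(0, len(x), batch)]
    return np.concatenate(out, axis=0)


def decode(state: ConvAutoencoder, Z: np.ndarray, batch: int = 256) -> np.ndarray:
    """Reconstruct images from embeddings; outputs lie in (0, 1)."""
    Z = np.asarray(Z, dtype=np.float32)
    if Z.ndim != 2 or Z.shape[1] != state.embed_dim:
        raise ValueError(f"expected (n, {state.embed_dim}) embeddings, got {Z.shape}")
    out = [state.decoder.forward(Z[i:i + batch], train=False)[:, 0]
           for i in range(0, len(Z), batch)]
    return np.concatenate(out, axis=0)


def denoise(state: ConvAutoencoder, images, batch: int = 256) -> np.ndarray:
    """x̃ = D(E(x)) for a batch of images."""
    return decode(state, encode(state, images, batch=batch), batch=batch)


def reconstruction_loss(state: ConvAutoencoder, images, batch: int = 256) -> float:
    """Summed squared reconstruction error Σ_i ‖x_i − x̃_i‖²."""
    x = _as_images(images)
    xt = denoise(state, x, batch=batch)
    return float(((x - xt) ** 2).sum(dtype=np.float64))


def pretrain(state: ConvAutoencoder, images, epochs: int = 150,
             lr: float = 2e-3, seed: int = 0,
             batch_size: int = 128) -> ConvAutoencoder:
    """Stage-1 pre-training of the autoencoder with Adam.

    Trains in place on the reconstruction loss and records the per-epoch
    loss curve in ``state.pretrain_history``.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    x = _as_images(images)
    n = len(x)
    rng = np.random.default_rng(seed)
    opt = _nn.Adam(state.params(), lr=lr)
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            xb = x[order[start:start + batch_size], None]
            z = state.encoder.forward(xb, train=True)
            xr = state.decoder.forward(z, train=True)
            diff = xr - xb
            loss = float((diff ** 2).sum(dtype=np.float64))
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite reconstruction loss at epoch {epoch + 1}"
                )
            total += loss
            opt.zero_grad()
            grad = (2.0 * diff).astype(np.float32)
            state.encoder.backward(state.decoder.backward(grad))
            opt.step()
        state.pretrain_history.append(total)
    return state
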