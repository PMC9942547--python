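"""Adaptive self-paced training of the joint denoiser + clustering CNN.

Training has two stages.  Stage 1 pre-trains the denoising autoencoder on
the reconstruction loss alone.  Stage 2 alternates, per epoch, a fixed
number of gradient iterations with a threshold update:

* each iteration recomputes the label features Y on the denoised images,
  pseudo-labels all pairs by thresholding their cosine similarities
  (plus the KNN override), and takes one Adam step on the pairwise
  cross-entropy loss (CNN) and one on the reconstruction loss (AE);
* after the iterations, the similarity matrix is recomputed and the
  percentile cursors move — the lower cursor up by 0.8·ε points, the upper
  down by 0.2·ε — so the selected-pair window widens every epoch; the
  thresholds are re-read from the current similarity distribution and the
  self-paced regularizer is λ = ub − lb.

Training stops when the epoch budget is exhausted or the cursors cross
(lb ≥ ub), whichever comes first.  The total objective is

    L = Σ_ij v_ij · g(A_ij, s_ij) + λ + Σ_i ‖x_i − x̃_i‖²

where v selects labeled pairs and g is binary cross-entropy on the
similarity; λ is a reported constant within an epoch (pair selection, not
gradients, realizes its effect).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from . import _nn
from .data_model import IonImageStack
from .denoiser import ConvAutoencoder, DivergenceError, denoise, pretrain


def _minmax(images: np.ndarray) -> np.ndarray:
    """Per-image min-max rescale; constant images map to zeros."""
    lo = images.min(axis=(1, 2), keepdims=True)
    hi = images.max(axis=(1, 2), keepdims=True)
    rng = np.where(hi > lo, hi - lo, 1.0)
    out = (images - lo) / rng
    out[(hi == lo)[:, 0, 0]] = 0.0
    return out.astype(np.float32)
from .pseudolabel import (
    UNLABELED,
    ClusteringCNN,
    init_thresholds,
    knn_positive_mask,
    knn_override,
    label_features,
    similarity_matrix,
    threshold_labels,
)

__all__ = [
    "SelfPacedSchedule",
    "TrainConfig",
    "TrainReport",
    "pairwise_loss",
    "total_loss",
    "update_schedule",
    "train",
]

_EPS = 1e-7
# harder clamp for gradients: KNN-forced positives may sit at s ≈ 0, where
# -1/s would otherwise dwarf every other pair's gradient
_GRAD_EPS = 1e-2


@dataclasses.dataclass
class SelfPacedSchedule:
    """Percentile cursors, thresholds and the λ bookkeeping."""

    l: float = 45.0
    u: float = 95.0
    lb: float = float("nan")
    ub: float = float("nan")
    lam: float = float("nan")
    eps: float = 5.0
    exhausted: bool = False

    def initialize(self, S: np.ndarray) -> "SelfPacedSchedule":
        self.lb, self.ub = init_thresholds(S, self.l, self.u)
        self.lam = self.ub - self.lb
        return self


def update_schedule(sched: SelfPacedSchedule, S: np.ndarray) -> SelfPacedSchedule:
    """Move the cursors, re-read thresholds from the current S, update λ.

    Returns a new schedule; ``exhausted=True`` signals that the selected
    window has closed (lb ≥ ub) and training should stop.
    """
    new = dataclasses.replace(sched)
    new.l = sched.l + 0.8 * sched.eps
    new.u = sched.u - 0.2 * sched.eps
    if new.l >= new.u or new.l >= 100.0 or new.u <= 0.0:
        new.exhausted = True
        return new
    vals = S[np.triu_indices(len(S), k=1)]
    new.lb = float(np.percentile(vals, new.l))
    new.ub = float(np.percentile(vals, new.u))
    new.lam = new.ub - new.lb
    if new.lb >= new.ub:
        new.exhausted = True
    return new


def pairwise_loss(A: np.ndarray, S: np.ndarray, mode: str = "bce") -> float:
    """Pairwise classification loss L_c over the selected (labeled) pairs.

    Sums the binary cross-entropy of the similarity against the
    pseudo-label over unordered off-diagonal pairs; unlabeled pairs
    contribute nothing.  ``mode="literal"`` evaluates the alternative
    form −A·log s − (1−A)(1−log s) instead.
    """
    iu = np.triu_indices(len(S), k=1)
    a = A[iu]
    sel = a != UNLABELED
    if not sel.any():
        return 0.0
    s = np.clip(S[iu][sel], _EPS, 1.0 - _EPS)
    af = a[sel].astype(np.float64)
    if mode == "bce":
        g = -af * np.log(s) - (1.0 - af) * np.log(1.0 - s)
    elif mode == "literal":
        g = -af * np.log(s) - (1.0 - af) * (1.0 - np.log(s))
    else:
        raise ValueError(f"unknown loss mode {mode!r}")
    return float(g.sum())


def total_loss(L_c: float, lam: float, L_ae: float) -> float:
    """Objective value: pairwise loss + λ + reconstruction loss."""
    return float(L_c) + float(lam) + float(L_ae)


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters of the full pipeline; defaults target the simulated
    benchmark (700 images of 40×40) finishing in about a minute on a CPU."""

    embed_dim: int = 7
    ae_channels: tuple[int, int] = (16, 32)
    cnn_channels: tuple[int, ...] = (8, 8, 16, 16, 32, 32, 32)
    knn_k: int = 10
    use_ae: bool = True
    use_knn: bool = True
    pre_epochs: int = 150
    epochs: int = 10
    iterations: int = 10
    eps: float = 2.5
    lr: float = 1e-2
    lr_warmup_epochs: int = 3
    image_batch: int | None = None
    pretrain_lr: float = 2e-3
    pretrain_batch: int = 128
    loss: str = "bce"


@dataclasses.dataclass
class TrainReport:
    """Per-epoch training log plus the final labels."""

    epochs: list[dict] = dataclasses.field(default_factory=list)
    pretrain_history: list[float] = dataclasses.field(default_factory=list)
    labels: Optional[np.ndarray] = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)


def _pairwise_grad(Y: np.ndarray, A: np.ndarray, mode: str) -> tuple[float, np.ndarray]:
    """Loss over labeled pairs and its gradient w.r.t. the softmax rows Y."""
    Y64 = Y.astype(np.float64)
    norms = np.linalg.norm(Y64, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    U = Y64 / norms[:, None]
    S = np.clip(U @ U.T, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    sel = (A != UNLABELED)
    np.fill_diagonal(sel, False)
    s = np.clip(S, _GRAD_EPS, 1.0 - _GRAD_EPS)
    af = (A == 1).astype(np.float64)
    if mode == "bce":
        g = np.where(sel, -af * np.log(s) - (1 - af) * np.log(1 - s), 0.0)
        dS = np.where(sel, -af / s + (1 - af) / (1 - s), 0.0)
    elif mode == "literal":
        g = np.where(sel, -af * np.log(s) - (1 - af) * (1 - np.log(s)), 0.0)
        dS = np.where(sel, -af / s + (1 - af) / s, 0.0)
    else:
        raise ValueError(f"unknown loss mode {mode!r}")
    # the symmetric matrix counts each unordered pair twice: halve the loss;
    # the gradient dL/dU_i = Σ_j g'(s_ij) U_j already needs both occurrences
    loss = 0.5 * float(g.sum())
    # dL/dU_i = Σ_j dS_ij U_j ; project out the radial component for dY
    dU = dS @ U
    dY = (dU - (dU * U).sum(axis=1, keepdims=True) * U) / norms[:, None]
    return loss, dY.astype(np.float32)


def _ae_step(ae: ConvAutoencoder, opt: _nn.Adam, x: np.ndarray,
             idx: np.ndarray | None = None) -> float:
    """One Adam step on the reconstruction loss; returns the batch L_ae."""
    xb = x[:, None] if idx is None else x[idx, None]
    z = ae.encoder.forward(xb, train=True)
    xr = ae.decoder.forward(z, train=True)
    diff = xr - xb
    loss = float((diff ** 2).sum(dtype=np.float64))
    opt.zero_grad()
    ae.encoder.backward(ae.decoder.backward((2.0 * diff).astype(np.float32)))
    opt.step()
    return loss


def train(stack: IonImageStack, k: int, config: TrainConfig | None = None,
          seed: int = 0, on_epoch=None) -> tuple[Optional[ConvAutoencoder], ClusteringCNN, TrainReport]:
    """Run the full two-stage pipeline on a normalized ion-image stack.

    Returns the trained autoencoder (None when ``use_ae=False``), the
    trained clustering CNN, and a :class:`TrainReport` whose ``labels``
    are the final argmax cluster assignments.  Fully reproducible from
    ``seed`` on CPU.
    """
    config = config or TrainConfig()
    if k < 2 or k > stack.n:
        raise ValueError(f"k={k} out of range [2, {stack.n}]")
    x = stack.images.astype(np.float32)
    n, h, w = x.shape
    root = np.random.SeedSequence(seed)
    ae_seed, cnn_seed, pre_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                                   for s in root.spawn(3))

    report = TrainReport()

    # Stage 1: pre-train the denoiser
    ae: Optional[ConvAutoencoder] = None
    if config.use_ae:
        ae = ConvAutoencoder(h, w, embed_dim=config.embed_dim,
                             channels=config.ae_channels, seed=ae_seed)
        pretrain(ae, x, epochs=config.pre_epochs, lr=config.pretrain_lr,
                 seed=pre_seed, batch_size=config.pretrain_batch)
        report.pretrain_history = list(ae.pretrain_history)

    cnn = ClusteringCNN(k, h, w, channels=config.cnn_channels, seed=cnn_seed)
    cnn_opt = _nn.Adam(cnn.params(), lr=config.lr)
    # the AE keeps fine-tuning at its own (pre-training) rate; the CNN
    # rate is an order of magnitude too hot for a converged denoiser
    ae_opt = (_nn.Adam(ae.params(), lr=config.pretrain_lr)
              if config.use_ae else None)

    ae_rng = np.random.default_rng(pre_seed + 1)
    batch_rng = np.random.default_rng(pre_seed + 2)

    # Stage 2: adaptive self-paced training.  The denoised images are
    # re-normalized per image before they feed the CNN: the autoencoder
    # smooths hotspot pixels away, so min-max on its output removes the
    # per-ion amplitude that survives normalization of the raw images.
    xt = _minmax(denoise(ae, x)) if config.use_ae else x
    # the KNN anchor is computed once, at the image level (not on CNN
    # features); with the denoiser enabled the denoised images define the
    # neighborhoods — raw-image neighbors are meaningless at high noise
    knn_mask = knn_positive_mask(xt, config.knn_k) if config.use_knn else None
    # similarity snapshots use full-batch statistics: with a full-dataset
    # forward the batch-norm statistics are the dataset statistics, which
    # keeps the percentile thresholds well-spread from the first epoch
    Y = label_features(cnn, xt, train=True)
    S = similarity_matrix(Y)
    sched = SelfPacedSchedule(eps=config.eps).initialize(S)

    for epoch in range(config.epochs):
        if sched.exhausted:
            break
        last = {}
        if config.lr_warmup_epochs:
            cnn_opt.lr = config.lr * min(1.0, (epoch + 1) / config.lr_warmup_epochs)
        for it in range(config.iterations):
            if config.image_batch and config.image_batch < n:
                sub = batch_rng.choice(n, size=config.image_batch, replace=False)
            else:
                sub = None
            xin = xt if sub is None else xt[sub]
            Y = label_features(cnn, xin, train=True)
            S_iter = similarity_matrix(Y)
            A = threshold_labels(S_iter, sched.lb, sched.ub)
            if knn_mask is not None:
                km = knn_mask if sub is None else knn_mask[np.ix_(sub, sub)]
                A = knn_override(A, mask=km)
            loss_c, dY = _pairwise_grad(Y, A, config.loss)
            if not np.isfinite(loss_c):
                raise DivergenceError(
                    f"non-finite pairwise loss at epoch {epoch + 1}, "
                    f"iteration {it + 1}"
                )
            cnn_opt.zero_grad()
            cnn.net.backward(dY)
            cnn_opt.step()
            if config.use_ae:
                batch = ae_rng.choice(n, size=min(config.pretrain_batch, n),
                                      replace=False)
                L_ae = _ae_step(ae, ae_opt, x, batch) * (n / len(batch))
            else:
                L_ae = 0.0
            iu = np.triu_indices(len(A), k=1)
            a = A[iu]
            last = {
                "L_c": loss_c,
                "L_ae": L_ae,
                "n_pos": int((a == 1).sum()),
                "n_neg": int((a == 0).sum()),
                "n_unlabeled": int((a == UNLABELED).sum()),
            }
        if config.use_ae:
            xt = _minmax(denoise(ae, x))
        Y = label_features(cnn, xt, train=True)
        S = similarity_matrix(Y)
        row = {
            "epoch": epoch + 1,
            "lam": sched.lam,
            "lb": sched.lb,
            "ub": sched.ub,
            "l": sched.l,
            "u": sched.u,
            **last,
            "total": total_loss(last.get("L_c", 0.0), sched.lam,
                                last.get("L_ae", 0.0)),
        }
        report.epochs.append(row)
        if on_epoch is not None:
            on_epoch(row, np.argmax(Y, axis=1))
        sched = update_schedule(sched, S)

    # final labels from a full-batch forward: clustering is transductive
    # here (the training stack is the stack being labeled), so batch
    # statistics are the dataset statistics used throughout training
    Y = label_features(cnn, xt, train=True)
    report.labels = np.argmax(Y, axis=1)
    return ae, cnn, report
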