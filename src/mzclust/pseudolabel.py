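"""Clustering CNN label features, similarities and pairwise pseudo-labels.

The clustering CNN ``f`` maps a (denoised) ion image to a k-vector of
softmax "label features" ``y``.  Cosine similarity between label features,

    s_ij = y_i · y_j / (‖y_i‖ ‖y_j‖),

lies in [0, 1] because softmax rows are non-negative.  Pairs with
similarity at or above an upper threshold ``ub`` are pseudo-labeled 1
(same cluster), pairs at or below a lower threshold ``lb`` are labeled 0
(different cluster), and pairs in between stay unlabeled and do not enter
the loss.  A K-nearest-neighbor constraint computed once on the *input*
images stabilizes the bootstrap: mutual or one-sided KNN pairs are forced
to label 1 regardless of their current similarity.
"""

from __future__ import annotations

import numpy as np

from . import _nn

__all__ = [
    "UNLABELED",
    "ClusteringCNN",
    "label_features",
    "similarity_matrix",
    "init_thresholds",
    "threshold_labels",
    "knn_positive_mask",
    "knn_override",
]

#: Sentinel for "pair not selected"; never enters the loss (mask v excludes it).
UNLABELED = np.int8(-1)


class ClusteringCNN:
    """Seven 3×3 conv layers (BatchNorm+ReLU each, stride 2 every second
    layer), global average pooling, and one linear layer with softmax."""

    def __init__(self, k: int, height: int, width: int,
                 channels: tuple[int, ...] = (8, 8, 16, 16, 32, 32, 32),
                 seed: int = 0):
        if k < 2:
            raise ValueError("number of clusters k must be >= 2")
        rng = np.random.default_rng(seed)
        layers: list[_nn.Layer] = []
        cin = 1
        # downsample early (strides 2,2,1,2,...): the spatial patterns of ion
        # images live at blob scale, and low-resolution layers are far cheaper
        strides = [2, 2, 1, 2] + [1] * max(0, len(channels) - 4)
        for i, cout in enumerate(channels):
            stride = strides[i]
            layers += [
                _nn.Conv2d(cin, cout, 3, stride=stride, pad=1, rng=rng),
                _nn.BatchNorm2d(cout),
                _nn.ReLU(),
            ]
            cin = cout
        # batch-normalizing the logits keeps the label features diverse at
        # initialization (raw logits barely vary across images, which would
        # collapse all cosine similarities toward 1)
        layers += [
            _nn.GlobalAvgPool2d(),
            _nn.Linear(cin, k, rng=rng),
            _nn.Reshape((k, 1, 1)),
            _nn.BatchNorm2d(k),
            _nn.Flatten(),
            _nn.Softmax(),
        ]
        self.net = _nn.Sequential(*layers)
        self.k = k
        self.height, self.width = height, width
        self.channels = tuple(channels)

    def params(self) -> list[_nn.Param]:
        return self.net.params()


def label_features(cnn: ClusteringCNN, images: np.ndarray,
                   train: bool = False, batch: int = 512) -> np.ndarray:
    """Softmax label features Y, shape (n, k); rows sum to 1."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 3 or x.shape[1:] != (cnn.height, cnn.width):
        raise ValueError(
            f"expected (n, {cnn.height}, {cnn.width}) images, got {x.shape}"
        )
    if train:
        return cnn.net.forward(x[:, None], train=True)
    out = [cnn.net.forward(x[i:i + batch, None], train=False)
           for i in range(0, len(x), batch)]
    return np.concatenate(out, axis=0)


def similarity_matrix(Y: np.ndarray) -> np.ndarray:
    """Cosine similarity matrix S of the label-feature rows.

    Symmetric, entries in [0, 1] for non-negative rows, unit diagonal.
    """
    Y = np.asarray(Y, dtype=np.float64)
    norms = np.linalg.norm(Y, axis=1)
    if (norms == 0).any():
        raise ValueError("all-zero label-feature row: cosine undefined")
    U = Y / norms[:, None]
    S = np.clip(U @ U.T, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2.0


def _offdiag_values(S: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(len(S), k=1)
    return S[iu]


def init_thresholds(S: np.ndarray, lower_pct: float = 45.0,
                    upper_pct: float = 95.0) -> tuple[float, float]:
    """(lb, ub) = given percentiles of the off-diagonal similarity values."""
    if len(S) < 2:
        raise ValueError("need at least 2 images to take pair percentiles")
    vals = _offdiag_values(S)
    lb = float(np.percentile(vals, lower_pct))
    ub = float(np.percentile(vals, upper_pct))
    if lb >= ub:
        raise ValueError(
            f"degenerate similarity distribution: lb={lb} >= ub={ub}"
        )
    return lb, ub


def threshold_labels(S: np.ndarray, lb: float, ub: float) -> np.ndarray:
    """Ternary pseudo-label matrix A′ from the similarity thresholds.

    ``s >= ub`` → 1 (same cluster), ``s <= lb`` → 0 (different cluster),
    otherwise :data:`UNLABELED`.  Symmetric with unit diagonal.
    """
    if lb >= ub:
        raise ValueError(f"lb={lb} must be < ub={ub}")
    A = np.full(S.shape, UNLABELED, dtype=np.int8)
    A[S >= ub] = 1
    A[S <= lb] = 0
    np.fill_diagonal(A, 1)
    return A


def knn_positive_mask(images: np.ndarray, K: int) -> np.ndarray:
    """Boolean (n, n) mask of pairs forced positive by the KNN rule.

    Neighbors by cosine similarity of flattened images; self excluded;
    ``mask[i, j]`` is True when j ∈ KNN(i) or i ∈ KNN(j).
    """
    x = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
    n = len(x)
    if not (1 <= K < n):
        raise ValueError(f"K={K} out of range [1, {n})")
    norms = np.linalg.norm(x, axis=1)
    norms[norms == 0] = 1.0
    U = x / norms[:, None]
    S = U @ U.T
    np.fill_diagonal(S, -np.inf)
    nbrs = np.argpartition(-S, K - 1, axis=1)[:, :K]
    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), K)
    mask[rows, nbrs.ravel()] = True
    return mask | mask.T


def knn_override(Aprime: np.ndarray, reference_images: np.ndarray | None = None,
                 K: int = 5, mask: np.ndarray | None = None) -> np.ndarray:
    """Force KNN pairs to pseudo-label 1; all other entries keep A′.

    The mask may be precomputed with :func:`knn_positive_mask` (the
    neighbor structure of the input images does not change over training).
    """
    if mask is None:
        if reference_images is None:
            raise ValueError("need reference_images or a precomputed mask")
        mask = knn_positive_mask(reference_images, K)
    A = Aprime.copy()
    A[mask] = 1
    return A
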