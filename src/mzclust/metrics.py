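"""Evaluation machinery: partition metrics, isotope metrics and baselines.

Partition quality against a known ground truth is scored with clustering
accuracy (ACC, optimal one-to-one label matching via the Hungarian
algorithm on the contingency table), normalized mutual information (NMI,
normalized by the arithmetic mean of the entropies) and the adjusted Rand
index (ARI).

On experimental data no ground truth exists, but high-resolution m/z axes
reveal isotope pairs: two features whose mass difference is ≈1.003 Da and
whose ion images are strongly Pearson-correlated almost surely come from
the same molecule and therefore belong in the same cluster.  The isotope
ratio (IR) is the fraction of such pairs a clustering keeps together; the
relative isotope ratio (RIR) divides IR by its expectation under a random
partition with the same cluster sizes, so RIR ≈ 1 means chance level.

The vectorization baselines (K-means, Gaussian mixture) flatten each ion
image to a pixel vector, discarding spatial context — the point of
comparison for the spatially aware deep method.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.mixture import GaussianMixture

from .data_model import IonImageStack

__all__ = [
    "clustering_accuracy",
    "nmi",
    "ari",
    "IsotopePairSet",
    "UndefinedMetricError",
    "detect_isotope_pairs",
    "isotope_ratio",
    "relative_isotope_ratio",
    "kmeans_baseline",
    "gmm_baseline",
]

ISOTOPE_SPACING = 1.003  # Da, the +1 isotope mass shift


class UndefinedMetricError(ValueError):
    """A metric has no defined value on the given input (e.g. no pairs)."""


def _check_partitions(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError(f"label vectors differ: {truth.shape} vs {pred.shape}")
    return truth, pred


def clustering_accuracy(truth, pred) -> float:
    """ACC: best fraction correct over one-to-one cluster-label matchings."""
    truth, pred = _check_partitions(truth, pred)
    t_ids, t_inv = np.unique(truth, return_inverse=True)
    p_ids, p_inv = np.unique(pred, return_inverse=True)
    k = max(len(t_ids), len(p_ids))
    cont = np.zeros((k, k), dtype=np.int64)
    np.add.at(cont, (t_inv, p_inv), 1)
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / len(truth))


def nmi(truth, pred) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    truth, pred = _check_partitions(truth, pred)
    return float(normalized_mutual_info_score(truth, pred,
                                              average_method="arithmetic"))


def ari(truth, pred) -> float:
    """Adjusted Rand index; 1 for identical partitions, ≈0 at chance."""
    truth, pred = _check_partitions(truth, pred)
    return float(adjusted_rand_score(truth, pred))


@dataclasses.dataclass
class IsotopePairSet:
    """Candidate isotope pairs (i, j, Δm, p) with i < j, plus the rule used."""

    pairs: list[tuple[int, int, float, float]]
    delta: float = 0.01
    p_min: float = 0.7
    iso_spacing: float = ISOTOPE_SPACING

    def __len__(self) -> int:
        return len(self.pairs)

    def index_pairs(self) -> np.ndarray:
        if not self.pairs:
            return np.empty((0, 2), dtype=np.intp)
        return np.asarray([(i, j) for i, j, _, _ in self.pairs], dtype=np.intp)


def detect_isotope_pairs(stack: IonImageStack, delta: float = 0.01,
                         p_min: float = 0.7) -> IsotopePairSet:
    """Find m/z pairs with |Δm − 1.003| < delta and image correlation > p_min.

    Correlations are computed over on-tissue pixels when the stack has a
    mask.  Constant images have undefined correlation and never pair.
    """
    mz = stack.mz
    if stack.pixel_mask is not None:
        flat = stack.images[:, stack.pixel_mask].astype(np.float64)
    else:
        flat = stack.flattened().astype(np.float64)
    centered = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    pairs = []
    lo = mz + ISOTOPE_SPACING - delta
    hi = mz + ISOTOPE_SPACING + delta
    starts = np.searchsorted(mz, lo, side="right")
    stops = np.searchsorted(mz, hi, side="left")
    for i in range(stack.n):
        for j in range(max(starts[i], i + 1), stops[i]):
            dm = mz[j] - mz[i]
            if not abs(dm - ISOTOPE_SPACING) < delta:
                continue
            if norms[i] == 0 or norms[j] == 0:
                continue
            p = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
            if p > p_min:
                pairs.append((int(i), int(j), float(dm), p))
    return IsotopePairSet(pairs=pairs, delta=delta, p_min=p_min)


def isotope_ratio(pairs: IsotopePairSet, labels) -> float:
    """IR: fraction of isotope pairs placed in the same cluster."""
    labels = np.asarray(labels)
    if len(pairs) == 0:
        raise UndefinedMetricError("no isotope pairs: isotope ratio undefined")
    idx = pairs.index_pairs()
    return float(np.mean(labels[idx[:, 0]] == labels[idx[:, 1]]))


def relative_isotope_ratio(pairs: IsotopePairSet, labels,
                           mode: str = "analytic", n_perm: int = 1000,
                           seed: int | None = None) -> float:
    """RIR: IR divided by the IR of a size-matched random clustering.

    ``analytic`` uses the exact co-clustering probability of a uniformly
    random partition with the observed cluster sizes,
    ``Σ_c n_c(n_c−1) / (n(n−1))``; ``permutation`` estimates it as the mean
    IR over ``n_perm`` seeded label shuffles.
    """
    labels = np.asarray(labels)
    ir = isotope_ratio(pairs, labels)
    n = len(labels)
    if mode == "analytic":
        _, sizes = np.unique(labels, return_counts=True)
        ir_random = float((sizes * (sizes - 1)).sum() / (n * (n - 1)))
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        idx = pairs.index_pairs()
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            hits += int((perm[idx[:, 0]] == perm[idx[:, 1]]).sum())
        ir_random = hits / (n_perm * len(pairs))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if ir_random == 0:
        raise UndefinedMetricError(
            "random-clustering isotope ratio is 0 (all singleton clusters)"
        )
    return float(ir / ir_random)


def kmeans_baseline(stack: IonImageStack, k: int, restarts: int = 10,
                    seed: int | None = None) -> np.ndarray:
    """K-means on flattened ion images (the vectorization baseline)."""
    if k > stack.n:
        raise ValueError(f"k={k} exceeds number of images n={stack.n}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(stack.flattened())


def gmm_baseline(stack: IonImageStack, k: int, seed: int | None = None,
                 reg_covar: float = 1e-4, max_iter: int = 200,
                 pca_dim: int | str | None = "auto") -> np.ndarray:
    """Regularized full-covariance Gaussian mixture on flattened images.

    A full covariance over raw pixel vectors is unidentifiable when the
    dimension approaches the per-component sample count, so the vectors
    are first reduced by PCA.  The default ``pca_dim="auto"`` keeps the
    largest d whose per-component Gaussian (d mean + d(d+1)/2 covariance
    parameters) stays identifiable from the expected n/k samples per
    component.  Pass an int to fix the dimension or ``None`` to fit on
    the raw flattened vectors.
    """
    if k > stack.n:
        raise ValueError(f"k={k} exceeds number of images n={stack.n}")
    X = stack.flattened()
    if pca_dim == "auto":
        per_comp = max(2, stack.n // k)
        d = int((np.sqrt(9 + 8 * per_comp) - 3) / 2)  # d(d+3)/2 <= n/k
        pca_dim = max(1, d)
    if pca_dim is not None:
        from sklearn.decomposition import PCA

        d = min(pca_dim, X.shape[0], X.shape[1])
        X = PCA(n_components=d, random_state=seed).fit_transform(X)
    gmm = GaussianMixture(n_components=k, covariance_type="full",
                          reg_covar=reg_covar, max_iter=max_iter,
                          random_state=seed)
    return gmm.fit_predict(X)
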