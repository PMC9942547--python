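"""Synthetic ion-image benchmark with known ground-truth clusters.

The default configuration emulates a 7-cluster benchmark: 100 ion images
per cluster on a 40×40 grid.  Clusters 1–3 (0-based 0–2) carry two to
three geometric segments (disks, intensity bands), cluster 4 (index 3) is
spatially homogeneous, and clusters 5–7 (indices 4–6) are the pixel-wise
intensity complements of clusters 1–3 — mimicking the common MSI situation
where one ion's image is the opposite of another's.

Each simulated image is ``clip(a · template + ε, 0, 1) ∨ hotspots`` with

* a per-image amplitude ``a = amplitude_scale · U(1−j, 1+j)`` — ion
  abundances vary over a wide dynamic range;
* i.i.d. Gaussian pixel noise ``ε ~ N(0, noise_sd)``;
* a small fraction of hotspot pixels set to near-saturated intensities,
  mimicking the matrix/detector hotspots notorious in MSI data.

The hotspots pin every image's maximum near 1, so per-image min-max
normalization cannot undo the amplitude variation; Euclidean vectorization
baselines consequently struggle while scale-invariant (cosine) similarity
is unaffected — the separability regime in which spatial feature learning
pays off.  The default noise parameters are calibrated so that a
vectorized K-means baseline scores near 0.65 accuracy.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .data_model import IonImageStack

__all__ = ["SimulationConfig", "LabeledStack", "make_templates", "simulate_dataset"]

#: Default noise parameters on the [0,1] intensity scale, calibrated
#: against the K-means baseline (see module docstring).
DEFAULT_NOISE_SD = 0.25
DEFAULT_AMPLITUDE_JITTER = 0.7


@dataclasses.dataclass
class SimulationConfig:
    n_clusters: int = 7
    images_per_cluster: int = 100
    height: int = 40
    width: int = 40
    noise_sd: float = DEFAULT_NOISE_SD
    amplitude_jitter: float = DEFAULT_AMPLITUDE_JITTER
    amplitude_scale: float = 0.6
    hotspot_fraction: float = 0.01
    inversion_pairs: Optional[Sequence[tuple[int, int]]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.images_per_cluster < 2:
            raise ValueError("images_per_cluster must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.amplitude_jitter < 1):
            raise ValueError("amplitude_jitter must be in [0, 1)")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if not (0 <= self.hotspot_fraction < 1):
            raise ValueError("hotspot_fraction must be in [0, 1)")
        if self.inversion_pairs is None and self.n_clusters == 7:
            # default geometry: clusters 4-6 invert clusters 0-2
            self.inversion_pairs = [(0, 4), (1, 5), (2, 6)]
        pairs = list(self.inversion_pairs or [])
        seen = set()
        for src, dst in pairs:
            for c in (src, dst):
                if not (0 <= c < self.n_clusters):
                    raise ValueError(f"inversion pair index {c} out of range")
            if src == dst or dst in seen or src in {d for _, d in pairs}:
                raise ValueError("inversion_pairs must map distinct clusters")
            seen.add(dst)
        self.inversion_pairs = pairs


@dataclasses.dataclass
class LabeledStack:
    """An ion-image stack together with its ground-truth cluster labels."""

    stack: IonImageStack
    truth: np.ndarray

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=np.int64)
        if len(self.truth) != self.stack.n:
            raise ValueError("truth length must match number of images")
        if self.truth.min() < 0:
            raise ValueError("labels must be non-negative")


def _disk(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy * h) ** 2 + (xx - cx * w) ** 2 <= (r * min(h, w)) ** 2


def _base_templates(h: int, w: int) -> list[np.ndarray]:
    """Catalogue of segment patterns, each a [0,1] image with 1-3 segments."""
    yy, xx = np.mgrid[0:h, 0:w]
    out = []
    # big central disk, low inside (2 segments)
    t = np.full((h, w), 0.8)
    t[_disk(h, w, 0.5, 0.5, 0.38)] = 0.2
    out.append(t)
    # small disk in the upper-right corner, low inside (2 segments)
    t = np.full((h, w), 0.75)
    t[_disk(h, w, 0.28, 0.72, 0.17)] = 0.15
    out.append(t)
    # three vertical bands (3 segments)
    t = np.full((h, w), 0.55)
    t[:, : w // 3] = 0.15
    t[:, 2 * w // 3 :] = 0.95
    out.append(t)
    # homogeneous mid-intensity (1 segment)
    out.append(np.full((h, w), 0.5))
    # diagonal half-plane split (2 segments)
    t = np.where(yy + xx < (h + w) // 2, 0.25, 0.75)
    out.append(t.astype(float))
    # horizontal thirds (3 segments)
    t = np.full((h, w), 0.5)
    t[: h // 3] = 0.9
    t[2 * h // 3 :] = 0.1
    out.append(t)
    return [o.astype(np.float64) for o in out]


def make_templates(config: SimulationConfig) -> np.ndarray:
    """Build the k cluster templates, shape (k, h, w), values in [0, 1]."""
    h, w = config.height, config.width
    catalogue = _base_templates(h, w)
    inverted = {dst: src for src, dst in config.inversion_pairs}
    templates: list[Optional[np.ndarray]] = [None] * config.n_clusters
    next_base = 0
    for c in range(config.n_clusters):
        if c in inverted:
            continue
        if next_base >= len(catalogue):
            raise ValueError(
                f"template catalogue exhausted: {config.n_clusters} clusters "
                f"need more than {len(catalogue)} base patterns; add "
                "inversion_pairs or reduce n_clusters"
            )
        templates[c] = catalogue[next_base]
        next_base += 1
    for src, dst in config.inversion_pairs:
        if templates[src] is None:
            raise ValueError(f"inversion source {src} is itself inverted")
        templates[dst] = 1.0 - templates[src]
    return np.stack(templates)


def simulate_dataset(config: SimulationConfig) -> LabeledStack:
    """Draw the full benchmark: k × images_per_cluster noisy ion images.

    Fully reproducible from ``config.seed``; m/z values are monotone
    placeholders (isotope metrics are not meaningful on simulated data).
    """
    rng = np.random.default_rng(config.seed)
    templates = make_templates(config)
    k, m = config.n_clusters, config.images_per_cluster
    n = k * m
    h, w = config.height, config.width
    truth = np.repeat(np.arange(k), m)
    amp = config.amplitude_scale * rng.uniform(
        1.0 - config.amplitude_jitter, 1.0 + config.amplitude_jitter, size=n)
    noise = rng.normal(0.0, config.noise_sd, size=(n, h, w)) \
        if config.noise_sd > 0 else np.zeros((n, h, w))
    images = amp[:, None, None] * templates[truth] + noise
    n_spikes = int(round(config.hotspot_fraction * h * w))
    if n_spikes:
        flat = images.reshape(n, -1)
        for i in range(n):
            idx = rng.choice(h * w, size=n_spikes, replace=False)
            flat[i, idx] = rng.uniform(0.8, 1.0, size=n_spikes)
    images = np.clip(images, 0.0, 1.0)
    mz = 100.0 + 0.5 * np.arange(n)
    stack = IonImageStack(
        mz=mz,
        images=images.astype(np.float32),
        meta={"source": "simulate", "seed": config.seed, "normalized": False},
    )
    return LabeledStack(stack=stack, truth=truth)
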