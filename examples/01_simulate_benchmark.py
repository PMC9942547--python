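"""Generate the synthetic ion-image benchmark and look at its structure.

Builds the default 7-cluster dataset (100 ion images per cluster, 40x40
pixels, amplitude variation + pixel noise + hotspot artifacts), and prints
how well a vectorized K-means baseline can recover the ground truth.
"""

import numpy as np

from mzclust import SimulationConfig, normalize_stack, simulate_dataset
from mzclust.metrics import clustering_accuracy, kmeans_baseline

config = SimulationConfig(seed=7)
labeled = simulate_dataset(config)
stack = labeled.stack
print(f"simulated {stack.n} ion images of {stack.shape[1]}x{stack.shape[2]} "
      f"pixels in {config.n_clusters} clusters")
print(f"m/z range: {stack.mz[0]:.1f} .. {stack.mz[-1]:.1f}")

normalized = normalize_stack(stack)
labels = kmeans_baseline(normalized, k=7, restarts=10, seed=0)
acc = clustering_accuracy(labeled.truth, labels)
print(f"K-means on flattened pixel vectors: ACC = {acc:.3f}")
print("ACC is the fraction of images matched to their true cluster under "
      "the best one-to-one label matching; the benchmark is calibrated so "
      "this vectorization baseline lands near 0.65 — spatial structure "
      "that pixel vectors cannot exploit is what the deep method uses.")
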