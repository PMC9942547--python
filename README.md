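# mzclust

Noise-robust deep clustering of mass-spectrometry-imaging (MSI) ion
images.

An MSI experiment records a mass spectrum at every pixel of a tissue
raster; read the other way around, every m/z feature yields an *ion
image* — the spatial map of that ion's intensity. Ions from the same
source (isotopes, adducts, fragments, molecules confined to the same
anatomical compartment) produce similar ion images, so clustering the
images in the spectral domain groups m/z features into interpretable
sets, which also serve as focused inputs for downstream spatial
segmentation. Plain vectorization methods (K-means or Gaussian mixtures
on flattened pixel vectors) ignore spatial context and buckle under MSI's
heavy noise; `mzclust` instead trains, directly on the ion images:

1. a **convolutional denoising autoencoder** — two strided convolutions
   down to a 7-dimensional embedding z and two transposed convolutions
   back, trained on the reconstruction error Σᵢ‖xᵢ − x̃ᵢ‖², so that
   x̃ = D(E(x)) keeps the spatial pattern and sheds the noise; and
2. a **clustering CNN** — seven convolutional layers with batch norm and
   ReLU plus a softmax head producing label features yᵢ ∈ Δᵏ⁻¹ — trained
   with **pairwise pseudo-labels**: pairs with cosine similarity
   s_ij = yᵢ·yⱼ/(‖yᵢ‖‖yⱼ‖) at or above an upper threshold count as
   "same cluster", pairs at or below a lower threshold as "different
   cluster", the rest stay out of the binary cross-entropy loss. A
   K-nearest-neighbor rule at the image level forces neighbors to share
   a cluster, stabilizing the random start.

The thresholds are the 45th/95th percentiles of the pairwise
similarities, **adaptively self-paced**: every epoch the window narrows
(l ← l + 0.8ε, u ← u − 0.2ε), more pairs become confidently labeled, and
the regularizer λ = ub − lb tracks the shrinking gap. Final clusters are
cᵢ = argmaxₚ yᵢₚ. The package also ships the simulated benchmark with
known ground truth, the evaluation suite (ACC / NMI / ARI, isotope ratio
and relative isotope ratio), the vectorization baselines, and I/O for
HDF5 stacks and processed imzML. The networks run on a small built-in
CPU numpy engine — no GPU or deep-learning framework required.

## Worked example

```python
from mzclust import SimulationConfig, simulate_dataset, normalize_stack
from mzclust.trainer import train
from mzclust.metrics import clustering_accuracy, nmi, ari, kmeans_baseline

labeled = simulate_dataset(SimulationConfig(seed=0))   # 7 x 100 images, 40x40
stack = normalize_stack(labeled.stack)

km = kmeans_baseline(stack, k=7, restarts=10, seed=0)
print(f"K-means ACC: {clustering_accuracy(labeled.truth, km):.3f}")

ae, cnn, report = train(stack, k=7, seed=0)            # ~2 min on one CPU
print(f"deep ACC:  {clustering_accuracy(labeled.truth, report.labels):.3f}")
print(f"deep NMI:  {nmi(labeled.truth, report.labels):.3f}")
print(f"deep ARI:  {ari(labeled.truth, report.labels):.3f}")
```

prints

```
K-means ACC: 0.657
deep ACC:  0.993
deep NMI:  0.985
deep ARI:  0.984
```

The benchmark's noise (wide amplitude range, pixel noise, hotspot
artifacts) is calibrated so the vectorization baseline lands near 0.65
accuracy; the deep pipeline recovers nearly the whole partition because
denoising plus learned spatial features make same-cluster images look
alike to the cosine similarity. `report.epochs` logs λ, the thresholds
and the labeled-pair counts per epoch; `examples/` walks through each
capability (simulation, denoising, clustering, isotope metrics) as short
narrative scripts, and the `mzclust` command line exposes the same steps
(`mzclust simulate / pretrain / train / evaluate / export`).

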