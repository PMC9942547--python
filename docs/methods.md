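# Methods

`mzclust` clusters the ion images of a mass-spectrometry-imaging (MSI)
experiment in the spectral domain: each of the n m/z features contributes
one h×w intensity image, and the goal is to group features whose spatial
distributions look alike — isotopes, adducts, fragments of one molecule,
or ions confined to the same tissue compartment. This note documents the
model, the synthetic benchmark, the numerical choices, and the limits of
what the tests demonstrate.

## Model

**Denoising (component i).** Every image is min-max normalized to [0, 1]
and passed through a convolutional autoencoder: an encoder E with two
stride-2 3×3 convolutions (16 and 32 channels) followed by a linear map to
a d = 7 dimensional embedding z, and a decoder D mirroring it with two
transposed convolutions and a sigmoid output, so x̃ = D(E(x)) ∈ (0, 1).
The autoencoder is trained on the summed squared reconstruction error

    L_ae = Σ_i ‖x_i − x̃_i‖².

Because the bottleneck can only represent a handful of spatial modes, the
reconstruction keeps the cluster-defining pattern and discards pixel
noise. The denoised images — not the raw ones — feed the clustering
network. They are re-normalized per image first: the autoencoder smooths
isolated hotspot pixels away, so min-max on its output also removes the
per-ion amplitude that survives normalization of the raw images (hotspots
pin the raw maximum).

**Pseudo-labeling (component ii).** A clustering CNN f with seven 3×3
convolutions (channels 8-8-16-16-32-32-32, BatchNorm + ReLU, stride 2 in
layers 1, 2 and 4), global average pooling and a linear + softmax head
maps each denoised image to label features y ∈ Δ^{k−1}. Cosine similarity
s_ij = y_i·y_j / (‖y_i‖‖y_j‖) lies in [0, 1]. A pair is pseudo-labeled

* same cluster (A_ij = 1) when s_ij ≥ ub,
* different cluster (A_ij = 0) when s_ij ≤ lb,
* unlabeled otherwise (it then contributes nothing to the loss).

The thresholds are percentiles of the off-diagonal similarity values,
initialized at the 45th (lb) and 95th (ub). In addition, a K-nearest-
neighbor constraint forces A_ij = 1 whenever either image is among the
other's K = 10 nearest neighbors (cosine on flattened images). The
neighbor structure is computed once, at the image level — on the denoised
images when the autoencoder is enabled, on the raw images otherwise — so
it is independent of the clustering network and anchors the bootstrap
when f is still random.

**Self-paced training.** Stage 1 pre-trains the autoencoder (150 epochs,
Adam, learning rate 2·10⁻³, batch 128). Stage 2 repeats, per epoch: ten
full-batch iterations, each recomputing Y, pseudo-labeling all pairs at
the current thresholds, and taking one Adam step on the pairwise
cross-entropy

    L_c = Σ_{ij} v_ij [ −A_ij log s_ij − (1 − A_ij) log(1 − s_ij) ],

with v_ij = 1 exactly for labeled pairs, plus one reconstruction-loss
step for the autoencoder; afterwards the percentile cursors move (l up by
0.8ε, u down by 0.2ε, ε = 2.5), the thresholds are re-read from the
current similarity distribution, and the self-paced regularizer is
updated as λ = ub − lb. The reported objective is L_c + λ + L_ae. λ acts
through pair selection, not through gradients. Training stops after 10
epochs or as soon as lb ≥ ub. Final labels are c_i = argmax_p y_ip, ties
to the lowest index.

The widening window grows the labeled-pair fraction toward
l + (100 − u) percent (plus KNN overrides); once the similarity
distribution polarizes, its point masses straddle the thresholds and the
realized counts can wobble around that trend. λ itself is *not* monotone on real runs: as training
polarizes the similarity distribution toward {0, 1}, re-reading the
percentiles can widen the gap even while the cursors close. The test
suite asserts λ = ub − lb everywhere and monotonicity on a fixed
distribution, and carries a deliberately failing check of run-level
monotonicity to document this behavior.

### Numerical and design choices

* **Gradient flow.** The pairwise loss trains the CNN only; the
  autoencoder continues on its reconstruction loss (stop-gradient at x̃).
  Joint end-to-end coupling adds cost and instability without measurable
  benefit on the benchmark.
* **Logit normalization.** A BatchNorm on the k logits precedes the
  softmax. Without it a freshly initialized network maps all images to
  nearly the same softmax point, every cosine is ≈ 1, and the percentile
  thresholds are degenerate.
* **Full-batch statistics.** Similarity snapshots and final labels use
  full-dataset forward passes with batch statistics; clustering is
  transductive here (the training stack is the stack being labeled), so
  batch statistics are the dataset statistics.
* **Warmup.** The CNN learning rate (Adam, 10⁻²) ramps linearly over the
  first 3 epochs. The earliest threshold positives are the least
  reliable labels of the whole run; learning slowly until the KNN anchor
  has shaped the features prevents irreversible early merges.
* **Clamping.** Similarities are clamped to [10⁻², 1 − 10⁻²] inside the
  gradient (KNN-forced positives can sit at s ≈ 0, where −1/s would
  dwarf every other pair) and to [10⁻⁷, 1 − 10⁻⁷] in reported losses.
* **Stopping before exhaustion.** With ε = 2.5 the window closes after
  20 epochs; the default stops at 10. In the terminal epochs the lower
  percentile climbs into the same-cluster similarity mass and forces
  true pairs to "different cluster" — running to exhaustion can shatter
  a converged partition in a single epoch.
* **Ties in argmax** break to the lowest cluster index; empty clusters
  are legal and reported.
* **Loss variant.** `loss="literal"` evaluates an alternative final term
  −(1 − A)(1 − log s) in place of the standard cross-entropy term; it
  rewards high similarity for negative pairs and exists only for
  comparison.

## Synthetic benchmark

`simulate` draws k = 7 clusters × 100 ion images on a 40×40 grid.
Templates: a big central disk, a small corner disk, and three vertical
bands (two to three segments each); a spatially homogeneous template; and
the pixel-wise complements of the first three — mimicking ions whose
images are opposites. Each image is

    clip(a · template + ε, 0, 1), then ~1% of pixels ← U(0.8, 1.0),

with amplitude a = 0.6 · U(0.3, 1.7) (ion abundances span a wide dynamic
range), pixel noise ε ~ N(0, 0.25²), and the overwritten pixels emulating
the hotspot artifacts common in MSI. Hotspots pin every image's maximum
near 1, so per-image normalization cannot undo the amplitude variation;
Euclidean vectorization baselines are crippled while cosine similarity is
unaffected. The noise defaults were calibrated — as the benchmark's
declared fidelity check — so that vectorized K-means lands near 0.65
accuracy (measured 0.635, 5 seeds); all other scores follow from that
single calibration. In this regime the full pipeline reaches ACC
≈ 0.92–0.99 depending on the draw, and a covariance-bearing Gaussian
mixture outperforms K-means (≈ 0.8–0.87),
reproducing the qualitative ordering K-means < GMM < deep method.

What the generator does *not* emulate: mass-spectral peak shapes, isotope
envelopes (the synthetic m/z axis is a monotone placeholder, so isotope
metrics are meaningless on simulated data), spatially correlated noise,
irregular tissue outlines, and cluster-size imbalance. Passing tests
demonstrate correct mechanics and the claimed separability ordering under
this stand-in noise model — not performance on any particular real tissue.

## Evaluation

* **ACC** — best fraction correct over one-to-one cluster matchings,
  solved by the Hungarian algorithm on the k×k contingency table (equal
  to the brute-force permutation maximum; tested for k ≤ 6).
* **NMI** — mutual information normalized by the arithmetic mean of the
  entropies; **ARI** — Rand index adjusted for chance.
* **Isotope pairs** — m/z pairs with |Δm − 1.003| < 0.01 Da and Pearson
  correlation > 0.7 between their images (over on-tissue pixels when a
  mask exists; constant images never pair). Only the +1 spacing is
  searched. **IR** is the fraction of pairs co-clustered; **RIR** divides
  IR by the co-clustering probability of a size-matched uniformly random
  partition, Σ_c n_c(n_c−1)/(n(n−1)) (a permutation estimator is kept as
  a cross-check; both agree within 2%).
* **Baselines** — K-means (10 restarts) on flattened pixel vectors, and a
  regularized full-covariance Gaussian mixture on a PCA reduction whose
  dimension is the largest d with d(d+3)/2 ≤ n/k (covariance
  identifiability; d = 12 on the default benchmark; `pca_dim=None` fits
  the raw vectors).

## Known limitations

* Exact recovery in the near-noiseless limit is not guaranteed: the
  lowest-abundance images (normalization amplifies their relative noise
  several-fold) are occasionally absorbed into the homogeneous cluster —
  typically ≤ 2% of images on an unlucky draw. Very low amplitude
  variation is *also* adverse: with nearly identical within-cluster
  images the similarity distribution collapses onto a few tied values and
  the percentile thresholds act on whole blocks, which can merge two
  clusters irreversibly. Random-initialization local minima of this kind
  are inherent to pseudo-label bootstraps; the KNN constraint reduces
  but does not eliminate them.
* Early merges are permanent by construction: inside a merged cluster
  all similarities are ≈ 1, and the threshold rule can never label such
  pairs "different cluster".
* The number of clusters k must be specified in advance.
* Problem sizes: defaults are sized for the 700-image benchmark on one
  CPU (~2 minutes per run). For much larger n the full-batch similarity
  matrix (n²) becomes the memory bottleneck.
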