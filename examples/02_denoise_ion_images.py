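"""Pre-train the convolutional autoencoder and measure its denoising.

The autoencoder compresses each ion image to a 7-dimensional embedding and
reconstructs it; pixel noise, being incompressible, is stripped away.  The
script reports the reconstruction loss curve and how much the denoising
tightens same-cluster distances.
"""

import numpy as np

from mzclust import SimulationConfig, normalize_stack, simulate_dataset
from mzclust.denoiser import ConvAutoencoder, denoise, pretrain

labeled = simulate_dataset(SimulationConfig(images_per_cluster=40, seed=7))
stack = normalize_stack(labeled.stack)

ae = ConvAutoencoder(40, 40, embed_dim=7, seed=0)
pretrain(ae, stack.images, epochs=60, lr=2e-3, seed=0)
history = ae.pretrain_history
print(f"reconstruction loss: {history[0]:.0f} (epoch 1) -> "
      f"{history[-1]:.0f} (epoch {len(history)})")

denoised = denoise(ae, stack.images)


def mean_within_cluster_distance(images):
    flat = images.reshape(len(images), -1)
    total, count = 0.0, 0
    for c in np.unique(labeled.truth):
        members = flat[labeled.truth == c]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                total += np.linalg.norm(members[i] - members[j])
                count += 1
    return total / count


raw_d = mean_within_cluster_distance(stack.images)
den_d = mean_within_cluster_distance(denoised)
print(f"mean within-cluster distance: raw {raw_d:.2f} -> denoised {den_d:.2f}")
print("the contraction means images of the same underlying ion pattern "
      "look alike after denoising, which is what the pairwise pseudo-labels "
      "downstream rely on")
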