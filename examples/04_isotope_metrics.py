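"""Isotope-pair detection and the (relative) isotope ratio.

On experimental data there is no ground truth, but +1 isotopes (mass
difference ~1.003 Da, strongly correlated images) must come from the same
molecule.  This script builds a tiny stack with planted isotope pairs and
shows how the isotope ratio (IR) and relative isotope ratio (RIR) score a
clustering.
"""

import numpy as np

from mzclust.data_model import IonImageStack
from mzclust.metrics import (
    detect_isotope_pairs,
    isotope_ratio,
    relative_isotope_ratio,
)

rng = np.random.default_rng(0)

# 10 ions: five molecules, each with a monoisotopic peak and a +1 isotope
base_mz = np.array([400.20, 452.31, 500.05, 551.44, 600.10])
mz = np.sort(np.concatenate([base_mz, base_mz + 1.0032]))
patterns = rng.random((5, 12, 12))
images = np.empty((10, 12, 12), dtype=np.float32)
for m, pattern in zip(base_mz, patterns):
    i = np.searchsorted(mz, m)
    j = np.searchsorted(mz, m + 1.0032)
    images[i] = pattern
    images[j] = 0.5 * pattern + 0.01 * rng.random((12, 12))  # same shape

stack = IonImageStack(mz=mz, images=images)
pairs = detect_isotope_pairs(stack, delta=0.01, p_min=0.7)
print(f"detected {len(pairs)} isotope pairs "
      f"(|dm - 1.003| < 0.01 Da, Pearson > 0.7)")

good = np.repeat(np.arange(5), 2)          # isotopes share a cluster
bad = np.tile([0, 1], 5)                   # isotopes split apart
for name, labels in [("good", good), ("bad", bad)]:
    ir = isotope_ratio(pairs, labels)
    rir = relative_isotope_ratio(pairs, labels)
    print(f"{name} clustering: IR={ir:.2f} RIR={rir:.2f}")
print("IR is the fraction of isotope pairs kept together; RIR divides it "
      "by the chance level of a size-matched random partition, so RIR~1 "
      "means no better than chance")
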