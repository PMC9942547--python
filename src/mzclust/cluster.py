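"""Final cluster assignment, cluster profiles, and peak-list export.

After training, each ion image's cluster is the argmax of its softmax
label features, c_i = argmax_p y_ip.  A cluster's spatial profile is the
mean ion image over its members — the hand-off consumed by downstream
spatial segmentation (e.g. spatial shrunken centroids in Cardinal), which
is outside this package's scope.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np

from .data_model import IonImageStack, mean_ion_image

__all__ = ["ClusterResult", "assign_clusters", "cluster_profiles",
           "export_cluster_peaklists"]


@dataclasses.dataclass
class ClusterResult:
    """Labels (0-based), per-cluster mean-image profiles and sizes."""

    labels: np.ndarray
    profiles: np.ndarray  # (k, h, w)
    sizes: np.ndarray  # (k,)

    @property
    def k(self) -> int:
        return len(self.sizes)

    @property
    def empty_clusters(self) -> list[int]:
        return np.flatnonzero(self.sizes == 0).tolist()


def assign_clusters(Y: np.ndarray) -> np.ndarray:
    """c_i = argmax_p y_ip; ties break to the lowest cluster index."""
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError(f"expected (n, k) label features, got shape {Y.shape}")
    return np.argmax(Y, axis=1)


def cluster_profiles(stack: IonImageStack, labels, k: int | None = None
                     ) -> ClusterResult:
    """Mean ion image and size per cluster; empty clusters get zero profiles."""
    labels = np.asarray(labels, dtype=np.int64)
    if len(labels) != stack.n:
        raise ValueError("labels length must match stack size")
    if k is None:
        k = int(labels.max()) + 1
    h, w = stack.images.shape[1:]
    profiles = np.zeros((k, h, w), dtype=np.float32)
    sizes = np.zeros(k, dtype=np.int64)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        sizes[c] = len(members)
        if len(members):
            profiles[c] = mean_ion_image(stack, members)
    return ClusterResult(labels=labels, profiles=profiles, sizes=sizes)


def export_cluster_peaklists(result: ClusterResult, mz, outdir) -> list[Path]:
    """Write one CSV peak list per cluster plus a JSON manifest.

    Cluster ids are 1-based in file names and the manifest; every m/z
    appears in exactly one peak list.  Returns the written CSV paths.
    """
    mz = np.asarray(mz)
    if len(mz) != len(result.labels):
        raise ValueError("mz length must match labels")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in range(result.k):
        path = outdir / f"cluster_{c + 1:02d}.csv"
        members = np.flatnonzero(result.labels == c)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["mz", "index"])
            for i in members:
                writer.writerow([repr(float(mz[i])), int(i)])
        paths.append(path)
    manifest = {
        "n_clusters": result.k,
        "n_ions": int(len(result.labels)),
        "sizes": {str(c + 1): int(s) for c, s in enumerate(result.sizes)},
        "empty_clusters": [c + 1 for c in result.empty_clusters],
        "files": [p.name for p in paths],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
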