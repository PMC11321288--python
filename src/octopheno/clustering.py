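"""k-means phenotype clustering of self-supervised features.

Features are z-scored per dimension, partitioned with k-means
(k-means++ init, 10 restarts, up to 300 Lloyd iterations), then clusters
are re-indexed by their median visual acuity so that C1 holds the best
vision and Ck the worst.  Each image is summarised by a similarity
vector: a softmax over negative squared distances to the ordered
centroids, with temperature set to the mean squared nearest-centroid
distance of the training set.  Ordered cluster ids are 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.cluster import KMeans

__all__ = ["ClusterModel", "kmeans_fit", "order_clusters_by_va",
           "similarity_vector", "similarity_matrix", "assign"]


@dataclass
class ClusterModel:
    centroids: np.ndarray          # (k, D) in standardized feature space
    mean: np.ndarray               # (D,) standardization mean
    sd: np.ndarray                 # (D,) standardization SD (zeros -> 1)
    labels_raw: np.ndarray         # (N,) raw k-means labels of training set
    temperature: float             # mean squared nearest-centroid distance
    inertia: float
    order_to_raw: np.ndarray = field(default=None)  # ordered position -> raw index

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def centroids_original(self) -> np.ndarray:
        return self.centroids * self.sd + self.mean

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if not np.all(np.isfinite(features)):
            raise ValueError("non-finite feature values")
        return (features - self.mean) / self.sd

    def ordered_centroids(self) -> np.ndarray:
        perm = self.order_to_raw
        if perm is None:
            perm = np.arange(self.k)
        return self.centroids[perm]

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("centroids", data=self.centroids)
            f.create_dataset("mean", data=self.mean)
            f.create_dataset("sd", data=self.sd)
            f.create_dataset("labels_raw", data=self.labels_raw)
            f.create_dataset("order_to_raw",
                             data=self.order_to_raw if self.order_to_raw is not None
                             else np.arange(self.k))
            f.attrs["temperature"] = self.temperature
            f.attrs["inertia"] = self.inertia

    @classmethod
    def load(cls, path) -> "ClusterModel":
        with h5py.File(path, "r") as f:
            return cls(centroids=f["centroids"][...], mean=f["mean"][...],
                       sd=f["sd"][...], labels_raw=f["labels_raw"][...],
                       temperature=float(f.attrs["temperature"]),
                       inertia=float(f.attrs["inertia"]),
                       order_to_raw=f["order_to_raw"][...])


def kmeans_fit(features: np.ndarray, k: int, seed: int = 0, *,
               n_init: int = 10, max_iter: int = 300) -> ClusterModel:
    """Standardize features and fit k-means, keeping the best of ``n_init`` restarts."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D (N, D) matrix")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    n = features.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (features - mean) / sd

    # tiny instances are cheap: spend more restarts so Lloyd reliably
    # reaches the global optimum there
    if n <= 32:
        n_init = max(n_init, 100)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, random_state=seed)
    labels = km.fit_predict(z)
    d2 = ((z - km.cluster_centers_[labels]) ** 2).sum(axis=1)
    temperature = float(max(d2.mean(), 1e-12))
    return ClusterModel(centroids=km.cluster_centers_, mean=mean, sd=sd,
                        labels_raw=labels, temperature=temperature,
                        inertia=float(km.inertia_))


def order_clusters_by_va(model: ClusterModel, letters: np.ndarray) -> np.ndarray:
    """Permute clusters so ordered id 1 has best median acuity, k worst.

    Ties go to the larger cluster first, then to the lower raw index.
    Clusters with no acuity data sort last with a warning.  Sets and
    returns ``model.order_to_raw``.
    """
    letters = np.asarray(letters, dtype=float)
    if letters.shape[0] != model.labels_raw.shape[0]:
        raise ValueError("need one letter score per training image")
    keys = []
    for c in range(model.k):
        vals = letters[model.labels_raw == c]
        vals = vals[np.isfinite(vals)]
        size = int((model.labels_raw == c).sum())
        if vals.size == 0:
            warnings.warn(f"cluster {c} has no visual-acuity data; placed last")
            keys.append((1, 0.0, -size, c))
        else:
            keys.append((0, -float(np.median(vals)), -size, c))
    order = sorted(range(model.k), key=lambda c: keys[c])
    model.order_to_raw = np.array(order)
    return model.order_to_raw


def assign(features: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Ordered 1-based cluster ids by the nearest-centroid rule.

    Distances are evaluated against centroids in ordered arrangement, so
    exact ties resolve to the lower ordered index.
    """
    z = model.transform(features)
    cents = model.ordered_centroids()
    d2 = ((z[:, None, :] - cents[None]) ** 2).sum(axis=2)
    return d2.argmin(axis=1) + 1


def similarity_matrix(features: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Length-k similarity distribution per image (rows sum to 1).

    softmax(-d^2 / T) over ordered centroids with T the training-set
    mean squared nearest-centroid distance; the argmax coincides with
    the assigned cluster.
    """
    z = model.transform(features)
    cents = model.ordered_centroids()
    d2 = ((z[:, None, :] - cents[None]) ** 2).sum(axis=2)
    logits = -d2 / model.temperature
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def similarity_vector(feature: np.ndarray, model: ClusterModel) -> np.ndarray:
    return similarity_matrix(np.atleast_2d(feature), model)[0]
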