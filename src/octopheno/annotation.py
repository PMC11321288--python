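"""Cluster interpretability artifacts for specialist review.

Three annotation strategies make the unsupervised clusters reviewable:
(1) a stage-cluster matrix of conditional probabilities P(grading stage |
cluster) computed over the labelled subset, (2) GradCAM attribution maps
routed through a linear probe from feature space to cluster labels using
the final two convolutional layers of the encoder, and (3) seen/unseen
review panels of patient-unique images per cluster.  A per-cluster
summary table (#images, #patients, ratio) accompanies them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression

from . import nn
from .byol import EncoderState
from .clustering import ClusterModel

GRADING_LABELS = ["healthy", "early_intermediate_amd", "mnv",
                  "crora_250_1000", "crora_ge_1000"]

__all__ = ["GRADING_LABELS", "stage_cluster_matrix", "fit_linear_probe",
           "LinearProbe", "gradcam_attribution", "sample_review_panels",
           "ReviewPanel", "cluster_summary_table"]


def stage_cluster_matrix(assignments: np.ndarray, labels) -> tuple[pd.DataFrame, list]:
    """P(grading stage | cluster) over labelled images.

    Returns (k x S DataFrame indexed by ordered cluster id, list of
    cluster ids that contain no labelled image; their rows are NaN).
    Unknown label strings are rejected.
    """
    assignments = np.asarray(assignments)
    labels = pd.Series(labels)
    known = labels.dropna()
    bad = set(known.unique()) - set(GRADING_LABELS)
    if bad:
        raise ValueError(f"unknown grading label(s): {sorted(bad)!r}")
    if known.empty:
        raise ValueError("no labelled images")
    clusters = np.unique(assignments)
    mat = pd.DataFrame(index=clusters, columns=GRADING_LABELS, dtype=float)
    flagged = []
    for c in clusters:
        sel = (assignments == c) & labels.notna().to_numpy()
        if not sel.any():
            flagged.append(int(c))
            continue
        counts = labels[sel].value_counts()
        mat.loc[c] = [counts.get(s, 0) / sel.sum() for s in GRADING_LABELS]
    mat.index.name = "cluster"
    return mat, flagged


@dataclass
class LinearProbe:
    """Multinomial linear map from (standardized) feature space to cluster ids."""

    coef: np.ndarray               # (k, D)
    intercept: np.ndarray          # (k,)
    classes: np.ndarray            # ordered cluster ids
    train_accuracy: float
    feature_mean: np.ndarray = None
    feature_sd: np.ndarray = None

    def logits(self, features: np.ndarray) -> np.ndarray:
        return np.atleast_2d(features) @ self.coef.T + self.intercept

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.classes[self.logits(features).argmax(axis=1)]


def fit_linear_probe(features: np.ndarray, assignments: np.ndarray, *,
                     mean: np.ndarray | None = None,
                     sd: np.ndarray | None = None,
                     max_epochs: int = 500, tol: float = 1e-6) -> LinearProbe:
    """Unregularized multinomial logistic fit of cluster ids on features.

    ``mean``/``sd`` record the standardization applied upstream so that
    GradCAM can chain gradients back to raw encoder features.
    """
    features = np.asarray(features, dtype=float)
    assignments = np.asarray(assignments)
    if np.unique(assignments).size < 2:
        raise ValueError("need at least two distinct clusters to fit a probe")
    clf = LogisticRegression(C=np.inf, max_iter=max_epochs, tol=tol)
    clf.fit(features, assignments)
    acc = float(clf.score(features, assignments))
    coef, intercept = clf.coef_, clf.intercept_
    if coef.shape[0] == 1 and len(clf.classes_) == 2:
        # binary fit returns one row; expand to symmetric per-class logits
        coef = np.vstack([-coef[0], coef[0]])
        intercept = np.array([-intercept[0], intercept[0]])
    d = features.shape[1]
    return LinearProbe(coef=coef, intercept=intercept,
                       classes=clf.classes_, train_accuracy=acc,
                       feature_mean=np.zeros(d) if mean is None else np.asarray(mean),
                       feature_sd=np.ones(d) if sd is None else np.asarray(sd))


@dataclass
class AttributionMap:
    map: np.ndarray                # (H, W), in [0, 1]
    cluster_id: int
    degenerate: bool = False       # all-zero after rectification


def _conv_relu_indices(backbone: nn.Sequential) -> list[int]:
    """Indices of the ReLU outputs following the final two conv layers."""
    conv_idx = [i for i, l in enumerate(backbone.layers) if isinstance(l, nn.Conv2d)]
    targets = []
    for ci in conv_idx[-2:]:
        j = ci
        while j < len(backbone.layers) and not isinstance(backbone.layers[j], nn.ReLU):
            j += 1
        targets.append(j)
    return targets


def gradcam_attribution(state: EncoderState, probe: LinearProbe,
                        image: np.ndarray, cluster_id: int, *,
                        combine: str = "mean") -> AttributionMap:
    """GradCAM map for ``cluster_id`` over the final two conv layers of f.

    Channel weights are the spatially averaged gradients of the cluster
    logit; the rectified weighted activation sums from both layers are
    upsampled to image resolution and combined (mean by default, max via
    ``combine='max'``), then max-normalized to [0, 1].
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if cluster_id not in probe.classes:
        raise ValueError(f"cluster id {cluster_id} not in probe classes")
    ci = int(np.where(probe.classes == cluster_id)[0][0])

    backbone = state.backbone
    x = image[None, None]
    _, outs = backbone.forward_collect(x, train=False)
    targets = _conv_relu_indices(backbone)

    # gradient of the cluster logit wrt raw features, chained through z-scoring
    g = (probe.coef[ci] / probe.feature_sd)[None, :]
    grads_at = {}
    for i in range(len(backbone.layers) - 1, -1, -1):
        if i in targets:
            grads_at[i] = g.copy()
        g = backbone.layers[i].backward(g)

    cams = []
    for i in targets:
        act = outs[i][0]                      # (C, h, w)
        grad = grads_at[i].reshape(act.shape)
        weights = grad.mean(axis=(1, 2))      # spatially averaged gradients
        cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
        cams.append(resize(cam, image.shape, order=1, anti_aliasing=False,
                           preserve_range=True))
    combined = np.maximum.reduce(cams) if combine == "max" else np.mean(cams, axis=0)
    combined = np.maximum(combined, 0.0)
    peak = combined.max()
    if peak <= 0:
        warnings.warn("attribution map is zero after rectification")
        return AttributionMap(map=np.zeros_like(image), cluster_id=int(cluster_id),
                              degenerate=True)
    return AttributionMap(map=combined / peak, cluster_id=int(cluster_id))


@dataclass
class ReviewPanel:
    cluster_id: int
    seen: list                     # image indices, one per distinct patient
    unseen: list
    truncated: bool = False


def sample_review_panels(assignments: np.ndarray, patient_ids, rng,
                         n_seen: int = 10, n_unseen: int = 10) -> dict[int, ReviewPanel]:
    """Per-cluster seen/unseen panels with all images from distinct patients.

    Patients are sampled uniformly without replacement; one image per
    sampled patient.  Clusters with fewer than ``n_seen + n_unseen``
    patients yield truncated panels with a warning.
    """
    assignments = np.asarray(assignments)
    patient_ids = np.asarray(patient_ids)
    panels = {}
    for c in np.unique(assignments):
        in_c = np.flatnonzero(assignments == c)
        by_patient: dict = {}
        for i in in_c:
            by_patient.setdefault(patient_ids[i], []).append(int(i))
        pats = sorted(by_patient)
        want = n_seen + n_unseen
        take = min(want, len(pats))
        truncated = take < want
        if truncated:
            warnings.warn(f"cluster {c}: only {len(pats)} patients; panel truncated")
        chosen = rng.choice(len(pats), size=take, replace=False)
        picks = [by_patient[pats[j]][rng.integers(len(by_patient[pats[j]]))]
                 for j in chosen]
        panels[int(c)] = ReviewPanel(cluster_id=int(c), seen=picks[:n_seen],
                                     unseen=picks[n_seen:], truncated=truncated)
    return panels


def cluster_summary_table(assignments: np.ndarray, patient_ids) -> pd.DataFrame:
    """Per-cluster image and unique-patient counts with images/patient ratio.

    The ratio is rounded to one decimal; a totals row is appended.
    """
    assignments = np.asarray(assignments)
    patient_ids = pd.Series(patient_ids)
    if patient_ids.isna().any():
        raise ValueError("every image needs a patient id")
    df = pd.DataFrame({"cluster": assignments, "patient_id": patient_ids})
    rows = []
    for c, grp in df.groupby("cluster"):
        n_img, n_pat = len(grp), grp["patient_id"].nunique()
        rows.append({"cluster": c, "n_images": n_img, "n_patients": n_pat,
                     "ratio": round(n_img / n_pat, 1)})
    out = pd.DataFrame(rows)
    total_pat = df["patient_id"].nunique()
    out.loc[len(out)] = {"cluster": "total", "n_images": len(df),
                         "n_patients": total_pat,
                         "ratio": round(len(df) / total_pat, 1)}
    return out
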