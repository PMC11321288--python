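# octopheno

Self-supervised phenotype discovery in retinal OCT. `octopheno` is a
research tool for proposing candidate imaging biomarkers of age-related
macular degeneration (AMD): it pretrains a convolutional encoder *f* on
unlabelled fovea-centered B-scans with a BYOL-style contrastive
objective, partitions the learned feature space into *k* clusters,
annotates each cluster for specialist review (visual-acuity ordering,
stage–cluster conditional probabilities, GradCAM attribution maps,
seen/unseen review panels), and benchmarks the clusters' prognostic
value against demographic, clinical-grading and fully supervised
baselines. Because the clinical cohorts this workflow targets are not
public, the package includes a synthetic OCT cohort generator with
planted, ground-truth biomarkers so the whole pipeline is testable end
to end.

It is aimed at researchers in ophthalmic image analysis who want a
reproducible, CPU-only reference implementation of the
contrastive-clustering biomarker-proposal workflow.

## Method sketch

1. **Contrastive pretraining.** Two augmented views of each B-scan
   (brightness, contrast, rotation, aspect ratio, horizontal flip,
   random resized crop) are encoded by an online network
   (encoder → projector → predictor) trained to predict the projection
   of a target network (EMA of the online weights, decay τ = 0.996).
   The per-pair loss is the normalized squared distance
   `L(p, z) = 2 − 2·cos(p, z)`, symmetrized over the view orderings;
   optimization is Adam (β₁ = 0.9, lr 5·10⁻⁴, weight decay 1.5·10⁻⁶).
2. **Clustering.** Penultimate-layer features are z-scored and
   partitioned by k-means (k-means++, 10 restarts). Clusters are
   re-indexed C1…Ck by descending median visual acuity, and each image
   gets a similarity vector `softmax(−d²/T)` over the ordered centroids.
3. **Annotation.** P(grading stage | cluster) matrices, linear-probe
   GradCAM attribution over the final two conv layers, and
   patient-unique review panels.
4. **Prognosis.** Lasso regression on similarity vectors predicts time
   to MNV / cRORA / late AMD (years) and current visual acuity
   (letters), under patient-wise 80/20 cross-validation repeated over
   folds and seeds, reported as MAE mean ± SD.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from octopheno import (CohortConfig, generate_cohort, AugmentationPolicy,
                       TrainConfig, train_byol, extract_features,
                       kmeans_fit, order_clusters_by_va, assign)
from octopheno.annotation import cluster_summary_table
from sklearn.metrics import adjusted_rand_score

cfg = CohortConfig(n_patients=100, visits_per_eye=2, seed=1)
images, visits, truth = generate_cohort(cfg)          # (200, 64, 64)

state = train_byol(images, AugmentationPolicy(),
                   TrainConfig(steps=300, batch_size=32, seed=0))
feats = extract_features(state, images)               # (200, 64)

model = kmeans_fit(feats, k=6, seed=0)
order_clusters_by_va(model, visits["letters"].to_numpy())
ids = assign(feats, model)

print("ARI vs planted classes:",
      round(adjusted_rand_score(truth.class_labels, ids), 3))
print(cluster_summary_table(ids, visits["patient_id"]).to_string(index=False))
```

Output (seed 1):

```
ARI vs planted classes: 0.163
cluster  n_images  n_patients  ratio
      1        87          56    1.6
      2        51          40    1.3
      3        20          15    1.3
      4        12          10    1.2
      5         5           4    1.2
      6        25          18    1.4
  total       200         100    2.0
```

Ordered cluster ids run from 1 (best median visual acuity) to 6
(worst); the summary table counts images and distinct patients per
cluster, mirroring how a clinical review would gauge whether a cluster
is patient-specific. Even this abbreviated 300-step training groups
images by planted biomarker well above chance (ARI 0 would be random);
the full 2000-step desk-scale run reaches ARI ≈ 0.3–0.4 against six
planted classes versus ≈ 0.08 for clustering raw pixels. The full CLI
(`octopheno simulate|pretrain|extract|cluster|annotate|prognose|report
--config cfg.yaml --seed 0 --outdir out/`) runs the same stages from a
YAML config and writes CSV/HDF5/PNG artifacts stamped with the config
hash.

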