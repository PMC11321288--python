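import numpy as np
import pytest

from octopheno.augment import AugmentationPolicy
from octopheno.byol import TrainConfig, extract_features, train_byol
from octopheno.clustering import assign, kmeans_fit, order_clusters_by_va
from octopheno.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 80-image cohort shared by unit tests (not the desk-scale run)."""
    cfg = CohortConfig(n_patients=40, eyes_per_patient=1, visits_per_eye=2, seed=11)
    images, visits, truth = generate_cohort(cfg)
    return cfg, images, visits, truth


@pytest.fixture(scope="session")
def desk_scale_run():
    """The desk-scale experiment: 2000 synthetic 64x64 B-scans, 6 planted
    classes, 2000 BYOL steps, k-means at k = number of classes.

    Computed once per session; shared by the training-behaviour tests and
    the end-to-end acceptance tests.
    """
    cfg = CohortConfig(n_patients=500, eyes_per_patient=1, visits_per_eye=4, seed=7)
    images, visits, truth = generate_cohort(cfg)
    policy = AugmentationPolicy()
    state = train_byol(images, policy, TrainConfig(steps=2000, batch_size=64, seed=0))
    feats = extract_features(state, images)
    model = kmeans_fit(feats, k=len(cfg.classes), seed=0)
    order_clusters_by_va(model, visits["letters"].to_numpy(float))
    ids = assign(feats, model)
    return cfg, images, visits, truth, state, feats, model, ids


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
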