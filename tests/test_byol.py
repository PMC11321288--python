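"""BYOL loss/EMA closed forms, gradient correctness, and training behaviour."""

import numpy as np
import pytest

from octopheno import nn
from octopheno.augment import AugmentationPolicy
from octopheno.byol import (EncoderState, TrainConfig, byol_loss, ema_update,
                            extract_features, load_checkpoint, save_checkpoint,
                            train_byol)


class TestLoss:
    def test_parallel_orthogonal_antiparallel(self, rng):
        v = rng.normal(size=12)
        assert byol_loss(v, v) == pytest.approx(0.0)
        assert byol_loss([1, 0], [0, 1]) == pytest.approx(2.0)
        assert byol_loss(v, -v) == pytest.approx(4.0)

    def test_scale_invariance(self, rng):
        p, z = rng.normal(size=8), rng.normal(size=8)
        assert byol_loss(3.7 * p, 0.01 * z) == pytest.approx(byol_loss(p, z))

    def test_bounds(self, rng):
        for _ in range(50):
            val = byol_loss(rng.normal(size=5), rng.normal(size=5))
            assert 0.0 <= val <= 4.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            byol_loss(np.zeros(4), np.ones(4))


class TestEMA:
    def test_closed_forms(self):
        t = {"w": np.array([1.0])}
        o = {"w": np.array([0.0])}
        ema_update(t, o, 0.9)
        assert t["w"][0] == pytest.approx(0.9)
        t2 = {"w": np.array([5.0])}
        ema_update(t2, {"w": np.array([1.0])}, 0.0)
        assert t2["w"][0] == pytest.approx(1.0)  # decay 0 copies online

    def test_decay_one_rejected_shape_checked(self):
        with pytest.raises(ValueError):
            ema_update({"w": np.zeros(2)}, {"w": np.zeros(2)}, 1.0)
        with pytest.raises(ValueError):
            ema_update({"w": np.zeros(2)}, {"w": np.zeros(3)}, 0.5)


class TestGradients:
    def test_conv_bn_linear_backward_match_numeric_gradient(self):
        """Finite-difference check of the full tiny network gradient."""
        rng = np.random.default_rng(0)
        net = nn.Sequential([
            nn.Conv2d(1, 2, stride=2, rng=rng), nn.BatchNorm2d(2), nn.ReLU(),
            nn.GlobalAvgPool(), nn.Linear(2, 3, rng=rng),
        ])
        x = rng.normal(size=(4, 1, 8, 8)).astype(nn.DTYPE)
        w = rng.normal(size=(4, 3))

        def loss_of(net_):
            y = net_.forward(x, train=True)
            return float((y * w).sum())

        y = net.forward(x, train=True)
        net.backward(w.astype(nn.DTYPE))
        for name, p, g in net.param_items():
            flat = p.ravel()
            idx = rng.integers(flat.size)
            eps = 1e-2
            old = flat[idx]
            flat[idx] = old + eps
            up = loss_of(net)
            flat[idx] = old - eps
            down = loss_of(net)
            flat[idx] = old
            num = (up - down) / (2 * eps)
            assert g.ravel()[idx] == pytest.approx(num, rel=0.05, abs=5e-3), name


@pytest.fixture(scope="module")
def tiny_training():
    """A short training run shared across cheap behavioural tests."""
    from octopheno.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(n_patients=60, visits_per_eye=2, seed=21)
    images, _, truth = generate_cohort(cfg)
    policy = AugmentationPolicy()
    config = TrainConfig(steps=250, batch_size=32, seed=4)
    state = train_byol(images, policy, config)
    return images, truth, policy, state


def _alignment_gain(state, images, policy, seed=99):
    """Mean two-view cosine minus mean cross-image cosine of features.

    A positive gain means views of one image agree more than features of
    different images do — the alignment the contrastive objective trains.
    """
    from octopheno.augment import augment as make_views

    rng = np.random.default_rng(seed)
    cos = []
    for img in images:
        a, b = make_views(img, policy, rng)
        f = extract_features(state, np.stack([a, b]))
        cos.append(1 - byol_loss(f[0], f[1]) / 2)
    feats = extract_features(state, images)
    fn = feats / np.linalg.norm(feats, axis=1, keepdims=True)
    gram = fn @ fn.T
    cross = gram[np.triu_indices(len(images), 1)].mean()
    return float(np.mean(cos) - cross)


class TestTraining:
    def test_single_step_changes_parameters(self):
        rng = np.random.default_rng(0)
        images = rng.uniform(size=(4, 64, 64))
        cfg = TrainConfig(steps=1, batch_size=2, seed=0)
        state = train_byol(images, AugmentationPolicy(), cfg)
        init = train_byol(images, AugmentationPolicy(),
                          TrainConfig(steps=1, batch_size=2, seed=0, lr=1e-12))
        diff = [np.abs(a - b).max() for (_, a, _), (_, b, _) in
                zip(state.backbone.param_items(), init.backbone.param_items())]
        assert max(diff) > 0
        assert len(state.log) >= 1

    def test_view_alignment_improves_with_training(self, desk_scale_run):
        """After training, two views of one image agree more (relative to the
        cross-image baseline) than they do at initialization."""
        cfg, images, _, _, state, _, _, _ = desk_scale_run
        policy = state.policy
        held_out = images[-25:]
        untrained = train_byol(images[:4], policy, TrainConfig(steps=1, batch_size=2,
                                                               seed=0, lr=1e-12))
        trained_gain = _alignment_gain(state, held_out, policy)
        assert trained_gain > _alignment_gain(untrained, held_out, policy)
        assert trained_gain > 0

    def test_no_feature_collapse(self, desk_scale_run):
        _, images, _, _, state, feats, _, _ = desk_scale_run
        assert feats[:200].std(axis=0).min() > 1e-3

    def test_linear_probe_gain_over_raw_pixels(self, desk_scale_run):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        _, images, _, truth, _, feats, _, _ = desk_scale_run
        pix = images.reshape(len(images), -1)
        y = truth.class_labels
        acc_f = cross_val_score(LogisticRegression(max_iter=1000), feats, y, cv=3).mean()
        acc_p = cross_val_score(LogisticRegression(max_iter=1000), pix, y, cv=3).mean()
        assert acc_f > acc_p

    def test_extraction_batching_equivalence_and_duplicates(self, tiny_training):
        images, _, _, state = tiny_training
        stack = np.concatenate([images[:6], images[:1]])  # duplicate of image 0
        f1 = extract_features(state, stack, batch_size=1)
        f32 = extract_features(state, stack, batch_size=32)
        assert np.allclose(f1, f32, atol=1e-5)
        assert np.allclose(f32[0], f32[-1], atol=1e-6)

    def test_checkpoint_roundtrip(self, tiny_training, tmp_path):
        images, _, _, state = tiny_training
        path = tmp_path / "ckpt.h5"
        save_checkpoint(state, path)
        loaded = load_checkpoint(path)
        a = extract_features(state, images[:5])
        b = extract_features(loaded, images[:5])
        assert np.allclose(a, b)

    def test_training_determinism(self):
        rng = np.random.default_rng(3)
        images = rng.uniform(size=(12, 64, 64))
        cfg = TrainConfig(steps=5, batch_size=4, seed=8)
        s1 = train_byol(images, AugmentationPolicy(), cfg)
        s2 = train_byol(images, AugmentationPolicy(), cfg)
        f1 = extract_features(s1, images)
        f2 = extract_features(s2, images)
        assert np.array_equal(f1, f2)
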