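"""BYOL-style self-supervised pretraining of the OCT feature extractor.

An online network (encoder f + projector + predictor) is trained to
predict the projection that a slowly moving target network (EMA copy of
encoder + projector) assigns to a second augmented view of the same
B-scan.  The loss is the normalised squared distance 2 - 2*cos(p, z),
symmetrised over the two view orderings.  After training, features are
read from the penultimate layer of f (global-average-pooled activations)
with no augmentation applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import nn
from .augment import AugmentationPolicy, augment

__all__ = [
    "TrainConfig",
    "EncoderState",
    "build_encoder",
    "byol_loss",
    "ema_update",
    "train_byol",
    "extract_features",
]


@dataclass
class TrainConfig:
    """Optimisation settings for BYOL pretraining.

    Defaults follow the Adam recipe (beta1 = 0.9, weight decay 1.5e-6,
    learning rate 5e-4) with an EMA target decay of 0.996; ``steps`` and
    ``batch_size`` are sized for the desk-scale 64x64 cohort.
    """

    steps: int = 2000
    batch_size: int = 64
    lr: float = 5e-4
    weight_decay: float = 1.5e-6
    beta1: float = 0.9
    ema_decay: float = 0.996
    proj_hidden: int = 128
    proj_dim: int = 32
    widths: tuple = (16, 32, 64, 64)
    readout: str = "avgmax"       # "avg", "max" or "avgmax" feature readout
    input_pool: int = 2           # fixed s x s average pooling before conv1
    seed: int = 0
    log_every: int = 50

    def validate(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not (0.0 <= self.ema_decay < 1.0):
            raise ValueError("ema_decay must be in [0,1)")


@dataclass
class EncoderState:
    """Online + target networks and bookkeeping after (or during) training."""

    backbone: nn.Sequential
    projector: nn.Sequential
    predictor: nn.Sequential
    target_backbone: nn.Sequential
    target_projector: nn.Sequential
    feature_width: int
    policy: AugmentationPolicy
    config: TrainConfig
    log: list = field(default_factory=list)


def feature_width(config: TrainConfig) -> int:
    return config.widths[-1] * (2 if config.readout == "avgmax" else 1)


def build_encoder(widths=(16, 32, 64, 64), rng=None, readout="avgmax",
                  input_pool=1) -> nn.Sequential:
    """Small conv backbone: stride-2 conv/BN/ReLU blocks then global pooling.

    The feature readout is the spatial mean of the last block ("avg") or
    the mean concatenated with the spatial max ("avgmax"); the latter
    keeps small focal lesion responses visible in the feature vector.
    Feature width is the last block's channel count (doubled for
    "avgmax"); a wide ResNet-class stack with 2048 features is the
    full-scale analogue.
    """
    rng = rng or np.random.default_rng(0)
    layers = []
    if input_pool > 1:
        layers.append(nn.AvgPool2d(input_pool))
    cin = 1
    for cout in widths:
        layers += [nn.Conv2d(cin, cout, k=3, stride=2, pad=1, rng=rng),
                   nn.BatchNorm2d(cout), nn.ReLU()]
        cin = cout
    readouts = {"avg": nn.GlobalAvgPool, "max": nn.GlobalMaxPool,
                "avgmax": nn.GlobalAvgMaxPool}
    layers.append(readouts[readout]())
    return nn.Sequential(layers)


def _build_head(cin, hidden, cout, rng) -> nn.Sequential:
    return nn.Sequential([
        nn.Linear(cin, hidden, rng=rng), nn.BatchNorm1d(hidden), nn.ReLU(),
        nn.Linear(hidden, cout, rng=rng),
    ])


def byol_loss(p: np.ndarray, z: np.ndarray) -> float:
    """Normalised squared distance 2 - 2*cos(p, z); lies in [0, 4].

    Invariant to positive rescaling of either argument; rejects zero
    vectors, whose direction is undefined.
    """
    p = np.asarray(p, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if p.shape != z.shape:
        raise ValueError("vectors must have equal length")
    np_, nz = np.linalg.norm(p), np.linalg.norm(z)
    if np_ == 0.0 or nz == 0.0:
        raise ValueError("byol_loss undefined for zero vectors")
    return float(2.0 - 2.0 * np.dot(p, z) / (np_ * nz))


def ema_update(target, online, decay: float):
    """target <- decay * target + (1 - decay) * online, elementwise.

    Accepts matching dicts of arrays, bare arrays, or Sequential modules
    (all state arrays, including BN running statistics, are blended).
    Updates in place and returns the target.
    """
    if not (0.0 <= decay < 1.0):
        raise ValueError("decay must be in [0,1)")
    if isinstance(target, nn.Sequential):
        tdict, odict = target.state_arrays(), online.state_arrays()
    elif isinstance(target, dict):
        tdict, odict = target, online
    else:
        t, o = np.asarray(target, dtype=float), np.asarray(online, dtype=float)
        if t.shape != o.shape:
            raise ValueError("shape mismatch")
        return decay * t + (1.0 - decay) * o
    if set(tdict) != set(odict):
        raise ValueError("parameter key mismatch")
    for key in tdict:
        if np.shape(tdict[key]) != np.shape(odict[key]):
            raise ValueError(f"shape mismatch for {key}")
        tdict[key][...] = decay * tdict[key] + (1.0 - decay) * odict[key]
    return target


def _normalized_mse_grad(p: np.ndarray, z: np.ndarray):
    """Per-row loss 2-2cos and gradient wrt p (z treated as constant)."""
    pn = np.linalg.norm(p, axis=1, keepdims=True)
    zn = np.linalg.norm(z, axis=1, keepdims=True)
    phat, zhat = p / pn, z / zn
    cos = (phat * zhat).sum(axis=1, keepdims=True)
    loss = 2.0 - 2.0 * cos
    dp = -2.0 * (zhat - cos * phat) / pn
    return loss.ravel(), dp


def train_byol(images: np.ndarray, policy: AugmentationPolicy,
               config: TrainConfig) -> EncoderState:
    """Run BYOL pretraining on a stack of standardized B-scans (N,H,W)."""
    config.validate()
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] < 2:
        raise ValueError("need a (N,H,W) stack with at least 2 images")
    rng = np.random.default_rng(config.seed)
    init_rng = np.random.default_rng(rng.integers(2**31))

    backbone = build_encoder(config.widths, rng=init_rng, readout=config.readout,
                             input_pool=config.input_pool)
    d = feature_width(config)
    projector = _build_head(d, config.proj_hidden, config.proj_dim, init_rng)
    predictor = _build_head(config.proj_dim, config.proj_hidden, config.proj_dim, init_rng)
    t_backbone = backbone.clone()
    t_projector = projector.clone()

    opt = nn.Adam([backbone, projector, predictor], lr=config.lr,
                  beta1=config.beta1, weight_decay=config.weight_decay)

    n = images.shape[0]
    log = []
    for step in range(config.steps):
        idx = rng.choice(n, size=min(config.batch_size, n), replace=n < config.batch_size)
        v1, v2 = [], []
        for i in idx:
            a, b = augment(images[i], policy, rng)
            v1.append(a)
            v2.append(b)
        x = np.stack(v1 + v2)[:, None].astype(nn.DTYPE)  # (2B,1,H,W): both orderings in one pass

        feats = backbone.forward(x, train=True)
        proj = projector.forward(feats, train=True)
        pred = predictor.forward(proj, train=True)

        tfeats = t_backbone.forward(x, train=True)
        tproj = t_projector.forward(tfeats, train=True)
        bsz = len(idx)
        z = np.concatenate([tproj[bsz:], tproj[:bsz]])  # swap: p(v1)->z(v2), p(v2)->z(v1)

        loss_rows, dpred = _normalized_mse_grad(pred, z)
        loss = float(loss_rows.mean())
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite BYOL loss at step {step}")

        backbone.backward(projector.backward(predictor.backward(
            (dpred / len(loss_rows)).astype(nn.DTYPE))))
        opt.step()
        ema_update(t_backbone, backbone, config.ema_decay)
        ema_update(t_projector, projector, config.ema_decay)

        if step % config.log_every == 0 or step == config.steps - 1:
            log.append((step, loss))

    return EncoderState(backbone, projector, predictor, t_backbone, t_projector,
                        feature_width=d, policy=policy, config=config, log=log)


def extract_features(state: EncoderState, images: np.ndarray,
                     batch_size: int = 64) -> np.ndarray:
    """Penultimate-layer features for each image, inference mode, no augmentation."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    rows = []
    for start in range(0, images.shape[0], batch_size):
        x = images[start : start + batch_size][:, None].astype(nn.DTYPE)
        rows.append(state.backbone.forward(x, train=False))
    feats = np.concatenate(rows)
    if not np.all(np.isfinite(feats)):
        raise FloatingPointError("non-finite features extracted")
    return feats


def save_checkpoint(state: EncoderState, path):
    """Persist weights + config + augmentation policy as keyed HDF5 arrays."""
    import json

    with h5py.File(path, "w") as f:
        for group, mod in [("backbone", state.backbone), ("projector", state.projector),
                           ("predictor", state.predictor),
                           ("target_backbone", state.target_backbone),
                           ("target_projector", state.target_projector)]:
            g = f.create_group(group)
            for key, arr in mod.state_arrays().items():
                g.create_dataset(key, data=arr)
        f.attrs["feature_width"] = state.feature_width
        f.attrs["config"] = json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                                        for k, v in vars(state.config).items()})
        f.attrs["policy"] = json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                                        for k, v in vars(state.policy).items()})
        f.attrs["log"] = json.dumps(state.log)


def load_checkpoint(path) -> EncoderState:
    import json

    with h5py.File(path, "r") as f:
        cfg_raw = json.loads(f.attrs["config"])
        pol_raw = json.loads(f.attrs["policy"])
        for k, v in list(cfg_raw.items()):
            if isinstance(v, list):
                cfg_raw[k] = tuple(v)
        for k, v in list(pol_raw.items()):
            if isinstance(v, list):
                pol_raw[k] = tuple(v)
        config = TrainConfig(**cfg_raw)
        policy = AugmentationPolicy(**pol_raw)
        rng = np.random.default_rng(0)
        backbone = build_encoder(config.widths, rng=rng, readout=config.readout,
                                 input_pool=config.input_pool)
        d = feature_width(config)
        projector = _build_head(d, config.proj_hidden, config.proj_dim, rng)
        predictor = _build_head(config.proj_dim, config.proj_hidden, config.proj_dim, rng)
        t_backbone = backbone.clone()
        t_projector = projector.clone()
        for group, mod in [("backbone", backbone), ("projector", projector),
                           ("predictor", predictor), ("target_backbone", t_backbone),
                           ("target_projector", t_projector)]:
            mod.load_state_arrays({k: np.array(v) for k, v in f[group].items()})
        log = [tuple(x) for x in json.loads(f.attrs["log"])]
    return EncoderState(backbone, projector, predictor, t_backbone, t_projector,
                        feature_width=d, policy=policy, config=config, log=log)
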