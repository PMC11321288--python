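"""Contrastive view generation for OCT B-scans.

The augmentation family deliberately spans nuisance factors of OCT
acquisition — global brightness and contrast, small rotations, aspect
ratio, horizontal symmetry, and a randomly sized and located crop — so
that the encoder learns features invariant to them while structural
biomarkers survive every transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize


@dataclass
class AugmentationPolicy:
    """Ranges for the stochastic transforms applied to each view.

    brightness: additive shift sampled from [-brightness, +brightness]
    (fraction of the [0,1] intensity scale); contrast: multiplicative
    factor about the image mean; rotation in degrees; aspect ratio
    stretches the crop window; crop_area is the fraction of image area
    retained before resizing back to ``out_size``.
    """

    brightness: float = 0.2
    contrast: tuple = (0.8, 1.25)
    rotation: float = 10.0
    aspect: tuple = (0.9, 1.1)
    flip_prob: float = 0.5
    crop_area: tuple = (0.7, 1.0)
    vertical_warp: float = 4.0
    horizontal_shift: float = 10.0
    speckle: float = 0.15
    out_size: tuple = (64, 64)

    def validate(self):
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0,1]")
        if not (0.0 < self.crop_area[0] <= self.crop_area[1] <= 1.0):
            raise ValueError("crop_area fractions must lie in (0,1]")
        for name in ("brightness", "rotation"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} range must be finite")

    @classmethod
    def identity(cls, out_size=(64, 64)) -> "AugmentationPolicy":
        return cls(brightness=0.0, contrast=(1.0, 1.0), rotation=0.0,
                   aspect=(1.0, 1.0), flip_prob=0.0, crop_area=(1.0, 1.0),
                   vertical_warp=0.0, horizontal_shift=0.0, speckle=0.0,
                   out_size=out_size)


def _vertical_warp(img: np.ndarray, amp: float, rng: np.random.Generator):
    """Smooth per-column vertical displacement (anatomy-shape nuisance).

    The field is a low-frequency sinusoid plus a Gaussian bump, emulating
    inter-eye variation in layer position, tilt and foveal-pit shape so
    the encoder learns to ignore it.
    """
    h, w = img.shape
    x = np.arange(w)
    field = np.full(w, rng.uniform(-amp, amp))  # global vertical shift
    field = field + rng.uniform(-amp, amp) * np.sin(
        2 * np.pi * rng.uniform(0.5, 2.0) * x / w + rng.uniform(0, 2 * np.pi))
    center = rng.uniform(0.25 * w, 0.75 * w)
    sigma = rng.uniform(0.1 * w, 0.3 * w)
    field = field + rng.uniform(-amp, amp) * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    rows = np.arange(h)[:, None] + field[None, :]
    cols = np.broadcast_to(x[None, :], (h, w))
    return ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")


def _one_view(img: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator):
    h, w = img.shape
    out = img.astype(float)

    c = rng.uniform(*policy.contrast)
    b = rng.uniform(-policy.brightness, policy.brightness)
    if c != 1.0 or b != 0.0:
        out = (out - out.mean()) * c + out.mean() + b

    angle = rng.uniform(-policy.rotation, policy.rotation) if policy.rotation else 0.0
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")

    if policy.vertical_warp > 0:
        out = _vertical_warp(out, policy.vertical_warp, rng)

    if policy.horizontal_shift > 0:
        dx = rng.uniform(-policy.horizontal_shift, policy.horizontal_shift)
        if dx != 0.0:
            out = ndimage.shift(out, (0.0, dx), order=1, mode="nearest")

    if policy.flip_prob and rng.uniform() < policy.flip_prob:
        out = out[:, ::-1]

    area = rng.uniform(*policy.crop_area)
    ar = rng.uniform(*policy.aspect)
    ch = int(round(h * np.sqrt(area / ar)))
    cw = int(round(w * np.sqrt(area * ar)))
    ch, cw = max(1, min(ch, h)), max(1, min(cw, w))
    if ch > h or cw > w:
        raise ValueError("crop larger than image")
    if (ch, cw) != (h, w):
        r0 = rng.integers(0, h - ch + 1)
        c0 = rng.integers(0, w - cw + 1)
        out = out[r0 : r0 + ch, c0 : c0 + cw]

    if out.shape != tuple(policy.out_size):
        out = resize(out, policy.out_size, order=1, anti_aliasing=False,
                     preserve_range=True)

    if policy.speckle > 0:
        # independent multiplicative noise per view: the only transform that
        # makes the encoder invariant to the acquisition speckle realisation
        level = rng.uniform(0.0, policy.speckle)
        out = out * (1.0 + level * rng.standard_normal(out.shape))

    return np.clip(out, 0.0, 1.0)


def augment(image: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator):
    """Draw two independent augmented views of one standardized B-scan."""
    policy.validate()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return _one_view(img, policy, rng), _one_view(img, policy, rng)
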