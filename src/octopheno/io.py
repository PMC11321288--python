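"""Input standardization, clinical score conversion, and on-disk formats.

Conventions used throughout the package: row 0 is the top of the B-scan
(vitreous), indices are 0-based, sizes are (height, width), intensities
live in [0, 1].  The full-scale standard frame is 208 x 256 pixels at
7.0 x 23.4 µm² per pixel; the desk-scale default is 64 x 64 with the
same 23.4 µm mediolateral pitch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

FULL_SCALE_SIZE = (208, 256)
FULL_SCALE_PIXEL_UM = (7.0, 23.4)

MANIFEST_COLUMNS = ["image_index", "patient_id", "eye_id", "visit_index",
                    "visit_time", "age", "sex", "letters", "logmar",
                    "grading_label"]


@dataclass
class BScan:
    """One standardized grayscale fovea-centered OCT slice."""

    image: np.ndarray
    pixel_size_um: tuple          # (axial, mediolateral)
    image_id: str = ""
    patient_id: str = ""
    eye_id: str = ""

    def validate(self):
        if self.image.ndim != 2:
            raise ValueError("B-scan must be 2-D grayscale")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("intensities must lie in [0,1]")


def standardize_bscan(raw: np.ndarray, target_size=FULL_SCALE_SIZE,
                      pixel_size_um=FULL_SCALE_PIXEL_UM, *, image_id: str = "",
                      patient_id: str = "", eye_id: str = "") -> BScan:
    """Bilinear resample to the target frame and min-max scale to [0,1].

    Colour inputs are rejected; a constant image degenerates to all
    zeros with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D grayscale image (colour inputs rejected)")
    img = raw
    if img.shape != tuple(target_size):
        img = resize(img, target_size, order=1, anti_aliasing=img.shape[0] > target_size[0],
                     preserve_range=True)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        warnings.warn("constant image; min-max scaling degenerates to zeros")
        img = np.zeros_like(img)
    return BScan(image=img, pixel_size_um=tuple(pixel_size_um), image_id=image_id,
                 patient_id=patient_id, eye_id=eye_id)


def logmar_to_letters(logmar):
    """ETDRS-style conversion letters = round(85 - 50*logMAR), clipped to [5, 95]."""
    arr = np.asarray(logmar, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("logMAR must be finite")
    letters = np.clip(np.round(85.0 - 50.0 * arr), 5.0, 95.0)
    return float(letters) if np.isscalar(logmar) or arr.ndim == 0 else letters


def write_manifest(visits: pd.DataFrame, path):
    visits.to_csv(path, index=False, float_format="%.6g")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "grading_label" in df:
        df["grading_label"] = df["grading_label"].where(df["grading_label"].notna(), None)
    return df


def save_image_png(image: np.ndarray, path):
    """8-bit grayscale PNG from a [0,1] float image."""
    iio.imwrite(path, (np.clip(image, 0, 1) * 255).round().astype(np.uint8))


def load_image_png(path) -> np.ndarray:
    return np.asarray(iio.imread(path), dtype=float) / 255.0


def save_features(features: np.ndarray, path):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=features)


def load_features(path) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as f:
        return f["features"][...]
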