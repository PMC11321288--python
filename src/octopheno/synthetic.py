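"""Synthetic OCT B-scan cohorts with planted, labelled AMD biomarkers.

A layered retinal phantom (ILM, RPE, Bruch's membrane, choroid–sclera
interface as smooth per-column boundary curves with a central foveal
pit) is perturbed by planted lesions that follow the standard grading
definitions — drusen as RPE elevations of known physical diameter,
fluid as hyporeflective pockets, atrophy as retinal thinning with
choroidal hypertransmission, a double-layer sign as a shallow RPE–Bruch
separation, scarring as subretinal hyperreflective material — then
rendered with per-layer reflectivities, multiplicative speckle and
scanner-like gain jitter.  Every image carries its ground truth (class,
lesion mask, true visual acuity, conversion times), making the cohort an
oracle for feature learning, clustering, attribution and prognosis.

Physical scale: the mediolateral pixel pitch is fixed at 23.4 µm so that
lesion sizes stated in µm convert to columns as round(size / 23.4); the
axial pitch is configurable (7.0 µm at full 208-row scale, coarser for
the 64-row desk scale so that retina plus choroid fit in the frame).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

LATERAL_UM_PER_PX = 23.4

#: planted classes in increasing order of functional severity
CLASS_ORDER = [
    "healthy",
    "thick_choroid",
    "drusen_small",
    "drusen_large",
    "DLS",
    "confluent_drusen",
    "PED",
    "subretinal_fluid",
    "atrophy_incomplete",
    "intraretinal_fluid",
    "atrophy_complete",
    "scarring",
]
ALL_CLASSES = CLASS_ORDER + ["poor_quality"]

#: mean true visual acuity in letters per class, strictly decreasing in severity
VA_BASE = {
    "healthy": 85.0, "thick_choroid": 82.0, "drusen_small": 79.0,
    "drusen_large": 75.0, "DLS": 72.0, "confluent_drusen": 69.0,
    "PED": 65.0, "subretinal_fluid": 62.0, "atrophy_incomplete": 58.0,
    "intraretinal_fluid": 54.0, "atrophy_complete": 48.0, "scarring": 38.0,
    "poor_quality": 68.0,
}

SEVERITY = {c: i for i, c in enumerate(CLASS_ORDER)}
SEVERITY["poor_quality"] = 2  # image quality, not pathology

#: mapping of planted classes onto the five-label clinical grading vocabulary
GRADING_MAP = {
    "healthy": "healthy", "thick_choroid": "healthy",
    "drusen_small": "early_intermediate_amd", "drusen_large": "early_intermediate_amd",
    "confluent_drusen": "early_intermediate_amd", "DLS": "early_intermediate_amd",
    "PED": "mnv", "subretinal_fluid": "mnv", "intraretinal_fluid": "mnv",
    "scarring": "mnv",
    "atrophy_incomplete": "crora_250_1000", "atrophy_complete": "crora_ge_1000",
    "poor_quality": None,
}

DEFAULT_REFLECTIVITY = {
    "vitreous": 0.05, "retina": 0.45, "rpe_band": 0.85, "choroid": 0.25,
    "sclera": 0.12, "fluid": 0.05, "scar": 0.92, "dls_gap": 0.10,
    "hyper_boost": 2.2,
}

DEFAULT_SIZE_UM = {
    "drusen_small": 45.0, "drusen_large": 120.0, "confluent_drusen": 420.0,
    "PED": 520.0, "subretinal_fluid": 500.0, "intraretinal_fluid": 320.0,
    "atrophy_incomplete": 420.0, "atrophy_complete": 800.0,
    "DLS": 520.0, "scarring": 700.0,
}


def um_to_cols(size_um: float) -> int:
    return int(round(size_um / LATERAL_UM_PER_PX))


@dataclass
class LayerGeometry:
    """Per-column boundary depths (pixels, row 0 = vitreous at top)."""

    ilm: np.ndarray
    rpe: np.ndarray
    bm: np.ndarray
    csi: np.ndarray
    height: int
    width: int
    pit_depth: float
    pit_width: float
    choroid_um: float
    axial_um: float
    # lesion rendering state
    fluid: list = field(default_factory=list)      # boolean pixel masks
    scars: list = field(default_factory=list)
    dls_cols: np.ndarray | None = None
    hyper_cols: np.ndarray | None = None           # boolean per column
    blur_sigma: float = 0.0
    shift_cols: int = 0

    def validate(self):
        if self.choroid_um <= 0:
            raise ValueError("choroid thickness must be > 0")
        for arr in (self.ilm, self.rpe, self.bm, self.csi):
            if arr.shape != (self.width,):
                raise ValueError("boundary length must equal image width")
            if np.any(arr < 0) or np.any(arr > self.height):
                raise ValueError("boundary depth outside image")
        if not (np.all(self.ilm < self.rpe) and np.all(self.rpe < self.bm)
                and np.all(self.bm < self.csi)):
            raise ValueError("boundaries must be strictly ordered top to bottom")

    def copy(self) -> "LayerGeometry":
        return replace(self, ilm=self.ilm.copy(), rpe=self.rpe.copy(),
                       bm=self.bm.copy(), csi=self.csi.copy(),
                       fluid=[m.copy() for m in self.fluid],
                       scars=[m.copy() for m in self.scars],
                       dls_cols=None if self.dls_cols is None else self.dls_cols.copy(),
                       hyper_cols=None if self.hyper_cols is None else self.hyper_cols.copy())


@dataclass
class BiomarkerSpec:
    """A planted lesion: class, physical size in µm, centre column."""

    label: str
    size_um: float | None = None
    column: int | None = None

    def validate(self, width: int):
        if self.label not in ALL_CLASSES:
            raise ValueError(f"unknown biomarker class {self.label!r}")
        size = self.resolved_size()
        if size is not None:
            if self.label == "drusen_large" and size < 63.0:
                raise ValueError("drusen_large requires diameter >= 63 um")
            if self.label in ("atrophy_incomplete", "atrophy_complete") and size < 250.0:
                raise ValueError("atrophy requires width >= 250 um")
            if um_to_cols(size) > width:
                raise ValueError("lesion wider than image")

    def resolved_size(self) -> float | None:
        if self.size_um is not None:
            return self.size_um
        return DEFAULT_SIZE_UM.get(self.label)


@dataclass
class CohortConfig:
    """Study-condition knobs for a generated cohort."""

    n_patients: int = 100
    eyes_per_patient: int = 1
    visits_per_eye: int = 3
    classes: tuple = ("healthy", "drusen_large", "PED", "intraretinal_fluid",
                      "atrophy_complete", "scarring")
    mixture: tuple | None = None          # defaults to uniform
    noise: float = 0.12
    gain_jitter: tuple = (0.85, 1.15)
    offset_jitter: float = 0.05
    image_size: tuple = (64, 64)
    axial_um: float = 12.0
    va_sd: float = 5.0
    visit_interval_years: float = 0.5
    # conversion-time model: t = max(0, a - b * severity) + Exp(scale)
    mnv_coeffs: tuple = (8.0, 1.0, 0.5)
    crora_coeffs: tuple = (10.0, 1.2, 0.5)
    label_fraction: float = 1.0
    seed: int = 0

    def resolved_mixture(self) -> np.ndarray:
        if self.mixture is None:
            return np.full(len(self.classes), 1.0 / len(self.classes))
        mix = np.asarray(self.mixture, dtype=float)
        if mix.shape != (len(self.classes),) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("mixture proportions must match classes and sum to 1")
        return mix

    def validate(self):
        if min(self.n_patients, self.eyes_per_patient, self.visits_per_eye) < 1:
            raise ValueError("all cohort counts must be >= 1")
        self.resolved_mixture()


@dataclass
class SyntheticGroundTruth:
    """Per-image oracle used by every downstream recovery test."""

    class_labels: np.ndarray            # (N,) planted class per image
    masks: np.ndarray                   # (N,H,W) boolean lesion masks
    conversions: pd.DataFrame           # eye_id, time_to_mnv, time_to_crora (years)
    va_true: np.ndarray                 # (N,) true letters before noise rounding
    outcome_coeffs: dict


def generate_retina_layers(height: int, width: int, pit_depth: float = 6.0,
                           pit_width: float = 16.0, rng=None, *,
                           choroid_um: float = 250.0, axial_um: float = 12.0,
                           undulation: float = 1.2) -> LayerGeometry:
    """Smooth, band-limited layered geometry with a central foveal pit."""
    if height < 64 or width < 64:
        raise ValueError("image must be at least 64 x 64 pixels")
    rng = rng or np.random.default_rng(0)
    x = np.arange(width)

    base = np.zeros(width)
    tilt = rng.uniform(-0.02, 0.02)
    base += tilt * (x - width / 2)
    for cycles in (1, 2, 3):
        base += rng.uniform(0, undulation) * np.sin(
            2 * np.pi * cycles * x / width + rng.uniform(0, 2 * np.pi))

    rpe = 0.55 * height + base
    thickness = 0.30 * height * rng.uniform(0.95, 1.05)
    ilm = rpe - thickness
    if pit_depth > 0:
        sigma = max(pit_width, 1.0) / 2.355  # FWHM -> SD
        ilm = ilm + pit_depth * np.exp(-0.5 * ((x - width / 2) / sigma) ** 2)
    rpe_band = max(2.0, 0.03 * height)
    bm = rpe + rpe_band
    csi = bm + choroid_um / axial_um

    geom = LayerGeometry(ilm=ilm, rpe=rpe, bm=bm, csi=np.minimum(csi, height - 1.0),
                         height=height, width=width, pit_depth=pit_depth,
                         pit_width=pit_width, choroid_um=choroid_um, axial_um=axial_um)
    geom.validate()
    return geom


def _bump(width_cols: int) -> np.ndarray:
    """Half-cosine dome profile over exactly ``width_cols`` columns."""
    i = np.arange(width_cols)
    return np.sin(np.pi * (i + 0.5) / width_cols)


def _col_window(center: int, w: int, width: int):
    c0 = int(np.clip(center - w // 2, 0, width - w))
    return c0, c0 + w


def plant_biomarker(geometry: LayerGeometry, spec: BiomarkerSpec, rng=None):
    """Apply one lesion; returns (modified geometry, boolean lesion mask)."""
    rng = rng or np.random.default_rng(0)
    geometry.validate()
    spec.validate(geometry.width)
    g = geometry.copy()
    h, w = g.height, g.width
    mask = np.zeros((h, w), dtype=bool)
    label = spec.label
    size = spec.resolved_size()
    rows = np.arange(h)[:, None]

    def center_col(wc):
        if spec.column is not None:
            return spec.column
        margin = max(wc // 2 + 1, int(0.15 * w))
        return int(rng.integers(margin, w - margin))

    def mark_between(upper: np.ndarray, lower: np.ndarray, c0: int, c1: int):
        """Mark pixels whose row lies in [upper, lower) for columns [c0, c1)."""
        sel = (rows >= np.minimum(upper, lower)[None, c0:c1]) & \
              (rows < np.maximum(upper, lower)[None, c0:c1])
        mask[:, c0:c1] |= sel

    if label in ("healthy",):
        return g, mask

    if label == "poor_quality":
        g.blur_sigma = float(rng.uniform(1.0, 2.0))
        g.shift_cols = int(rng.integers(-int(0.15 * w), int(0.15 * w) + 1))
        return g, mask

    if label in ("drusen_small", "drusen_large", "confluent_drusen", "PED"):
        wc = um_to_cols(size)
        c = center_col(wc)
        c0, c1 = _col_window(c, wc, w)
        if label == "confluent_drusen":
            profile = np.zeros(wc)
            n_bumps = 3
            seg = wc / n_bumps
            for k in range(n_bumps):
                s0, s1 = int(round(k * seg)), int(round((k + 1) * seg))
                profile[s0:s1] = _bump(s1 - s0)
            height_px = 0.06 * h
        else:
            profile = _bump(wc)
            height_px = {"drusen_small": 0.035, "drusen_large": 0.06, "PED": 0.14}[label] * h
        elev = height_px * profile
        old_rpe = g.rpe.copy()
        new_rpe = old_rpe[c0:c1] - elev
        new_rpe = np.maximum(new_rpe, g.ilm[c0:c1] + 1.0)
        g.rpe[c0:c1] = new_rpe
        mark_between(g.rpe, old_rpe + 1.0, c0, c1)
        g.validate()
        return g, mask

    if label in ("subretinal_fluid", "intraretinal_fluid"):
        wc = um_to_cols(size)
        c = center_col(wc)
        c0, c1 = _col_window(c, wc, w)
        pocket = np.zeros((h, w), dtype=bool)
        if label == "subretinal_fluid":
            depth = 0.10 * h * _bump(wc)
            upper = g.rpe[c0:c1] - depth
            sel = (rows >= upper[None, :]) & (rows < g.rpe[None, c0:c1])
            pocket[:, c0:c1] = sel
        else:
            n_blobs = 3
            cols = np.linspace(c0 + wc / 6, c1 - wc / 6, n_blobs)
            for bc in cols:
                ry = 0.05 * h * rng.uniform(0.8, 1.2)
                rx = wc / (2 * n_blobs)
                cy = (g.ilm[int(bc)] + g.rpe[int(bc)]) / 2 + rng.uniform(-0.02, 0.02) * h
                yy, xx = np.ogrid[:h, :w]
                pocket |= ((yy - cy) / ry) ** 2 + ((xx - bc) / rx) ** 2 <= 1.0
        g.fluid.append(pocket)
        mask |= pocket
        return g, mask

    if label in ("atrophy_incomplete", "atrophy_complete"):
        wc = um_to_cols(size)
        c = center_col(wc)
        c0, c1 = _col_window(c, wc, w)
        frac = 0.35 if label == "atrophy_incomplete" else 0.55
        thin = frac * (g.rpe[c0:c1] - g.ilm[c0:c1]) * _bump(wc)
        old_rpe = g.rpe.copy()
        g.rpe[c0:c1] = g.rpe[c0:c1] - thin  # RPE elevated: thinner retina
        g.rpe[c0:c1] = np.maximum(g.rpe[c0:c1], g.ilm[c0:c1] + 1.0)
        mark_between(g.rpe, old_rpe + 1.0, c0, c1)
        if label == "atrophy_complete":
            hyper = np.zeros(w, dtype=bool)
            hyper[c0:c1] = True
            g.hyper_cols = hyper
        g.validate()
        return g, mask

    if label == "thick_choroid":
        old_csi = g.csi.copy()
        extra = g.choroid_um * 0.8 / g.axial_um
        g.csi = np.minimum(g.csi + extra, h - 1.0)
        g.choroid_um *= 1.8
        mark_between(old_csi, g.csi, 0, w)
        g.validate()
        return g, mask

    if label == "DLS":
        wc = um_to_cols(size)
        c = center_col(wc)
        c0, c1 = _col_window(c, wc, w)
        dls = np.zeros(w, dtype=bool)
        dls[c0:c1] = True
        g.dls_cols = dls
        sep = 1.5 * _bump(wc)
        old_rpe = g.rpe.copy()
        g.rpe[c0:c1] = g.rpe[c0:c1] - sep
        g.rpe[c0:c1] = np.maximum(g.rpe[c0:c1], g.ilm[c0:c1] + 1.0)
        mark_between(g.rpe, old_rpe + 1.0, c0, c1)
        g.validate()
        return g, mask

    if label == "scarring":
        wc = um_to_cols(size)
        c = center_col(wc)
        c0, c1 = _col_window(c, wc, w)
        thick = 0.09 * h * _bump(wc)
        scar = np.zeros((h, w), dtype=bool)
        upper = g.rpe[c0:c1] - thick
        lower = g.rpe[c0:c1] + thick / 2
        sel = (rows >= upper[None, :]) & (rows < lower[None, :])
        scar[:, c0:c1] = sel
        g.scars.append(scar)
        mask |= scar
        return g, mask

    raise ValueError(f"unhandled biomarker class {label!r}")  # pragma: no cover


def render_bscan(geometry: LayerGeometry, reflectivity: dict | None = None,
                 noise: float = 0.0, rng=None,
                 gain_jitter: tuple | None = None,
                 offset_jitter: float = 0.0) -> np.ndarray:
    """Render geometry to a [0,1] grayscale image.

    With ``noise`` = 0 and no jitter the image is piecewise constant at
    the configured per-layer reflectivities.  Hypertransmission columns
    receive a brighter choroidal band; multiplicative speckle is applied
    last and the result clipped to [0,1].
    """
    geometry.validate()
    rng = rng or np.random.default_rng(0)
    refl = dict(DEFAULT_REFLECTIVITY)
    if reflectivity:
        refl.update(reflectivity)
    h, w = geometry.height, geometry.width
    rows = np.arange(h)[:, None]

    img = np.full((h, w), refl["vitreous"])
    img[rows >= geometry.ilm[None, :]] = refl["retina"]
    img[rows >= geometry.rpe[None, :]] = refl["rpe_band"]
    choroid_sel = rows >= geometry.bm[None, :]
    img[choroid_sel] = refl["choroid"]
    img[rows >= geometry.csi[None, :]] = refl["sclera"]

    if geometry.hyper_cols is not None and geometry.hyper_cols.any():
        boost = min(refl["choroid"] * refl["hyper_boost"], 0.9)
        band = choroid_sel & (rows < geometry.csi[None, :]) & geometry.hyper_cols[None, :]
        img[band] = boost

    if geometry.dls_cols is not None and geometry.dls_cols.any():
        gap = (rows >= geometry.rpe[None, :] + 0.5) & (rows < geometry.bm[None, :] - 0.5)
        img[gap & geometry.dls_cols[None, :]] = refl["dls_gap"]

    for pocket in geometry.fluid:
        img[pocket] = refl["fluid"]
    for scar in geometry.scars:
        img[scar] = refl["scar"]

    if geometry.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, geometry.blur_sigma)
    if geometry.shift_cols:
        img = np.roll(img, geometry.shift_cols, axis=1)

    if gain_jitter is not None:
        gain = rng.uniform(*gain_jitter)
        offset = rng.uniform(-offset_jitter, offset_jitter)
        img = (img - 0.5) * gain + 0.5 + offset
    if noise > 0:
        img = img * (1.0 + noise * rng.standard_normal(img.shape))
    return np.clip(img, 0.0, 1.0)


def _conversion_time(coeffs, severity, rng) -> float:
    a, b, scale = coeffs
    return float(max(0.0, a - b * severity) + rng.exponential(scale))


def generate_cohort(config: CohortConfig, rng=None):
    """Generate (images, visit table, ground truth) for a longitudinal cohort.

    Each eye keeps a fixed anatomy and lesion across visits; every visit
    is re-rendered with fresh speckle and scanner jitter.  True visual
    acuity is the class base plus Gaussian noise; conversion times
    decrease linearly in the ordinal severity of the planted class with
    exponential noise.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    mix = config.resolved_mixture()
    h, w = config.image_size

    images, mask_list, rows = [], [], []
    class_labels, va_true = [], []
    conv_rows = []
    image_index = 0
    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        age = float(np.clip(rng.normal(75, 8), 51, 102))
        sex = "F" if rng.uniform() < 0.55 else "M"
        for e in range(config.eyes_per_patient):
            eid = f"{pid}_E{e}"
            cls = str(rng.choice(config.classes, p=mix))
            geom = generate_retina_layers(h, w, pit_depth=rng.uniform(4, 8),
                                          pit_width=rng.uniform(12, 20), rng=rng,
                                          axial_um=config.axial_um)
            geom, mask = plant_biomarker(geom, BiomarkerSpec(cls), rng)
            sev = SEVERITY[cls]
            t_mnv = _conversion_time(config.mnv_coeffs, sev, rng)
            t_crora = _conversion_time(config.crora_coeffs, sev, rng)
            conv_rows.append({"eye_id": eid, "patient_id": pid,
                              "time_to_mnv": t_mnv, "time_to_crora": t_crora})
            for v in range(config.visits_per_eye):
                img = render_bscan(geom, noise=config.noise, rng=rng,
                                   gain_jitter=config.gain_jitter,
                                   offset_jitter=config.offset_jitter)
                base = VA_BASE[cls]
                letters = float(np.clip(round(base + rng.normal(0, config.va_sd)), 5, 95))
                labeled = rng.uniform() < config.label_fraction
                grading = GRADING_MAP[cls] if labeled else None
                images.append(img.astype(np.float32))
                mask_list.append(mask)
                class_labels.append(cls)
                va_true.append(base)
                rows.append({
                    "image_index": image_index, "patient_id": pid, "eye_id": eid,
                    "visit_index": v,
                    "visit_time": v * config.visit_interval_years,
                    "age": round(age + v * config.visit_interval_years, 2),
                    "sex": sex, "letters": letters,
                    "logmar": round((85.0 - letters) / 50.0, 4),
                    "grading_label": grading,
                })
                image_index += 1

    visits = pd.DataFrame(rows)
    truth = SyntheticGroundTruth(
        class_labels=np.array(class_labels),
        masks=np.stack(mask_list),
        conversions=pd.DataFrame(conv_rows),
        va_true=np.array(va_true),
        outcome_coeffs={"mnv": config.mnv_coeffs, "crora": config.crora_coeffs,
                        "severity": dict(SEVERITY)},
    )
    return np.stack(images), visits, truth
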