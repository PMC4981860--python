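"""Synthetic multi-protocol MR phantom studies with liver-shaped ROIs.

The generator emulates the statistical texture of axial liver MR slices —
not MR physics.  Each phantom patient gets, per protocol, a stack of
slices containing a liver-shaped region (union of two ellipses with a
concave notch, shrinking toward the stack ends) filled with a textured
parenchyma signal:

    base level + smooth bias field + (optionally skewed) noise
    + dark vessel-like random-walk tubes

Each texture dial targets one family of estimators: the noise SD drives
co-occurrence contrast (E57), the skew parameter drives asymmetry (E22),
the bias-field amplitude/scale drive the curvature descriptors (E73/E75),
and the base level drives the location statistics (E3/E6).  Vessels
provide ground truth for the inhomogeneity QC check.

Generation is a pure function of (spec, class, patient index): every
patient draws from an independent substream seeded by
``SeedSequence([seed, class_index, patient_index])``.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import skewnorm
from skimage import measure

from .imaging_io import MRSlice, MRStudy, write_series
from .protocols import Protocol
from .roi_grid import ROIContour, compute_sample_side

__all__ = [
    "TextureParams",
    "PhantomSpec",
    "generate_study",
    "generate_cohort",
    "default_two_class_spec",
    "null_spec",
]

WINDOW = (0.0, 1023.0)  # fixed intensity window of all phantom slices


@dataclass(frozen=True)
class TextureParams:
    """Texture of one protocol for one class (raw intensity units)."""

    base: float = 500.0          # parenchyma level, window units
    noise_sd: float = 25.0       # pixel noise SD -> E57
    skew: float = 0.0            # skew-normal shape of the noise -> E22
    bias_amp: float = 15.0       # smooth bias-field amplitude -> E73/E75
    bias_scale_px: float = 18.0  # bias-field correlation length, pixels
    vessel_density: float = 2.0  # expected vessels per slice
    vessel_contrast_sd: float = 6.0  # vessel darkness, in noise-SD units
    vessel_width_px: int = 2
    vessel_length_px: int = 40


@dataclass(frozen=True)
class PhantomSpec:
    """A two-class phantom cohort definition."""

    n_per_class: tuple[int, int] = (20, 20)
    class_textures: tuple[dict[Protocol, TextureParams], ...] = ()
    rows: int = 96
    cols: int = 96
    fov_mm: tuple[float, float] = (360.0, 360.0)
    thickness_mm: float = 7.0
    n_slices: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.rows < 32 or self.cols < 32 or self.n_slices < 1 \
                or self.thickness_mm <= 0:
            raise ValueError("degenerate phantom geometry")


def _default_protocols(base, noise_sd, skew, bias_amp) -> dict[Protocol, TextureParams]:
    return {
        Protocol.SSFSE_T2: TextureParams(base=base, noise_sd=noise_sd,
                                         skew=skew, bias_amp=bias_amp),
        Protocol.FAST_STIR: TextureParams(base=base * 0.8, noise_sd=noise_sd,
                                          skew=skew, bias_amp=bias_amp),
        Protocol.DYNAMIC: TextureParams(base=base * 1.1, noise_sd=noise_sd,
                                        skew=skew, bias_amp=bias_amp),
    }


def default_two_class_spec(n_per_class=(20, 20), seed=0, **geometry) -> PhantomSpec:
    """Two well-separated texture classes ("control" vs "disease").

    The disease class has a higher base level and noisier, more skewed,
    more strongly biased texture, so every scoring estimator moves in the
    direction of its published positive/negative coefficient.
    """
    control = _default_protocols(base=480.0, noise_sd=15.0, skew=0.0,
                                 bias_amp=10.0)
    disease = _default_protocols(base=600.0, noise_sd=45.0, skew=2.0,
                                 bias_amp=35.0)
    return PhantomSpec(n_per_class=tuple(n_per_class),
                       class_textures=(control, disease),
                       seed=seed, **geometry)


def null_spec(n_per_class=(20, 20), seed=0, **geometry) -> PhantomSpec:
    """Both classes share identical texture: labels carry no signal."""
    tex = _default_protocols(base=520.0, noise_sd=25.0, skew=0.5,
                             bias_amp=20.0)
    return PhantomSpec(n_per_class=tuple(n_per_class),
                       class_textures=(tex, tex), seed=seed, **geometry)


# ---------------------------------------------------------------------------
# geometry

def liver_mask(rows: int, cols: int, scale: float = 1.0) -> np.ndarray:
    """Liver-shaped binary mask: two overlapping ellipses minus a notch.

    ``scale`` in (0, 1] shrinks the shape to mimic through-slice area
    change.  Purely geometric; no anatomical atlas.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    r = (np.arange(rows) - rows * 0.48) / (rows * 0.36 * scale)
    c = (np.arange(cols) - cols * 0.42) / (cols * 0.40 * scale)
    e1 = r[:, None] ** 2 + c[None, :] ** 2 <= 1.0
    r2 = (np.arange(rows) - rows * 0.40) / (rows * 0.26 * scale)
    c2 = (np.arange(cols) - cols * 0.62) / (cols * 0.24 * scale)
    e2 = r2[:, None] ** 2 + c2[None, :] ** 2 <= 1.0
    rn = (np.arange(rows) - rows * 0.78) / (rows * 0.16)
    cn = (np.arange(cols) - cols * 0.30) / (cols * 0.18)
    notch = rn[:, None] ** 2 + cn[None, :] ** 2 <= 1.0
    return (e1 | e2) & ~notch


def mask_to_contour(mask: np.ndarray, slice_index: int,
                    step: int = 3) -> ROIContour:
    """Outline a mask as a polygon contour (sub-sampled marching squares)."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask has no contour")
    verts = max(contours, key=len)[::step]
    rows, cols = mask.shape
    verts = np.clip(verts, 0, [rows - 1, cols - 1])
    return ROIContour(slice_index=slice_index,
                      vertices=tuple(map(tuple, verts)))


# ---------------------------------------------------------------------------
# texture synthesis

def _smooth_field(rng, shape, scale_px: float) -> np.ndarray:
    """Unit-SD smooth random field (Gaussian-filtered white noise)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale_px,
                                mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _skewed_noise(rng, shape, skew: float) -> np.ndarray:
    """Zero-mean unit-SD noise with skew-normal shape parameter."""
    if skew == 0:
        return rng.standard_normal(shape)
    d = skew / np.hypot(1.0, skew)
    mu = d * np.sqrt(2.0 / np.pi)
    sd = np.sqrt(1.0 - mu ** 2)
    raw = skewnorm.rvs(skew, size=shape, random_state=rng)
    return (raw - mu) / sd


def _vessel_mask(rng, liver: np.ndarray, params: TextureParams) -> np.ndarray:
    """Dark-tube ground truth: random-walk paths dilated to tube width."""
    rows, cols = liver.shape
    mask = np.zeros_like(liver, dtype=bool)
    n_vessels = rng.poisson(params.vessel_density)
    in_r, in_c = np.nonzero(liver)
    if len(in_r) == 0:
        return mask
    for _ in range(n_vessels):
        k = rng.integers(len(in_r))
        r, c = float(in_r[k]), float(in_c[k])
        theta = rng.uniform(0, 2 * np.pi)
        for _step in range(params.vessel_length_px):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < rows and 0 <= ci < cols):
                break
            mask[ri, ci] = True
            theta += rng.normal(0.0, 0.3)
            r += np.sin(theta)
            c += np.cos(theta)
    if params.vessel_width_px > 1:
        mask = ndimage.binary_dilation(
            mask, iterations=params.vessel_width_px - 1)
    return mask & liver


def _patient_rng(spec: PhantomSpec, patient_class: int,
                 patient_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, patient_class, patient_index]))


def generate_study(spec: PhantomSpec, patient_class: int, patient_index: int
                   ) -> tuple[MRStudy, list[dict], dict]:
    """Generate one phantom patient.

    Returns (study, contour records, ground truth).  Contour records are
    sidecar-format dicts; the truth dict holds the class label, per-slice
    vessel masks per protocol, and per-grid-square vessel overlap
    fractions (grid as laid by the sampling stage).
    """
    textures = spec.class_textures[patient_class]
    rng = _patient_rng(spec, patient_class, patient_index)
    pid = f"C{patient_class}P{patient_index:03d}"
    study = MRStudy(patient_id=pid)
    contours: list[dict] = []
    truth: dict = {"patient": pid, "class": patient_class,
                   "vessel_masks": {}, "samples": []}

    side = compute_sample_side(spec.fov_mm, spec.rows, spec.cols,
                               spec.thickness_mm)
    half = (spec.n_slices - 1) / 2.0
    for proto, params in textures.items():
        slices = []
        vmasks = []
        for si in range(spec.n_slices):
            scale = 1.0 - 0.25 * (abs(si - half) / half if half > 0 else 0.0)
            liver = liver_mask(spec.rows, spec.cols, scale=scale)
            img = np.full((spec.rows, spec.cols), params.base)
            if params.bias_amp > 0:
                img += params.bias_amp * _smooth_field(
                    rng, (spec.rows, spec.cols), params.bias_scale_px)
            if params.noise_sd > 0:
                img += params.noise_sd * _skewed_noise(
                    rng, (spec.rows, spec.cols), params.skew)
            vm = _vessel_mask(rng, liver, params)
            img[vm] -= params.vessel_contrast_sd * max(params.noise_sd, 1.0)
            img[~liver] *= 0.15  # dark background outside the organ
            img = np.clip(np.round(img), WINDOW[0], WINDOW[1])
            slc = MRSlice(pixels=img, fov_mm=spec.fov_mm,
                          thickness_mm=spec.thickness_mm,
                          window_min=WINDOW[0], window_max=WINDOW[1],
                          protocol=proto, slice_index=si)
            slices.append(slc)
            vmasks.append(vm)
            contours.append({
                "patient": pid, "protocol": str(proto), "slice_index": si,
                "vertices": [list(v) for v in
                             mask_to_contour(liver, si).vertices],
            })
            for r0 in range(0, spec.rows - side + 1, side):
                for c0 in range(0, spec.cols - side + 1, side):
                    n_liv = int(liver[r0:r0 + side, c0:c0 + side].sum())
                    if n_liv == 0:
                        continue
                    n_ves = int(vm[r0:r0 + side, c0:c0 + side].sum())
                    truth["samples"].append({
                        "patient": pid, "protocol": str(proto),
                        "slice_index": si,
                        "grid_row": r0 // side, "grid_col": c0 // side,
                        "liver_fraction": n_liv / side ** 2,
                        "vessel_fraction": n_ves / side ** 2,
                    })
        study.slices[proto] = slices
        study.selected[proto] = list(range(spec.n_slices))
        truth["vessel_masks"][proto] = vmasks
    return study, contours, truth


def generate_cohort(spec: PhantomSpec, out_dir: str | os.PathLike) -> dict:
    """Write a feature-ready two-class cohort to disk.

    Produces one DICOM directory per patient, a contour sidecar
    ``contours.json``, ``labels.csv`` (patient_id, label) and
    ``truth.csv`` (per-grid-square liver/vessel overlap).  Returns a
    summary dict with the file paths and patient ids.
    """
    if len(spec.class_textures) != 2:
        raise ValueError("a cohort spec needs exactly two class definitions")
    if min(spec.n_per_class) < 1:
        raise ValueError("each class needs at least one patient")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    all_contours: list[dict] = []
    labels: list[tuple[str, int]] = []
    truth_rows: list[dict] = []
    patient_dirs: dict[str, str] = {}
    for cls, n in enumerate(spec.n_per_class):
        for idx in range(n):
            study, contours, truth = generate_study(spec, cls, idx)
            pdir = os.path.join(out_dir, study.patient_id)
            write_series(study, pdir)
            patient_dirs[study.patient_id] = pdir
            all_contours.extend(contours)
            labels.append((study.patient_id, cls))
            truth_rows.extend(truth["samples"])
    with open(os.path.join(out_dir, "contours.json"), "w") as fh:
        json.dump(all_contours, fh)
    with open(os.path.join(out_dir, "labels.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "label"])
        w.writerows(labels)
    with open(os.path.join(out_dir, "truth.csv"), "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(truth_rows[0].keys()))
        w.writeheader()
        w.writerows(truth_rows)
    return {
        "out_dir": out_dir,
        "patients": patient_dirs,
        "labels": dict(labels),
        "contours": os.path.join(out_dir, "contours.json"),
        "labels_csv": os.path.join(out_dir, "labels.csv"),
        "truth_csv": os.path.join(out_dir, "truth.csv"),
    }
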