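"""The 84-estimator registry computed on each tissue sample.

Every grid square of parenchyma is summarised by 84 numerical texture
"estimators", identified E1..E84 and organised in four families:

* E1-E30   first-order statistics of the intensity histogram,
* E31-E60  gray-level co-occurrence (Haralick-type) features,
* E61-E80  differential-geometric features of the intensity surface,
* E81-E84  spectral (2-D Fourier) descriptors.

Seven ids carry fixed, published meanings and must not move: E3 harmonic
mean, E6 mode, E22 Pearson's (second) asymmetry coefficient, E31 column
marginal mean of the multi-oriented co-occurrence matrix, E57 second-order
contrast, E73 averaged mean curvature, E75 maximum principal curvature.
The remaining ids are filler entries of this registry, chosen as standard
descriptors of each family; their definitions are frozen in the manifest
(see :func:`registry_manifest`) and versioned.

Co-occurrence conventions: intensities are quantized to ``n_levels``
equal-width bins over the context value range, pairs are accumulated
symmetrically at ``distance`` pixels along four orientations with
displacement vectors (0,+1), (+1,+1), (+1,0), (+1,-1) (0, 45, 90, 135
degrees in matrix coordinates), each orientation matrix is normalised to
probabilities, and the "multi-oriented" (pooled) matrix is their
element-wise mean.

Curvature conventions: intensity is read as a height field z = s * I with
scale ``s`` defaulting to 1/(value range) so the geometry does not depend
on the intensity window; derivatives are central differences on an
edge-replicated grid; summary statistics are taken over interior pixels
(one-pixel border excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from skimage.feature import graycomatrix

from .protocols import Protocol
from .roi_grid import TissueSample

__all__ = [
    "EstimatorContext",
    "EstimatorVector",
    "REGISTRY_VERSION",
    "ESTIMATOR_IDS",
    "NAMED_ESTIMATORS",
    "registry_manifest",
    "compute_estimators",
    "compute_sample_estimators",
    "aggregate_patient",
    "curvature_fields",
    "pooled_glcm",
]

REGISTRY_VERSION = "1.0"

#: The ids with published meanings, fixed by contract.
NAMED_ESTIMATORS = {
    "E3": "harmonic mean",
    "E6": "mode",
    "E22": "Pearson asymmetry coefficient",
    "E31": "column marginal mean of multi-oriented co-occurrence matrix",
    "E57": "second-order contrast",
    "E73": "averaged mean curvature",
    "E75": "maximum principal curvature",
}

#: Orientation displacement vectors (row, col), 0/45/90/135 degrees.
ORIENT_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))
_ORIENT_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass(frozen=True)
class EstimatorContext:
    """Shared parameters of the estimator registry.

    ``value_min``/``value_max`` define the fixed range over which
    intensities are quantized (normally the slice window, or [0, 1] when
    the pipeline feeds window-normalised pixels).  ``curvature_scale``
    defaults to 1/(value range).
    """

    value_min: float
    value_max: float
    n_levels: int = 16
    distance: int = 1
    curvature_scale: float | None = None
    harmonic_shift: bool = True

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("n_levels must be at least 2")
        if not self.value_min <= self.value_max:
            raise ValueError("value_min must not exceed value_max")

    @property
    def value_range(self) -> float:
        return self.value_max - self.value_min

    @property
    def quant_step(self) -> float:
        r = self.value_range
        return r / self.n_levels if r > 0 else 1.0

    @property
    def scale(self) -> float:
        if self.curvature_scale is not None:
            return self.curvature_scale
        r = self.value_range
        return 1.0 / r if r > 0 else 1.0

    @classmethod
    def for_slice(cls, slc, normalized: bool = True, **kw) -> "EstimatorContext":
        """Context for samples cut from a slice.

        With ``normalized=True`` (the pipeline default) pixels are expected
        on the [0, 1] window-normalised scale.
        """
        if normalized:
            return cls(value_min=0.0, value_max=1.0, **kw)
        return cls(value_min=slc.window_min, value_max=slc.window_max, **kw)


class EstimatorError(ValueError):
    """An estimator is undefined on this sample; carries the reason."""


@dataclass
class EstimatorVector:
    """All 84 estimator values for one sample or one patient aggregate.

    Non-finite or undefined entries live in ``missing`` (id -> reason);
    ``values`` holds the rest.  Together they always cover the 84 ids.
    """

    values: dict[str, float]
    missing: dict[str, str] = field(default_factory=dict)
    sample_ref: tuple[int, int, int] | str = "AGGREGATE"
    protocol: Protocol | None = None
    n_samples: int = 1

    def __post_init__(self):
        covered = set(self.values) | set(self.missing)
        if covered != set(ESTIMATOR_IDS):
            raise ValueError("an estimator vector must cover exactly E1..E84")

    def __getitem__(self, key: str) -> float:
        if key in self.missing:
            raise KeyError(f"{key} is missing: {self.missing[key]}")
        return self.values[key]

    def get(self, key: str, default=None):
        return self.values.get(key, default)


# ---------------------------------------------------------------------------
# per-sample workspace: shared, lazily computed intermediates

class _Workspace:
    def __init__(self, pixels: np.ndarray, ctx: EstimatorContext):
        self.pix = np.asarray(pixels, dtype=np.float64)
        if self.pix.ndim != 2 or self.pix.size == 0:
            raise ValueError("a sample must be a non-empty 2-D matrix")
        self.ctx = ctx
        self.x = self.pix.ravel()
        self.n = self.x.size

    @cached_property
    def mean(self):
        return float(self.x.mean())

    @cached_property
    def sd(self):
        return float(self.x.std())

    @cached_property
    def median(self):
        return float(np.median(self.x))

    def percentile(self, q):
        return float(np.percentile(self.x, q))

    @cached_property
    def levels(self):
        """Quantized gray levels, shape of the sample, ints in [0, L)."""
        ctx = self.ctx
        r = ctx.value_range
        if r == 0:
            return np.zeros_like(self.pix, dtype=np.uint8)
        lv = np.floor((self.pix - ctx.value_min) / r * ctx.n_levels)
        return np.clip(lv, 0, ctx.n_levels - 1).astype(np.uint8)

    @cached_property
    def level_counts(self):
        return np.bincount(self.levels.ravel(),
                           minlength=self.ctx.n_levels)

    @cached_property
    def glcm_per_orientation(self):
        """Normalised symmetric co-occurrence matrix per orientation."""
        ctx = self.ctx
        if ctx.distance >= min(self.pix.shape):
            raise EstimatorError("sample smaller than the GLCM offset")
        mats = graycomatrix(self.levels, distances=[ctx.distance],
                            angles=list(_ORIENT_ANGLES),
                            levels=ctx.n_levels, symmetric=True,
                            normed=True)
        return [mats[:, :, 0, a] for a in range(len(_ORIENT_ANGLES))]

    @cached_property
    def glcm_pooled(self):
        return np.mean(self.glcm_per_orientation, axis=0)

    @cached_property
    def curvature(self):
        if self.pix.shape[0] < 3 or self.pix.shape[1] < 3:
            raise EstimatorError("sample too small for curvature (needs 3x3)")
        return curvature_fields(self.pix, scale=self.ctx.scale)

    @cached_property
    def spectrum(self):
        """Non-DC power spectrum values and their radial frequencies."""
        F = np.fft.fft2(self.pix)
        power = np.abs(F) ** 2
        fr = np.fft.fftfreq(self.pix.shape[0])
        fc = np.fft.fftfreq(self.pix.shape[1])
        rad = np.hypot(fr[:, None], fc[None, :])
        keep = np.ones_like(power, dtype=bool)
        keep[0, 0] = False  # DC carries only the mean level
        return power[keep], rad[keep]


def _central_diff(arr: np.ndarray, axis: int) -> np.ndarray:
    """Central difference with one-pixel edge replication."""
    pad = [(0, 0), (0, 0)]
    pad[axis] = (1, 1)
    a = np.pad(arr, pad, mode="edge")
    if axis == 0:
        return (a[2:, :] - a[:-2, :]) / 2.0
    return (a[:, 2:] - a[:, :-2]) / 2.0


def curvature_fields(pixels: np.ndarray, scale: float = 1.0) -> dict[str, np.ndarray]:
    """Per-pixel surface derivatives and curvatures of z = scale * I.

    Returns fx, fy, fxx, fyy, fxy, mean curvature H, Gaussian curvature K,
    and principal curvatures k1 >= k2, all on the full pixel grid.
    """
    f = scale * np.asarray(pixels, dtype=np.float64)
    fy = _central_diff(f, 0)   # along rows
    fx = _central_diff(f, 1)   # along columns
    fxx = _central_diff(fx, 1)
    fyy = _central_diff(fy, 0)
    fxy = _central_diff(fx, 0)
    g = 1.0 + fx ** 2 + fy ** 2
    H = ((1.0 + fx ** 2) * fyy - 2.0 * fx * fy * fxy
         + (1.0 + fy ** 2) * fxx) / (2.0 * g ** 1.5)
    K = (fxx * fyy - fxy ** 2) / g ** 2
    disc = np.sqrt(np.maximum(H ** 2 - K, 0.0))
    return {"fx": fx, "fy": fy, "fxx": fxx, "fyy": fyy, "fxy": fxy,
            "H": H, "K": K, "k1": H + disc, "k2": H - disc}


def pooled_glcm(pixels: np.ndarray, ctx: EstimatorContext) -> np.ndarray:
    """The multi-oriented (pooled) co-occurrence probability matrix."""
    return _Workspace(np.asarray(pixels), ctx).glcm_pooled


# ---------------------------------------------------------------------------
# first-order family

def _e3_harmonic(ws: _Workspace):
    x = ws.x
    if x.min() <= 0:
        if not ws.ctx.harmonic_shift:
            raise EstimatorError("non-positive pixels; harmonic mean undefined")
        x = x + ws.ctx.quant_step
        if x.min() <= 0:
            raise EstimatorError("non-positive pixels after guard shift")
    return ws.n / float(np.sum(1.0 / x))


def _e4_geometric(ws: _Workspace):
    x = ws.x
    if x.min() <= 0:
        if not ws.ctx.harmonic_shift:
            raise EstimatorError("non-positive pixels; geometric mean undefined")
        x = x + ws.ctx.quant_step
        if x.min() <= 0:
            raise EstimatorError("non-positive pixels after guard shift")
    return float(np.exp(np.mean(np.log(x))))


def _e6_mode(ws: _Workspace):
    # modal quantization bin, ties toward the smallest level; reported as
    # the bin's lower edge on the input intensity scale
    lvl = int(np.argmax(ws.level_counts))
    if ws.ctx.value_range == 0:
        return float(ws.ctx.value_min)
    return ws.ctx.value_min + lvl * ws.ctx.value_range / ws.ctx.n_levels


def _e18_cv(ws: _Workspace):
    if ws.mean == 0:
        raise EstimatorError("zero mean; coefficient of variation undefined")
    return ws.sd / ws.mean


def _e19_skew(ws: _Workspace):
    if ws.sd == 0:
        return 0.0
    return float(np.mean((ws.x - ws.mean) ** 3)) / ws.sd ** 3


def _e20_kurt(ws: _Workspace):
    if ws.sd == 0:
        return 0.0
    return float(np.mean((ws.x - ws.mean) ** 4)) / ws.sd ** 4 - 3.0


def _e21_bowley(ws: _Workspace):
    q1, q2, q3 = (ws.percentile(q) for q in (25, 50, 75))
    if q3 == q1:
        return 0.0
    return (q3 + q1 - 2.0 * q2) / (q3 - q1)


def _e22_pearson(ws: _Workspace):
    # Pearson's second skewness coefficient, population SD
    if ws.sd == 0:
        return 0.0
    return 3.0 * (ws.mean - ws.median) / ws.sd


def _hist_probs(ws: _Workspace):
    c = ws.level_counts
    return c[c > 0] / ws.n


def _e23_hist_entropy(ws: _Workspace):
    p = _hist_probs(ws)
    return float(-(p * np.log(p)).sum())


def _e27_trimmed(ws: _Workspace):
    # 10 % trimmed from each tail (floor rule)
    k = int(math.floor(0.1 * ws.n))
    s = np.sort(ws.x)
    return float(s[k:ws.n - k].mean()) if ws.n - 2 * k > 0 else ws.median


# ---------------------------------------------------------------------------
# co-occurrence family

def _glcm_stats(P: np.ndarray):
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)
    pr = P.sum(axis=1)          # row marginal
    pc = P.sum(axis=0)          # column marginal
    mu_r = float(i @ pr)
    mu_c = float(i @ pc)
    return i, pr, pc, mu_r, mu_c


def _glcm_contrast(P):
    i, _, _, _, _ = _glcm_stats(P)
    return float(((i[:, None] - i[None, :]) ** 2 * P).sum())


def _glcm_energy(P):
    return float((P ** 2).sum())


def _glcm_entropy(P):
    p = P[P > 0]
    return float(-(p * np.log(p)).sum())


def _glcm_correlation(P):
    i, pr, pc, mu_r, mu_c = _glcm_stats(P)
    var_r = float(((i - mu_r) ** 2) @ pr)
    var_c = float(((i - mu_c) ** 2) @ pc)
    if var_r == 0 or var_c == 0:
        return 1.0  # degenerate (constant) texture: perfectly correlated
    cov = float(((i[:, None] - mu_r) * (i[None, :] - mu_c) * P).sum())
    return cov / math.sqrt(var_r * var_c)


def _glcm_homogeneity(P):
    i, _, _, _, _ = _glcm_stats(P)
    return float((P / (1.0 + (i[:, None] - i[None, :]) ** 2)).sum())


def _glcm_dissimilarity(P):
    i, _, _, _, _ = _glcm_stats(P)
    return float((np.abs(i[:, None] - i[None, :]) * P).sum())


def _glcm_cluster(P, power):
    i, _, _, mu_r, mu_c = _glcm_stats(P)
    t = i[:, None] + i[None, :] - mu_r - mu_c
    return float((t ** power * P).sum())


def _sum_dist(P):
    L = P.shape[0]
    p = np.zeros(2 * L - 1)
    for i in range(L):
        for j in range(L):
            p[i + j] += P[i, j]
    return p


def _diff_dist(P):
    L = P.shape[0]
    p = np.zeros(L)
    for i in range(L):
        for j in range(L):
            p[abs(i - j)] += P[i, j]
    return p


def _dist_mean(p):
    k = np.arange(p.size, dtype=np.float64)
    return float(k @ p)


def _dist_var(p):
    m = _dist_mean(p)
    k = np.arange(p.size, dtype=np.float64)
    return float(((k - m) ** 2) @ p)


def _dist_entropy(p):
    q = p[p > 0]
    return float(-(q * np.log(q)).sum())


# ---------------------------------------------------------------------------
# geometric family helpers (interior pixels only)

def _interior(a: np.ndarray) -> np.ndarray:
    return a[1:-1, 1:-1].ravel()


def _curv(ws: _Workspace, key: str) -> np.ndarray:
    return _interior(ws.curvature[key])


def _grad_mag(ws: _Workspace) -> np.ndarray:
    c = ws.curvature
    return np.hypot(_interior(c["fx"]), _interior(c["fy"]))


def _laplacian(ws: _Workspace) -> np.ndarray:
    c = ws.curvature
    return _interior(c["fxx"]) + _interior(c["fyy"])


# ---------------------------------------------------------------------------
# spectral family

_BAND_EDGES = (1.0 / 6.0, 1.0 / 3.0)  # normalised radial frequency


def _band_fraction(ws: _Workspace, band: int):
    power, rad = ws.spectrum
    total = power.sum()
    if total == 0:
        return 0.0
    lo_edge, hi_edge = _BAND_EDGES
    if band == 0:
        sel = rad < lo_edge
    elif band == 1:
        sel = (rad >= lo_edge) & (rad < hi_edge)
    else:
        sel = rad >= hi_edge
    return float(power[sel].sum() / total)


def _spectral_entropy(ws: _Workspace):
    power, _ = ws.spectrum
    total = power.sum()
    if total == 0:
        return 0.0
    p = power[power > 0] / total
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# the registry

def _build_registry():
    R = []

    def add(eid, name, family, fn):
        R.append((eid, name, family, fn))

    F = "first_order"
    add("E1", "mean", F, lambda w: w.mean)
    add("E2", "standard deviation (population)", F, lambda w: w.sd)
    add("E3", "harmonic mean", F, _e3_harmonic)
    add("E4", "geometric mean", F, _e4_geometric)
    add("E5", "median", F, lambda w: w.median)
    add("E6", "mode", F, _e6_mode)
    add("E7", "variance (population)", F, lambda w: w.sd ** 2)
    add("E8", "minimum", F, lambda w: float(w.x.min()))
    add("E9", "maximum", F, lambda w: float(w.x.max()))
    add("E10", "range", F, lambda w: float(w.x.max() - w.x.min()))
    add("E11", "5th percentile", F, lambda w: w.percentile(5))
    add("E12", "10th percentile", F, lambda w: w.percentile(10))
    add("E13", "25th percentile", F, lambda w: w.percentile(25))
    add("E14", "75th percentile", F, lambda w: w.percentile(75))
    add("E15", "90th percentile", F, lambda w: w.percentile(90))
    add("E16", "95th percentile", F, lambda w: w.percentile(95))
    add("E17", "interquartile range", F,
        lambda w: w.percentile(75) - w.percentile(25))
    add("E18", "coefficient of variation", F, _e18_cv)
    add("E19", "skewness (moment)", F, _e19_skew)
    add("E20", "excess kurtosis", F, _e20_kurt)
    add("E21", "Bowley quartile skewness", F, _e21_bowley)
    add("E22", "Pearson asymmetry coefficient", F, _e22_pearson)
    add("E23", "histogram entropy", F, _e23_hist_entropy)
    add("E24", "histogram energy", F,
        lambda w: float((_hist_probs(w) ** 2).sum()))
    add("E25", "root mean square", F,
        lambda w: float(np.sqrt(np.mean(w.x ** 2))))
    add("E26", "mean absolute deviation", F,
        lambda w: float(np.mean(np.abs(w.x - w.mean))))
    add("E27", "trimmed mean (10%)", F, _e27_trimmed)
    add("E28", "median absolute deviation", F,
        lambda w: float(np.median(np.abs(w.x - w.median))))
    add("E29", "midhinge", F,
        lambda w: 0.5 * (w.percentile(25) + w.percentile(75)))
    add("E30", "midrange", F,
        lambda w: 0.5 * float(w.x.min() + w.x.max()))

    G = "cooccurrence"
    add("E31", "column marginal mean (pooled)", G,
        lambda w: _glcm_stats(w.glcm_pooled)[4])
    add("E32", "row marginal mean (pooled)", G,
        lambda w: _glcm_stats(w.glcm_pooled)[3])

    def _marg_var(P, axis):
        i, pr, pc, mu_r, mu_c = _glcm_stats(P)
        p, mu = (pc, mu_c) if axis == 1 else (pr, mu_r)
        return float(((i - mu) ** 2) @ p)

    add("E33", "column marginal variance (pooled)", G,
        lambda w: _marg_var(w.glcm_pooled, 1))
    add("E34", "row marginal variance (pooled)", G,
        lambda w: _marg_var(w.glcm_pooled, 0))
    add("E35", "angular second moment (pooled)", G,
        lambda w: _glcm_energy(w.glcm_pooled))
    add("E36", "co-occurrence entropy (pooled)", G,
        lambda w: _glcm_entropy(w.glcm_pooled))
    add("E37", "co-occurrence correlation (pooled)", G,
        lambda w: _glcm_correlation(w.glcm_pooled))
    add("E38", "homogeneity / IDM (pooled)", G,
        lambda w: _glcm_homogeneity(w.glcm_pooled))
    add("E39", "dissimilarity (pooled)", G,
        lambda w: _glcm_dissimilarity(w.glcm_pooled))
    add("E40", "cluster shade (pooled)", G,
        lambda w: _glcm_cluster(w.glcm_pooled, 3))
    add("E41", "cluster prominence (pooled)", G,
        lambda w: _glcm_cluster(w.glcm_pooled, 4))
    add("E42", "maximum probability (pooled)", G,
        lambda w: float(w.glcm_pooled.max()))
    add("E43", "sum average (pooled)", G,
        lambda w: _dist_mean(_sum_dist(w.glcm_pooled)))
    add("E44", "sum variance (pooled)", G,
        lambda w: _dist_var(_sum_dist(w.glcm_pooled)))
    add("E45", "sum entropy (pooled)", G,
        lambda w: _dist_entropy(_sum_dist(w.glcm_pooled)))
    add("E46", "difference average (pooled)", G,
        lambda w: _dist_mean(_diff_dist(w.glcm_pooled)))
    add("E47", "difference variance (pooled)", G,
        lambda w: _dist_var(_diff_dist(w.glcm_pooled)))
    add("E48", "difference entropy (pooled)", G,
        lambda w: _dist_entropy(_diff_dist(w.glcm_pooled)))

    def _autocorr(P):
        i, _, _, _, _ = _glcm_stats(P)
        return float((i[:, None] * i[None, :] * P).sum())

    add("E49", "autocorrelation (pooled)", G,
        lambda w: _autocorr(w.glcm_pooled))

    def _inv_diff(P):
        i, _, _, _, _ = _glcm_stats(P)
        return float((P / (1.0 + np.abs(i[:, None] - i[None, :]))).sum())

    add("E50", "inverse difference (pooled)", G,
        lambda w: _inv_diff(w.glcm_pooled))
    add("E51", "diagonal probability (pooled)", G,
        lambda w: float(np.trace(w.glcm_pooled)))
    add("E52", "contrast, 0 deg", G,
        lambda w: _glcm_contrast(w.glcm_per_orientation[0]))
    add("E53", "contrast, 45 deg", G,
        lambda w: _glcm_contrast(w.glcm_per_orientation[1]))
    add("E54", "contrast, 90 deg", G,
        lambda w: _glcm_contrast(w.glcm_per_orientation[2]))
    add("E55", "contrast, 135 deg", G,
        lambda w: _glcm_contrast(w.glcm_per_orientation[3]))
    add("E56", "angular second moment, 0 deg", G,
        lambda w: _glcm_energy(w.glcm_per_orientation[0]))
    add("E57", "second-order contrast (pooled)", G,
        lambda w: _glcm_contrast(w.glcm_pooled))
    add("E58", "co-occurrence entropy, 0 deg", G,
        lambda w: _glcm_entropy(w.glcm_per_orientation[0]))
    add("E59", "homogeneity / IDM, 0 deg", G,
        lambda w: _glcm_homogeneity(w.glcm_per_orientation[0]))
    add("E60", "dissimilarity, 0 deg", G,
        lambda w: _glcm_dissimilarity(w.glcm_per_orientation[0]))

    C = "geometric"
    add("E61", "gradient magnitude mean", C, lambda w: float(_grad_mag(w).mean()))
    add("E62", "gradient magnitude SD", C, lambda w: float(_grad_mag(w).std()))
    add("E63", "gradient magnitude maximum", C, lambda w: float(_grad_mag(w).max()))
    add("E64", "gradient magnitude median", C,
        lambda w: float(np.median(_grad_mag(w))))
    add("E65", "mean absolute Laplacian", C,
        lambda w: float(np.abs(_laplacian(w)).mean()))
    add("E66", "Laplacian SD", C, lambda w: float(_laplacian(w).std()))
    add("E67", "Gaussian curvature mean", C, lambda w: float(_curv(w, "K").mean()))
    add("E68", "Gaussian curvature SD", C, lambda w: float(_curv(w, "K").std()))
    add("E69", "Gaussian curvature maximum", C, lambda w: float(_curv(w, "K").max()))
    add("E70", "Gaussian curvature minimum", C, lambda w: float(_curv(w, "K").min()))
    add("E71", "mean curvature SD", C, lambda w: float(_curv(w, "H").std()))
    add("E72", "mean absolute mean curvature", C,
        lambda w: float(np.abs(_curv(w, "H")).mean()))
    add("E73", "averaged mean curvature", C, lambda w: float(_curv(w, "H").mean()))
    add("E74", "mean curvature maximum", C, lambda w: float(_curv(w, "H").max()))
    add("E75", "maximum principal curvature", C,
        lambda w: float(_curv(w, "k1").max()))
    add("E76", "minimum principal curvature", C,
        lambda w: float(_curv(w, "k2").min()))
    add("E77", "first principal curvature mean", C,
        lambda w: float(_curv(w, "k1").mean()))
    add("E78", "second principal curvature mean", C,
        lambda w: float(_curv(w, "k2").mean()))
    add("E79", "surface area element mean", C,
        lambda w: float(np.sqrt(1.0 + _grad_mag(w) ** 2).mean()))
    add("E80", "elliptic pixel fraction (K > 0)", C,
        lambda w: float((_curv(w, "K") > 0).mean()))

    S = "spectral"
    add("E81", "low-band power fraction", S, lambda w: _band_fraction(w, 0))
    add("E82", "mid-band power fraction", S, lambda w: _band_fraction(w, 1))
    add("E83", "high-band power fraction", S, lambda w: _band_fraction(w, 2))
    add("E84", "spectral entropy", S, _spectral_entropy)
    return R


_REGISTRY = _build_registry()
ESTIMATOR_IDS = tuple(eid for eid, _, _, _ in _REGISTRY)
assert len(ESTIMATOR_IDS) == 84 and len(set(ESTIMATOR_IDS)) == 84


def registry_manifest() -> dict:
    """The frozen registry layout: id, name, family, parameters, version."""
    return {
        "version": REGISTRY_VERSION,
        "parameters": {
            "n_levels": 16, "distance": 1,
            "orientations_deg": [0, 45, 90, 135],
            "symmetric": True, "pooling": "mean",
            "band_edges": list(_BAND_EDGES),
        },
        "estimators": [
            {"id": eid, "name": name, "family": fam,
             "published": eid in NAMED_ESTIMATORS}
            for eid, name, fam, _ in _REGISTRY
        ],
    }


def compute_estimators(pixels: np.ndarray, ctx: EstimatorContext,
                       sample_ref=( -1, -1, -1),
                       protocol: Protocol | None = None) -> EstimatorVector:
    """Evaluate all 84 registry entries on one pixel matrix.

    Individual estimator failures (undefined values, too-small samples)
    never abort the vector; they are recorded in ``missing`` with a reason.
    """
    ws = _Workspace(pixels, ctx)
    values: dict[str, float] = {}
    missing: dict[str, str] = {}
    for eid, _name, _fam, fn in _REGISTRY:
        try:
            v = float(fn(ws))
        except EstimatorError as exc:
            missing[eid] = str(exc)
            continue
        if not math.isfinite(v):
            missing[eid] = "non-finite value"
        else:
            values[eid] = v
    return EstimatorVector(values=values, missing=missing,
                           sample_ref=sample_ref, protocol=protocol)


def compute_sample_estimators(sample: TissueSample,
                              ctx: EstimatorContext,
                              protocol: Protocol | None = None) -> EstimatorVector:
    """Registry evaluation for a QC-passing tissue sample."""
    if not sample.qc_pass:
        raise ValueError("estimators are computed on QC-passing samples only")
    return compute_estimators(
        sample.pixels, ctx,
        sample_ref=(sample.slice_index, sample.grid_row, sample.grid_col),
        protocol=protocol)


def aggregate_patient(vectors: list[EstimatorVector],
                      protocol: Protocol) -> EstimatorVector:
    """Per-estimator arithmetic mean over a patient's passing samples.

    Missing values are excluded pairwise; an estimator missing from every
    sample stays missing in the aggregate.
    """
    if not vectors:
        raise ValueError(f"no QC-passing samples for protocol {protocol}")
    values: dict[str, float] = {}
    missing: dict[str, str] = {}
    for eid in ESTIMATOR_IDS:
        vals = [v.values[eid] for v in vectors if eid in v.values]
        if vals:
            values[eid] = float(np.mean(vals))
        else:
            missing[eid] = "missing in all samples"
    return EstimatorVector(values=values, missing=missing,
                           sample_ref="AGGREGATE", protocol=protocol,
                           n_samples=len(vectors))
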