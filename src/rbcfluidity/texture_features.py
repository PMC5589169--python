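"""Per-channel texture descriptors feeding the decision-support system.

Three descriptor families are concatenated per channel image:

* first-order statistics of the intensity distribution (moments plus
  gray-histogram energy/entropy);
* second-order gray-level co-occurrence (GLCM) measures — contrast,
  correlation, energy, homogeneity, entropy — averaged over a set of pixel
  offsets, with pair counting optionally restricted to a mask;
* rotation-invariant co-occurrence local binary patterns (RICLBP): each
  pixel gets an 8-bit LBP code canonicalised to its minimum over circular
  bit-shifts, and the descriptor is the normalized joint histogram of
  unordered code pairs at a fixed displacement along four directions.

The LBP ring uses the 8 square-grid neighbours in circular order, so a 90°
image rotation cyclically shifts each code by two bits and the pooled pair
histogram is *exactly* invariant to 90°/180°/270° rotations.  Ties compare
with ``>=`` so codes are reproducible bit-exactly and invariant to adding a
constant to the image.

The two channels of an image pair are kept separate: they feed two parallel
classification pipelines that are only fused at the decision level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
    ShapeMismatchError,
)
from .gp_imaging import ChannelImage

FIRST_ORDER_NAMES = (
    "fo_mean",
    "fo_variance",
    "fo_skewness",
    "fo_kurtosis",
    "fo_energy",
    "fo_entropy",
)
GLCM_NAMES = (
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
    "glcm_entropy",
)


@dataclass(frozen=True)
class FeatureVector:
    """Named real-valued descriptors for one image/channel."""

    names: tuple[str, ...]
    values: np.ndarray
    channel: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != values.size:
            raise ShapeMismatchError("feature names and values lengths differ")
        if not np.all(np.isfinite(values)):
            raise ParameterError("feature values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))


@dataclass(frozen=True)
class GLCMConfig:
    n_levels: int = 32
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ConfigurationError("n_levels must be >= 2")
        if not self.offsets:
            raise ConfigurationError("at least one offset is required")


@dataclass(frozen=True)
class RICLBPConfig:
    radius_px: int = 1
    n_points: int = 8
    pair_displacement_px: int = 2

    def __post_init__(self) -> None:
        if self.radius_px < 1 or self.pair_displacement_px < 1:
            raise ConfigurationError("radius and displacement must be >= 1")
        if self.n_points != 8:
            raise ConfigurationError(
                "only the 8-neighbour ring is supported (90-degree rotation group)"
            )


# --------------------------------------------------------------------------
# First-order statistics
# --------------------------------------------------------------------------

def first_order_features(
    image: np.ndarray, mask: np.ndarray | None = None, n_bins: int = 64
) -> FeatureVector:
    """Mean, variance, skewness, kurtosis, histogram energy and entropy.

    Moments are population moments over the masked pixels; skewness and
    excess kurtosis of a constant region are defined as 0.  Energy and
    entropy (bits) come from an ``n_bins`` equal-width gray histogram over
    the masked intensity range; a constant image has energy 1 and entropy 0.
    """
    image = np.asarray(image, dtype=np.float64)
    vals = image[np.asarray(mask, dtype=bool)] if mask is not None else image.ravel()
    if vals.size == 0:
        raise DegenerateInputError("empty mask for first-order features")
    mean = vals.mean()
    centered = vals - mean
    var = float(np.mean(centered**2))
    scale = max(1.0, mean * mean)
    if var <= 1e-15 * scale:
        skew = kurt = 0.0
        var = float(var)
    else:
        m3 = np.mean(centered**3)
        m4 = np.mean(centered**4)
        skew = float(m3 / var**1.5)
        kurt = float(m4 / var**2 - 3.0)
    if np.ptp(vals) == 0:
        p = np.array([1.0])
    else:
        counts, _ = np.histogram(vals, bins=n_bins)
        p = counts[counts > 0] / vals.size
    energy = float(np.sum(p**2))
    entropy = float(-np.sum(p * np.log2(p)))
    return FeatureVector(
        FIRST_ORDER_NAMES, [float(mean), var, skew, kurt, energy, entropy]
    )


# --------------------------------------------------------------------------
# Gray-level co-occurrence
# --------------------------------------------------------------------------

def _quantize(image: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.intp)
    q = np.floor((image - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(q, 0, n_levels - 1)


def _offset_pairs(arr: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Views of (pixel, pixel+offset) pairs fully inside the raster."""
    h, w = arr.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    a = arr[r0:r1, c0:c1]
    b = arr[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a, b


def glcm_matrix(
    image: np.ndarray,
    mask: np.ndarray | None,
    cfg: GLCMConfig,
    offset: tuple[int, int],
) -> np.ndarray:
    """Co-occurrence matrix for one offset, restricted to in-mask pixel pairs."""
    image = np.asarray(image, dtype=np.float64)
    mask = (
        np.ones(image.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    )
    q = _quantize(image, mask, cfg.n_levels)
    a, b = _offset_pairs(q, *offset)
    ma, mb = _offset_pairs(mask, *offset)
    keep = ma & mb
    counts = np.bincount(
        a[keep] * cfg.n_levels + b[keep], minlength=cfg.n_levels**2
    ).reshape(cfg.n_levels, cfg.n_levels)
    mat = counts.astype(np.float64)
    if cfg.symmetric:
        mat = mat + mat.T
    if cfg.normalize and mat.sum() > 0:
        mat = mat / mat.sum()
    return mat


def _glcm_props(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float(np.sum(p * (i - j) ** 2))
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(pi * np.arange(n)))
    mu_j = float(np.sum(pj * np.arange(n)))
    var_i = float(np.sum(pi * (np.arange(n) - mu_i) ** 2))
    var_j = float(np.sum(pj * (np.arange(n) - mu_j) ** 2))
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0  # degenerate single-level matrix: perfectly correlated
    else:
        correlation = float(
            np.sum(p * (i - mu_i) * (j - mu_j)) / np.sqrt(var_i * var_j)
        )
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_energy": energy,
        "glcm_homogeneity": homogeneity,
        "glcm_entropy": entropy,
    }


def glcm_features(
    image: np.ndarray, mask: np.ndarray | None = None, cfg: GLCMConfig = GLCMConfig()
) -> FeatureVector:
    """GLCM contrast/correlation/energy/homogeneity/entropy, offset-averaged."""
    per_offset = []
    for offset in cfg.offsets:
        mat = glcm_matrix(image, mask, cfg, offset)
        if mat.sum() == 0:
            continue
        per_offset.append(_glcm_props(mat))
    if not per_offset:
        raise DegenerateInputError("no valid pixel pairs for any GLCM offset")
    values = [float(np.mean([d[name] for d in per_offset])) for name in GLCM_NAMES]
    return FeatureVector(GLCM_NAMES, values)


# --------------------------------------------------------------------------
# Rotation-invariant co-occurrence LBP
# --------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _ri_lut() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(code -> shift-minimal representative, sorted representatives,
    code -> dense representative index) for 8-bit codes."""
    lut = np.empty(256, dtype=np.intp)
    for c in range(256):
        lut[c] = min(((c << s) | (c >> (8 - s))) & 0xFF for s in range(8))
    reps = np.unique(lut)
    index = np.full(256, -1, dtype=np.intp)
    index[reps] = np.arange(reps.size)
    return lut, reps, index


def lbp_codes(image: np.ndarray, cfg: RICLBPConfig = RICLBPConfig()) -> np.ndarray:
    """Rotation-invariant LBP code per interior pixel.

    Each of the 8 ring neighbours (N, NE, E, SE, S, SW, W, NW at the
    configured radius) contributes one bit (neighbour >= center), and the
    8-bit code is mapped to its minimum over circular bit-shifts.  The output
    raster is smaller than the input by the radius on every side.
    """
    image = np.asarray(image, dtype=np.float64)
    r = cfg.radius_px
    if image.ndim != 2 or min(image.shape) <= 2 * r:
        raise ShapeMismatchError("image too small for the requested LBP radius")
    center = image[r:-r, r:-r]
    ring = (
        (-r, 0), (-r, r), (0, r), (r, r), (r, 0), (r, -r), (0, -r), (-r, -r)
    )
    code = np.zeros(center.shape, dtype=np.intp)
    h, w = image.shape
    for k, (dr, dc) in enumerate(ring):
        neighbour = image[r + dr : h - r + dr, r + dc : w - r + dc]
        code |= (neighbour >= center).astype(np.intp) << k
    lut, _, _ = _ri_lut()
    return lut[code]


def riclbp_names() -> tuple[str, ...]:
    _, reps, _ = _ri_lut()
    iu, ju = np.triu_indices(reps.size)
    return tuple(f"riclbp_{reps[i]}_{reps[j]}" for i, j in zip(iu, ju))


def riclbp_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    cfg: RICLBPConfig = RICLBPConfig(),
) -> FeatureVector:
    """Normalized joint histogram of unordered RICLBP code pairs.

    Pairs are taken at the configured displacement along the four directions
    0°, 45°, 90° and 135°; each unordered, rotation-equivalent pair class is
    one bin.  When a mask is given, only pairs with both pixels inside the
    mask (after cropping the LBP margin) are counted.
    """
    codes = lbp_codes(image, cfg)
    _, reps, index = _ri_lut()
    idx = index[codes]
    n = reps.size
    r = cfg.radius_px
    if mask is None:
        interior_mask = np.ones(codes.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != np.asarray(image).shape:
            raise ShapeMismatchError("mask shape differs from image shape")
        interior_mask = mask[r:-r, r:-r]
    d = cfg.pair_displacement_px
    counts = np.zeros(n * n, dtype=np.int64)
    for dr, dc in ((0, d), (d, 0), (d, d), (d, -d)):
        a, b = _offset_pairs(idx, dr, dc)
        ma, mb = _offset_pairs(interior_mask, dr, dc)
        keep = ma & mb
        if not keep.any():
            continue
        lo = np.minimum(a[keep], b[keep])
        hi = np.maximum(a[keep], b[keep])
        counts += np.bincount(lo * n + hi, minlength=n * n)
    total = counts.sum()
    if total == 0:
        raise DegenerateInputError("no valid code pairs for RICLBP")
    iu, ju = np.triu_indices(n)
    hist = counts.reshape(n, n)[iu, ju] / total
    return FeatureVector(riclbp_names(), hist)


# --------------------------------------------------------------------------
# Per-image-pair assembly
# --------------------------------------------------------------------------

def extract_features(
    blue: ChannelImage,
    green: ChannelImage,
    mask: np.ndarray | None = None,
    n_fo_bins: int = 64,
    glcm_cfg: GLCMConfig = GLCMConfig(),
    riclbp_cfg: RICLBPConfig = RICLBPConfig(),
) -> tuple[FeatureVector, FeatureVector]:
    """Concatenated first-order + GLCM + RICLBP descriptors per channel.

    The two channel vectors stay separate — they feed parallel pipelines.
    ``mask=None`` computes features on the full frame (default); passing the
    cell mask restricts every family to in-mask pixels/pairs.
    """
    if blue.shape != green.shape:
        raise ShapeMismatchError("channel shapes differ")
    out = []
    for img in (blue, green):
        fo = first_order_features(img.pixels, mask, n_fo_bins)
        gl = glcm_features(img.pixels, mask, glcm_cfg)
        ri = riclbp_features(img.pixels, mask, riclbp_cfg)
        out.append(
            FeatureVector(
                fo.names + gl.names + ri.names,
                np.concatenate([fo.values, gl.values, ri.values]),
                channel=img.band,
            )
        )
    return out[0], out[1]


def feature_table(
    cohort,
    mask_mode: str = "full",
    n_fo_bins: int = 64,
    glcm_cfg: GLCMConfig = GLCMConfig(),
    riclbp_cfg: RICLBPConfig = RICLBPConfig(),
    min_area_px: int = 100,
):
    """Feature DataFrame for a whole cohort: one row per (patient, z, channel).

    ``mask_mode`` is ``"full"`` (whole frame) or ``"cell"`` (restrict to the
    segmented cell mask).
    """
    import pandas as pd

    from .gp_imaging import segment_cells

    if mask_mode not in ("full", "cell"):
        raise ConfigurationError("mask_mode must be 'full' or 'cell'")
    rows = []
    names: tuple[str, ...] | None = None
    for patient in cohort.patients:
        for z, (blue, green) in enumerate(patient.stack):
            mask = (
                segment_cells(blue, green, min_area_px) if mask_mode == "cell" else None
            )
            fv_blue, fv_green = extract_features(
                blue, green, mask, n_fo_bins, glcm_cfg, riclbp_cfg
            )
            for fv in (fv_blue, fv_green):
                if names is None:
                    names = fv.names
                elif fv.names != names:
                    raise ConfigurationError("feature schema changed within a run")
                rows.append(
                    {
                        "patient": patient.id,
                        "group": patient.group,
                        "z": z,
                        "channel": fv.channel,
                        **dict(zip(fv.names, fv.values)),
                    }
                )
    return pd.DataFrame(rows)
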