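"""Laurdan generalized-polarization (GP) imaging.

Laurdan is an environment-sensitive membrane dye whose emission spectrum
shifts with lipid packing: ordered (gel) membrane shifts emission toward the
blue band (400-460 nm), fluid (liquid-crystalline) membrane toward the green
band (470-530 nm).  The generalized polarization

    GP = (I_blue - G * I_green) / (I_blue + G * I_green)

is a per-pixel ratiometric index in [-1, +1]: +1 is fully ordered, -1 fully
fluid.  Being a ratio of the same excitation, it is independent of excitation
intensity and probe concentration.  ``G`` is an instrument calibration
constant correcting the relative detection efficiency of the two bands.

This module converts a background-subtracted two-channel image pair into a
masked GP map and summary statistics (mean, variance, fixed-edge histogram),
and handles the TIFF/PNG/JSON I/O for those products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import DegenerateInputError, ParameterError, ShapeMismatchError

BLUE_BAND = "blue_400_460"
GREEN_BAND = "green_470_530"
BANDS = (BLUE_BAND, GREEN_BAND)

#: Pixel pitch of the acquisition this pipeline targets (nm / pixel).
DEFAULT_PIXEL_SIZE_NM = 200.0

#: Denominator tolerance below which total intensity is treated as zero and
#: the pixel is dropped from the GP mask (photon-count scale).
DENOMINATOR_TOL = 1e-9

#: Red (fluid, low GP) -> green (gel, high GP) colormap used for map export.
GP_COLORMAP = LinearSegmentedColormap.from_list(
    "gp_red_green", [(0.85, 0.1, 0.1), (0.55, 0.45, 0.1), (0.1, 0.75, 0.1)]
)


@dataclass(frozen=True)
class ChannelImage:
    """Single-band non-negative intensity raster on the photon-count scale."""

    pixels: np.ndarray
    band: str
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=np.float64)
        if pixels.ndim != 2:
            raise ShapeMismatchError(f"channel raster must be 2-D, got {pixels.ndim}-D")
        if pixels.size == 0:
            raise DegenerateInputError("channel raster is empty")
        if not np.all(np.isfinite(pixels)):
            raise ParameterError("channel raster contains non-finite values")
        if pixels.min() < 0:
            raise ParameterError("channel intensities must be non-negative")
        if self.band not in BANDS:
            raise ParameterError(f"band must be one of {BANDS}, got {self.band!r}")
        if not self.pixel_size_nm > 0:
            raise ParameterError("pixel_size_nm must be positive")
        object.__setattr__(self, "pixels", pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class GFactor:
    """Calibration constant for the relative detection efficiency of the bands.

    The calibration value depends on the instrument; 1.0 is the uncalibrated
    default and any positive value may be configured.
    """

    g: float = 1.0

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ParameterError("G factor must be positive")


@dataclass(frozen=True)
class GPMap:
    """Per-pixel GP values with a validity mask.

    ``values`` is NaN outside the mask — off-membrane pixels are flagged
    invalid, never silently zero.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        mask = np.asarray(self.mask, dtype=bool)
        if values.shape != mask.shape:
            raise ShapeMismatchError("GP values and mask shapes differ")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass(frozen=True)
class GPSummary:
    """Masked-pixel statistics of one GP map."""

    mean_gp: float
    variance_gp: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_pixels: int

    def to_dict(self) -> dict:
        return {
            "mean_gp": self.mean_gp,
            "variance_gp": self.variance_gp,
            "bin_edges": np.asarray(self.bin_edges).tolist(),
            "counts": np.asarray(self.counts).tolist(),
            "n_pixels": self.n_pixels,
        }


def _check_pair(blue: ChannelImage, green: ChannelImage) -> None:
    if blue.shape != green.shape:
        raise ShapeMismatchError(f"channel shapes differ: {blue.shape} vs {green.shape}")
    if blue.pixel_size_nm != green.pixel_size_nm:
        raise ShapeMismatchError("channel pixel pitches differ")


def subtract_background(image: ChannelImage, background: float) -> ChannelImage:
    """Subtract a scalar background, clamping at zero."""
    if background < 0:
        raise ParameterError("background must be non-negative")
    return ChannelImage(
        np.maximum(image.pixels - background, 0.0), image.band, image.pixel_size_nm
    )


def estimate_background(image: ChannelImage) -> float:
    """Estimate the scalar background of one channel image.

    Mean intensity of the pixels below the global Otsu threshold; 0 for a
    constant image.  A manually measured value can always be passed to
    :func:`subtract_background` instead.
    """
    pixels = image.pixels
    if np.ptp(pixels) == 0:
        return 0.0
    thresh = threshold_otsu(pixels)
    low = pixels[pixels < thresh]
    if low.size == 0:
        return 0.0
    return float(low.mean())


def segment_cells(
    blue: ChannelImage, green: ChannelImage, min_area_px: int = 100
) -> np.ndarray:
    """Foreground mask of retained cells, with small debris removed.

    Otsu threshold on the summed-intensity image, then 8-connected components
    with area below ``min_area_px`` are dropped.  The default (100 px = 4 µm²
    at 200 nm/pixel) is far below a red-cell footprint but above typical
    debris.  An all-background image yields an empty mask.
    """
    _check_pair(blue, green)
    if not min_area_px > 0:
        raise ParameterError("min_area_px must be positive")
    total = blue.pixels + green.pixels
    if np.ptp(total) == 0:
        return np.zeros(total.shape, dtype=bool)
    mask = total > threshold_otsu(total)
    labeled = label(mask, connectivity=2)
    if labeled.max() == 0:
        return np.zeros(total.shape, dtype=bool)
    areas = np.bincount(labeled.ravel())
    keep = areas >= min_area_px
    keep[0] = False
    return keep[labeled]


def compute_gp_map(
    blue: ChannelImage,
    green: ChannelImage,
    g: GFactor | float = GFactor(),
    mask: np.ndarray | None = None,
    denom_tol: float = DENOMINATOR_TOL,
) -> GPMap:
    """Per-pixel GP = (I_blue − G·I_green) / (I_blue + G·I_green).

    Inputs are expected background-subtracted.  Pixels whose total intensity
    (denominator) does not exceed ``denom_tol`` are removed from the output
    mask rather than producing unstable ratios.
    """
    _check_pair(blue, green)
    g_value = g.g if isinstance(g, GFactor) else GFactor(float(g)).g
    if mask is None:
        mask = np.ones(blue.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != blue.shape:
        raise ShapeMismatchError("mask shape differs from image shape")

    denom = blue.pixels + g_value * green.pixels
    valid = mask & (denom > denom_tol)
    if not valid.any():
        raise DegenerateInputError("no valid membrane pixels after intensity masking")

    values = np.full(blue.shape, np.nan)
    numer = blue.pixels - g_value * green.pixels
    values[valid] = numer[valid] / denom[valid]
    # non-negative intensities bound the ratio by construction; clip guards
    # against last-bit rounding only
    values[valid] = np.clip(values[valid], -1.0, 1.0)
    return GPMap(values, valid)


def gp_summary(gp: GPMap, n_bins: int = 100) -> GPSummary:
    """Mean, population variance and fixed-edge histogram over masked pixels.

    Histogram edges always span [-1, 1] so histograms are comparable across
    images and patients.
    """
    if not n_bins > 0:
        raise ParameterError("n_bins must be positive")
    vals = gp.masked_values
    if vals.size == 0:
        raise DegenerateInputError("GP map has an empty mask")
    counts, edges = np.histogram(vals, bins=n_bins, range=(-1.0, 1.0))
    return GPSummary(
        mean_gp=float(vals.mean()),
        variance_gp=float(vals.var()),
        bin_edges=edges,
        counts=counts,
        n_pixels=int(vals.size),
    )


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_channel_tiff(
    path: str | Path, band: str, pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
) -> ChannelImage:
    import tifffile

    data = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    if data.ndim == 3:  # two-page TIFF: page 0 = blue band, page 1 = green band
        data = data[0 if band == BLUE_BAND else 1]
    return ChannelImage(data, band, pixel_size_nm)


def write_gp_map(gp: GPMap, base_path: str | Path) -> tuple[Path, Path]:
    """Write a GP map as 32-bit float TIFF plus a color-mapped PNG.

    PNG uses the red (fluid, GP = −1) to green (gel, GP = +1) convention.
    Returns the (tiff_path, png_path) pair.
    """
    import matplotlib.pyplot as plt
    import tifffile

    base = Path(base_path)
    tiff_path = base.with_suffix(".tif")
    png_path = base.with_suffix(".png")
    tifffile.imwrite(str(tiff_path), gp.values.astype(np.float32))
    shown = np.where(gp.mask, gp.values, np.nan)
    plt.imsave(str(png_path), shown, cmap=GP_COLORMAP, vmin=-1.0, vmax=1.0)
    return tiff_path, png_path


def write_gp_summary(summary: GPSummary, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary.to_dict(), indent=2))
    return path
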