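"""Cube preprocessing: spatial downsampling, anchor normalization, outlier masking.

The three steps run in a fixed order.  First each band image is spatially
resized (default to 20% per axis) by area-weighted averaging, which smooths
acquisition noise.  Then every pixel spectrum is divided by the mean of its
own three longest-wavelength band values, removing per-pixel brightness
variation; after this "anchor" normalization a clean pixel sits near 1 at the
red end of the spectrum.  Finally pixels carrying any normalized value above
1.5 or below 0 are masked out, as are pixels whose anchor mean was
non-positive (normalization undefined).

The masked categories are disjoint: a pixel is counted as degenerate first,
otherwise as high if any band exceeds the upper threshold, otherwise as low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _skimage_resize

from .io import HyperCube

__all__ = [
    "PreprocessParams",
    "PixelMask",
    "NormalizedCube",
    "resize_spatial",
    "normalize_anchor",
    "mask_outliers",
    "preprocess_cube",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Preprocessing configuration.

    resize_factor
        Per-axis spatial shrink factor in (0, 1]; output dims are floored.
    n_anchor
        Number of longest-wavelength bands averaged into the normalizer.
    hi, lo
        Outlier thresholds on normalized values (any-band rule).
    interpolation
        ``"area"`` (box averaging, default) or ``"bilinear"``.
    """

    resize_factor: float = 0.2
    n_anchor: int = 3
    hi: float = 1.5
    lo: float = 0.0
    interpolation: str = "area"

    def __post_init__(self):
        if not (0.0 < self.resize_factor <= 1.0):
            raise ValueError("resize_factor must be in (0, 1]")
        if self.n_anchor < 1:
            raise ValueError("n_anchor must be >= 1")
        if self.hi <= self.lo:
            raise ValueError("hi threshold must exceed lo")
        if self.interpolation not in ("area", "bilinear"):
            raise ValueError("interpolation must be 'area' or 'bilinear'")


@dataclass
class PixelMask:
    """Retention mask over the (resized) spatial grid with category tallies."""

    retained: np.ndarray
    n_high: int = 0
    n_low: int = 0
    n_degenerate: int = 0

    def __post_init__(self):
        self.retained = np.asarray(self.retained, dtype=bool)
        n_masked = int((~self.retained).sum())
        if self.n_high + self.n_low + self.n_degenerate != n_masked:
            raise ValueError(
                "mask categories must partition the masked pixels "
                f"({self.n_high}+{self.n_low}+{self.n_degenerate} != {n_masked})"
            )

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass
class NormalizedCube:
    """An anchor-normalized cube plus its degenerate-anchor flags and mask."""

    cube: HyperCube
    anchor_bands: tuple
    degenerate: np.ndarray
    mask: PixelMask | None = None

    @property
    def grid(self):
        return self.cube.grid

    @property
    def meta(self):
        return self.cube.meta

    @property
    def data(self) -> np.ndarray:
        return self.cube.data

    def retained_spectra(self) -> np.ndarray:
        """Retained pixel spectra in row-major spatial order, shape (n, bands)."""
        if self.mask is None:
            raise ValueError("cube has no mask yet; run mask_outliers first")
        return self.cube.data[self.mask.retained]


def _overlap_weights(n_in: int, n_out: int, step: float) -> np.ndarray:
    """Row-stochastic (n_out, n_in) matrix of pixel-interval overlaps.

    Output pixel j averages the input interval [j*step, (j+1)*step), clipped
    to the image; fractional edge pixels get fractional weight.
    """
    w = np.zeros((n_out, n_in))
    for j in range(n_out):
        a = j * step
        b = min((j + 1) * step, float(n_in))
        i0, i1 = int(np.floor(a)), int(np.ceil(b))
        for i in range(i0, min(i1, n_in)):
            w[j, i] = min(b, i + 1) - max(a, i)
        w[j] /= w[j].sum()
    return w


def resize_spatial(cube: HyperCube, factor: float,
                   interpolation: str = "area") -> HyperCube:
    """Shrink each band image by ``factor`` per axis.

    Area mode averages each output pixel over its (possibly fractional)
    footprint of input pixels, so spatially constant images are preserved
    exactly and a 10x10 image at factor 0.2 becomes the 2x2 table of 5x5
    block means.  Wavelength grid and provenance are unchanged.
    """
    if not (0.0 < factor <= 1.0):
        raise ValueError(f"resize factor must be in (0, 1], got {factor}")
    h, w, b = cube.data.shape
    h_out, w_out = int(np.floor(factor * h)), int(np.floor(factor * w))
    if h_out < 1 or w_out < 1:
        raise ValueError(
            f"factor {factor} collapses a {h}x{w} frame to zero size"
        )
    if factor == 1.0:
        return HyperCube(cube.data.copy(), cube.grid, cube.meta)
    if interpolation == "area":
        step = 1.0 / factor
        wy = _overlap_weights(h, h_out, step)
        wx = _overlap_weights(w, w_out, step)
        out = np.tensordot(wy, cube.data, axes=(1, 0))          # (h_out, w, b)
        out = np.tensordot(wx, out, axes=(1, 1)).transpose(1, 0, 2)
    elif interpolation == "bilinear":
        out = _skimage_resize(cube.data, (h_out, w_out, b), order=1,
                              mode="edge", anti_aliasing=False,
                              preserve_range=True)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return HyperCube(np.ascontiguousarray(out), cube.grid, cube.meta)


def normalize_anchor(cube: HyperCube, n_anchor: int = 3) -> NormalizedCube:
    """Divide each pixel spectrum by the mean of its longest-wavelength bands.

    The anchor bands are the ``n_anchor`` bands with the largest wavelength
    (for the 70-band visible grid these are 685, 687 and 691 nm).  Pixels
    whose anchor mean is <= 0 cannot be normalized; they are flagged
    degenerate, left unscaled, and excluded from retention downstream.
    """
    b = cube.grid.band_count
    if not (1 <= n_anchor <= b):
        raise ValueError(f"n_anchor must be in 1..{b}, got {n_anchor}")
    anchor_bands = tuple(range(b - n_anchor, b))  # grid is ascending
    anchor_mean = cube.data[..., anchor_bands].mean(axis=-1)
    degenerate = anchor_mean <= 0.0
    scale = np.where(degenerate, 1.0, anchor_mean)
    data = cube.data / scale[..., None]
    out = HyperCube(data, cube.grid, cube.meta)
    return NormalizedCube(out, anchor_bands, degenerate)


def mask_outliers(norm: NormalizedCube, hi: float = 1.5,
                  lo: float = 0.0) -> PixelMask:
    """Mask whole pixels whose normalized spectrum leaves [lo, hi].

    A single out-of-range band value discards the pixel: the spectrum is the
    analysis unit and downstream scoring needs complete spectra.  Degenerate
    anchor pixels are always masked.
    """
    if hi <= lo:
        raise ValueError(f"hi ({hi}) must exceed lo ({lo})")
    data = norm.cube.data
    any_high = (data > hi).any(axis=-1)
    any_low = (data < lo).any(axis=-1)
    degenerate = norm.degenerate
    high = any_high & ~degenerate
    low = any_low & ~degenerate & ~high
    retained = ~(degenerate | high | low)
    return PixelMask(
        retained=retained,
        n_high=int(high.sum()),
        n_low=int(low.sum()),
        n_degenerate=int(degenerate.sum()),
    )


def preprocess_cube(cube: HyperCube,
                    params: PreprocessParams | None = None) -> NormalizedCube:
    """Resize, normalize and mask one cube (deterministic composition)."""
    params = params or PreprocessParams()
    resized = resize_spatial(cube, params.resize_factor, params.interpolation)
    norm = normalize_anchor(resized, params.n_anchor)
    norm.mask = mask_outliers(norm, params.hi, params.lo)
    return norm
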