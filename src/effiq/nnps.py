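"""Effective normalised noise power spectrum from flat-field images.

A central square ROI (1024 x 1024 pixels in the reference protocol) of each
linearized flat field is tiled into overlapping 256 x 256 sub-regions
(overlap 128), each sub-region detrended, and the two-dimensional noise
power spectrum taken as the sub-ROI average of

    NPS(u, v) = (dx * dy) / (Nx * Ny) * |DFT2(residual)|^2   [mm^2]

Dividing by the squared mean linearized signal gives the normalised NNPS.
The one-dimensional vertical eNNPS averages 2-D NNPS columns in a band
flanking the vertical frequency axis (the on-axis column excluded, where
residual trends concentrate), folds to non-negative frequencies and rescales
them to the object plane.

Detrending defaults to a per-sub-ROI quadratic surface fit — standard
flat-field practice to keep heel-effect shading out of the low-frequency
bins — with a plain mean subtraction fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .exceptions import EstimationError, ValidationError
from .io import FrequencySeries, GeometrySetup, RadiographImage

__all__ = ["NnpsConfig", "Nnps2D", "NNPSEstimator", "extract_subrois", "nnps_2d", "nnps_1d_vertical"]


@dataclass
class NnpsConfig:
    roi_px: int = 1024
    sub_px: int = 256
    overlap_px: int = 128
    n_images: int = 4
    detrend: str = "poly2d"  # {'poly2d', 'mean'}
    band_lines: int = 7
    exclude_axis: bool = True

    def __post_init__(self) -> None:
        step = self.sub_px - self.overlap_px
        if step <= 0:
            raise ValidationError("overlap_px must be smaller than sub_px")
        if (self.roi_px - self.sub_px) % step != 0:
            raise ValidationError("(roi_px - sub_px) must be divisible by (sub_px - overlap_px)")
        if self.detrend not in ("poly2d", "mean"):
            raise ValidationError("detrend must be 'poly2d' or 'mean'")
        if self.sub_px & (self.sub_px - 1):
            warnings.warn("sub_px is not a power of two; FFTs will be slower", stacklevel=2)

    @property
    def n_subrois_per_image(self) -> int:
        step = self.sub_px - self.overlap_px
        return ((self.roi_px - self.sub_px) // step + 1) ** 2


@dataclass
class Nnps2D:
    """2-D NNPS on fftshifted frequency axes (mm^-1), values in mm^2."""

    u_mm: np.ndarray  # column (horizontal) frequencies
    v_mm: np.ndarray  # row (vertical) frequencies
    matrix: np.ndarray
    n_subrois: int
    mean_signal: float

    def __post_init__(self) -> None:
        if np.any(self.matrix < 0):
            raise ValidationError("NNPS matrix must be non-negative")


def extract_subrois(image: RadiographImage, config: NnpsConfig | None = None) -> list[np.ndarray]:
    """Overlapping sub-ROIs tiling the central roi_px square of the image."""
    config = config or NnpsConfig()
    r, c = image.pixels.shape
    if r < config.roi_px or c < config.roi_px:
        raise ValidationError(
            f"image {r}x{c} is smaller than the {config.roi_px}-pixel analysis ROI; "
            "use a scaled-down NnpsConfig"
        )
    r0 = (r - config.roi_px) // 2
    c0 = (c - config.roi_px) // 2
    roi = image.pixels[r0 : r0 + config.roi_px, c0 : c0 + config.roi_px]
    step = config.sub_px - config.overlap_px
    out = []
    for i in range(0, config.roi_px - config.sub_px + 1, step):
        for j in range(0, config.roi_px - config.sub_px + 1, step):
            out.append(roi[i : i + config.sub_px, j : j + config.sub_px])
    return out


def _poly2d_residual(tile: np.ndarray, basis_cache: dict) -> np.ndarray:
    """Residual after removing a least-squares 2-D quadratic surface."""
    shape = tile.shape
    if shape not in basis_cache:
        ny, nx = shape
        y = np.linspace(-1, 1, ny)[:, None] * np.ones((1, nx))
        x = np.ones((ny, 1)) * np.linspace(-1, 1, nx)[None, :]
        cols = [np.ones_like(x), x, y, x * x, x * y, y * y]
        a = np.stack([c.ravel() for c in cols], axis=1)
        # pseudo-inverse once per tile shape
        basis_cache[shape] = (a, np.linalg.pinv(a))
    a, pinv = basis_cache[shape]
    coef = pinv @ tile.ravel()
    return tile - (a @ coef).reshape(shape)


def nnps_2d(images: list[RadiographImage], config: NnpsConfig | None = None) -> Nnps2D:
    """Average the squared DFT modulus of detrended sub-ROIs into a 2-D NNPS."""
    config = config or NnpsConfig()
    if not images:
        raise EstimationError("no flat-field images given")
    pitch = images[0].pixel_pitch_mm
    means = []
    for img in images:
        if not img.linearized:
            raise ValidationError("NNPS requires linearized flat fields")
        if abs(img.pixel_pitch_mm - pitch) > 1e-9:
            raise ValidationError("all flat fields must share one pixel pitch")
        means.append(float(img.pixels.mean()))
    if max(means) > 1.1 * min(means):
        warnings.warn("flat-field means differ by more than 10%", stacklevel=2)
    basis_cache: dict = {}
    accum = None
    n_subrois = 0
    for img in images:
        for tile in extract_subrois(img, config):
            if config.detrend == "poly2d":
                resid = _poly2d_residual(tile, basis_cache)
            else:
                resid = tile - tile.mean()
            power = np.abs(np.fft.fft2(resid)) ** 2
            accum = power if accum is None else accum + power
            n_subrois += 1
    if n_subrois < 2:
        raise EstimationError("need at least 2 sub-ROIs for an NPS estimate")
    n = config.sub_px
    nps = np.fft.fftshift(accum / n_subrois) * (pitch * pitch) / (n * n)
    mean_signal = float(np.mean(means))
    nnps = nps / mean_signal**2
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=pitch))
    return Nnps2D(u_mm=freqs.copy(), v_mm=freqs.copy(), matrix=nnps,
                  n_subrois=n_subrois, mean_signal=mean_signal)


def nnps_1d_vertical(
    nnps2d: Nnps2D,
    config: NnpsConfig | None = None,
    geometry: GeometrySetup | None = None,
) -> FrequencySeries:
    """1-D vertical eNNPS: band average beside the vertical axis, folded.

    Averages the 2-D NNPS over the ``band_lines`` frequency columns on each
    side of the vertical frequency axis (u = 0 column excluded when
    ``exclude_axis``), then folds +/-v onto a non-negative frequency grid.
    """
    config = config or NnpsConfig()
    u = nnps2d.u_mm
    n = u.size
    zero_col = int(np.argmin(np.abs(u)))
    cols = [
        zero_col + k
        for k in range(-config.band_lines, config.band_lines + 1)
        if (k != 0 or not config.exclude_axis)
    ]
    if min(cols) < 0 or max(cols) >= n:
        raise ValidationError("band_lines wider than the frequency grid")
    band = nnps2d.matrix[:, cols].mean(axis=1)  # function of v
    v = nnps2d.v_mm
    zero_row = int(np.argmin(np.abs(v)))
    step = float(v[1] - v[0])
    n_pos = min(zero_row, n - zero_row) if n % 2 == 0 else zero_row
    values = np.empty(n_pos)
    values[0] = band[zero_row]
    for k in range(1, n_pos):
        values[k] = 0.5 * (band[zero_row + k] + band[zero_row - k])
    freqs = np.arange(n_pos) * step
    m = geometry.magnification if geometry is not None else 1.0
    plane = "object" if geometry is not None else "detector"
    return FrequencySeries(freqs * m, values, plane=plane, quantity="eNNPS")


class NNPSEstimator(BaseEstimator):
    """Scikit-learn style estimator for the effective NNPS.

    ``fit`` consumes the (four) linearized flat fields; ``nnps2d_`` holds the
    2-D estimate and ``series_`` the folded 1-D vertical eNNPS, referred to
    the object plane when a geometry is supplied.
    """

    def __init__(
        self,
        roi_px: int = 1024,
        sub_px: int = 256,
        overlap_px: int = 128,
        detrend: str = "poly2d",
        band_lines: int = 7,
        exclude_axis: bool = True,
    ):
        self.roi_px = roi_px
        self.sub_px = sub_px
        self.overlap_px = overlap_px
        self.detrend = detrend
        self.band_lines = band_lines
        self.exclude_axis = exclude_axis

    def _config(self) -> NnpsConfig:
        return NnpsConfig(
            roi_px=self.roi_px,
            sub_px=self.sub_px,
            overlap_px=self.overlap_px,
            detrend=self.detrend,
            band_lines=self.band_lines,
            exclude_axis=self.exclude_axis,
        )

    def fit(self, images: list[RadiographImage], geometry: GeometrySetup | None = None):
        config = self._config()
        self.nnps2d_ = nnps_2d(images, config)
        self.series_ = nnps_1d_vertical(self.nnps2d_, config, geometry)
        return self

    def transform(self, images=None) -> FrequencySeries:
        check_is_fitted(self, "series_")
        return self.series_
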