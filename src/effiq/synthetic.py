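"""Synthetic radiograph generator with known ground truth.

The study this pipeline reimplements deposited no images, so every measurable
image class is emulated here with analytically known truth:

* flat fields (noise power oracle for the NNPS stage),
* slanted-edge images (Gaussian PSF of known width for the MTF stage),
* beam-stop grid images (known scatter fraction),
* exposure series (known detector response),
* a Kramers-form filtered bremsstrahlung spectrum (stand-in for an external
  spectrum calculator, for the q-value stage).

The noise model is additive Gaussian by default — every downstream formula
consumes only second-order statistics, and Gaussian noise gives an exact
closed-form NNPS truth sigma^2 * pitch^2 / mean^2.  A Poisson option exists
behind ``noise='poisson'`` for dose-scaling sanity checks.

Edge rendering is exact: the blurred step is integrated analytically over
each square pixel aperture (repeated antiderivatives of the normal CDF), so
the MTF oracle carries no rasterisation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .exceptions import ValidationError
from .fluence import Spectrum, load_attenuation_table
from .io import AcquisitionMeta, RadiographImage

__all__ = [
    "SyntheticGroundTruth",
    "BeamStopGridSpec",
    "make_flat_field",
    "make_edge_image",
    "make_beam_stop_image",
    "make_exposure_series",
    "make_spectrum",
]

_AL_DENSITY_G_CM3 = 2.699
_CU_DENSITY_G_CM3 = 8.96


@dataclass
class SyntheticGroundTruth:
    """What the generator actually put into an image (the oracle record)."""

    seed: int
    pixel_pitch_mm: float | None = None
    true_mtf_sigma_mm: float | None = None
    true_angle_deg: float | None = None
    true_nnps_level_mm2: float | None = None
    true_sf: float | None = None
    response_coeffs: tuple[float, ...] | None = None

    def analytic_mtf(self, frequencies_mm: np.ndarray) -> np.ndarray:
        """Presampled MTF of the generated edge: Gaussian PSF x pixel aperture.

        The square pixel aperture projected onto the edge normal is two boxes
        of widths p*cos(theta) and p*sin(theta); each contributes a sinc.
        """
        if self.true_mtf_sigma_mm is None or self.pixel_pitch_mm is None:
            raise ValidationError("no edge truth recorded")
        f = np.asarray(frequencies_mm, dtype=float)
        s, p = self.true_mtf_sigma_mm, self.pixel_pitch_mm
        th = np.deg2rad(self.true_angle_deg or 0.0)
        gauss = np.exp(-2.0 * np.pi**2 * s**2 * f**2)
        aperture = np.abs(np.sinc(p * np.cos(th) * f) * np.sinc(p * np.sin(th) * f))
        return gauss * aperture


@dataclass
class BeamStopGridSpec:
    """Rectangular array of opaque-ish lead cylinders in a PMMA plate."""

    n_rows: int = 11
    n_cols: int = 11
    pitch_mm: float = 25.0
    cylinder_diameter_mm: float = 10.0
    center_offset_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 5 or self.n_cols < 5:
            raise ValidationError("grid must be at least 5 x 5 (a central 5x5 block must exist)")
        if self.pitch_mm <= self.cylinder_diameter_mm:
            raise ValidationError("cylinder pitch must exceed the cylinder diameter")

    def centers_mm(self) -> np.ndarray:
        """(n_rows*n_cols, 2) array of (row_mm, col_mm) offsets from image center."""
        r = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.pitch_mm
        c = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.pitch_mm
        rr, cc = np.meshgrid(r, c, indexing="ij")
        out = np.stack([rr.ravel(), cc.ravel()], axis=1)
        out[:, 0] += self.center_offset_mm[0]
        out[:, 1] += self.center_offset_mm[1]
        return out

    def central_block(self, size: int = 5) -> np.ndarray:
        """Centers of the central size x size cylinders (row_mm, col_mm)."""
        r0 = (self.n_rows - size) // 2
        c0 = (self.n_cols - size) // 2
        centers = self.centers_mm().reshape(self.n_rows, self.n_cols, 2)
        return centers[r0 : r0 + size, c0 : c0 + size].reshape(-1, 2)


def _apply_noise(pixels: np.ndarray, noise_sd: float, noise: str, rng: np.random.Generator) -> np.ndarray:
    if noise == "gaussian":
        if noise_sd > 0:
            pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
        return pixels
    if noise == "poisson":
        return rng.poisson(np.clip(pixels, 0, None)).astype(float)
    raise ValidationError(f"unknown noise model {noise!r}")


def make_flat_field(
    mean_level: float,
    noise_sd: float,
    pitch_mm: float,
    shape: tuple[int, int] = (1200, 1200),
    trend_amplitude: float = 0.0,
    seed: int = 0,
    *,
    noise: str = "gaussian",
    meta: AcquisitionMeta | None = None,
) -> tuple[RadiographImage, SyntheticGroundTruth]:
    """Homogeneous-phantom flat field: mean + optional quadratic trend + noise.

    The smooth trend emulates heel-effect shading; with Gaussian noise the
    true normalised noise power is flat at noise_sd^2 * pitch^2 / mean^2.
    """
    if mean_level <= 0:
        raise ValidationError("mean_level must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    u = np.linspace(-1.0, 1.0, rows)[:, None]
    v = np.linspace(-1.0, 1.0, cols)[None, :]
    pixels = np.full(shape, float(mean_level))
    if trend_amplitude:
        pixels = pixels + trend_amplitude * (u**2 + v**2 - 2.0 / 3.0)
    pixels = _apply_noise(pixels, noise_sd, noise, rng)
    if noise == "poisson":
        level = mean_level * pitch_mm**2 / mean_level**2
    else:
        level = noise_sd**2 * pitch_mm**2 / mean_level**2
    img = RadiographImage(pixels, pitch_mm, linearized=True, meta=meta or AcquisitionMeta())
    truth = SyntheticGroundTruth(seed=seed, pixel_pitch_mm=pitch_mm, true_nnps_level_mm2=level)
    return img, truth


# -- analytic edge rendering -------------------------------------------------
#
# Pixel value = step (blurred by an isotropic Gaussian of width sigma)
# averaged over the square pixel aperture.  Along the edge normal this is the
# normal CDF convolved with two boxes (the aperture's projections); repeated
# antiderivatives of the CDF give it in closed form.


def _i2_gauss(x: np.ndarray) -> np.ndarray:
    # second antiderivative of the standard normal CDF
    phi = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
    return 0.5 * ((x**2 + 1.0) * ndtr(x) + x * phi)


def _i2_step(x: np.ndarray) -> np.ndarray:
    # sigma -> 0 limit: second antiderivative of the Heaviside step
    return 0.5 * np.square(np.clip(x, 0.0, None))


def _edge_profile(d_mm: np.ndarray, sigma_mm: float, w1_mm: float, w2_mm: float) -> np.ndarray:
    """Fraction of 'high' side seen by a pixel whose center is d_mm from the edge."""
    h1, h2 = w1_mm / 2.0, w2_mm / 2.0
    corners = [(d_mm + s1 * h1 + s2 * h2, s1 * s2) for s1 in (1, -1) for s2 in (1, -1)]
    if sigma_mm > 0:
        acc = sum(sign * _i2_gauss(x / sigma_mm) for x, sign in corners)
        return sigma_mm**2 * acc / (w1_mm * w2_mm)
    acc = sum(sign * _i2_step(x) for x, sign in corners)
    return acc / (w1_mm * w2_mm)


def make_edge_image(
    angle_deg: float = 3.0,
    sigma_mm: float = 0.2,
    pitch_mm: float = 0.143,
    shape: tuple[int, int] = (600, 600),
    contrast: tuple[float, float] = (100.0, 1000.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    edge_shift_mm: float = 0.0,
    meta: AcquisitionMeta | None = None,
) -> tuple[RadiographImage, SyntheticGroundTruth]:
    """Slanted-edge image: a step tilted ``angle_deg`` from the column axis.

    The left side of the image is the bright (unattenuated) side.  The truth
    records sigma and the angle; ``SyntheticGroundTruth.analytic_mtf`` gives
    the corresponding presampled MTF.
    """
    if not (0.5 <= angle_deg <= 15.0):
        raise ValidationError("angle_deg must be in [0.5, 15] degrees")
    if sigma_mm < 0:
        raise ValidationError("sigma_mm must be non-negative")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    th = np.deg2rad(angle_deg)
    # pixel-center coordinates in mm, origin at image center
    y = (np.arange(rows) - (rows - 1) / 2.0)[:, None] * pitch_mm
    x = (np.arange(cols) - (cols - 1) / 2.0)[None, :] * pitch_mm
    # edge runs nearly vertically; normal points toward +x (the dark side)
    d = (x - edge_shift_mm) * np.cos(th) - y * np.sin(th)
    w1 = pitch_mm * np.cos(th)
    w2 = pitch_mm * np.sin(th)
    # profile over a 1-D grid of distances, then interpolate (d is smooth in x,y)
    dmax = float(np.abs(d).max())
    grid = np.linspace(-dmax - pitch_mm, dmax + pitch_mm, 4096)
    prof = _edge_profile(grid, sigma_mm, w1, w2)
    frac_dark = np.interp(d, grid, prof)
    low, high = contrast
    pixels = high + (low - high) * frac_dark
    pixels = _apply_noise(pixels, noise_sd, "gaussian", rng)
    img = RadiographImage(pixels, pitch_mm, linearized=True, meta=meta or AcquisitionMeta())
    truth = SyntheticGroundTruth(
        seed=seed, pixel_pitch_mm=pitch_mm, true_mtf_sigma_mm=sigma_mm, true_angle_deg=angle_deg
    )
    return img, truth


def make_beam_stop_image(
    grid: BeamStopGridSpec | None = None,
    primary_level: float = 700.0,
    scatter_level: float = 300.0,
    lead_transmission: float = 0.0,
    noise_sd: float = 0.0,
    pitch_mm: float = 0.143,
    shape: tuple[int, int] = (2200, 2200),
    seed: int = 0,
    *,
    meta: AcquisitionMeta | None = None,
) -> tuple[RadiographImage, SyntheticGroundTruth]:
    """Beam-stop grid image: hard cylinder shadows on a primary+scatter field.

    Behind a stop only the (slightly transmitted) primary is removed, so the
    shadow level is primary*transmission + scatter and the true scatter
    fraction is exactly the shadow-to-background ratio the analyzer measures.
    """
    grid = grid or BeamStopGridSpec()
    if primary_level <= 0:
        raise ValidationError("primary_level must be positive")
    if scatter_level < 0:
        raise ValidationError("scatter_level must be non-negative")
    if not (0.0 <= lead_transmission < 1.0):
        raise ValidationError("lead_transmission must be in [0, 1)")
    rows, cols = shape
    half_r = rows * pitch_mm / 2.0
    half_c = cols * pitch_mm / 2.0
    centers = grid.centers_mm()
    reach = grid.cylinder_diameter_mm / 2.0
    if (np.abs(centers[:, 0]) + reach > half_r).any() or (np.abs(centers[:, 1]) + reach > half_c).any():
        raise ValidationError("beam-stop grid does not fit inside the image")
    rng = np.random.default_rng(seed)
    pixels = np.full(shape, primary_level + scatter_level, dtype=float)
    shadow_val = primary_level * lead_transmission + scatter_level
    r2 = reach**2
    cy0, cx0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    reach_px = int(np.ceil(reach / pitch_mm)) + 1
    for cy, cx in centers:
        # disk rendered inside its bounding box only
        pr, pc = cy0 + cy / pitch_mm, cx0 + cx / pitch_mm
        r0, r1 = max(0, int(pr) - reach_px), min(rows, int(pr) + reach_px + 2)
        c0, c1 = max(0, int(pc) - reach_px), min(cols, int(pc) + reach_px + 2)
        yy = (np.arange(r0, r1)[:, None] - pr) * pitch_mm
        xx = (np.arange(c0, c1)[None, :] - pc) * pitch_mm
        box = pixels[r0:r1, c0:c1]
        box[yy**2 + xx**2 <= r2] = shadow_val
    pixels = _apply_noise(pixels, noise_sd, "gaussian", rng)
    true_sf = shadow_val / (primary_level + scatter_level)
    img = RadiographImage(pixels, pitch_mm, linearized=True, meta=meta or AcquisitionMeta())
    truth = SyntheticGroundTruth(seed=seed, pixel_pitch_mm=pitch_mm, true_sf=true_sf)
    return img, truth


def make_exposure_series(
    response_kind: str = "linear",
    coeffs: tuple[float, ...] = (5.0, 2.0),
    dak_levels: tuple[float, ...] = tuple(float(k) for k in range(1, 11)),
    pitch_mm: float = 0.143,
    shape: tuple[int, int] = (64, 64),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[RadiographImage, float]], SyntheticGroundTruth]:
    """Exposure series: one small flat image per detector-air-kerma level.

    The mean pixel value of image i is response(dak_levels[i]); the response
    is a polynomial with intercept-first coefficients (degree 1 for 'linear',
    degree 5 for 'polynomial5').
    """
    if response_kind not in ("linear", "polynomial5"):
        raise ValidationError(f"unknown response_kind {response_kind!r}")
    degree = 1 if response_kind == "linear" else 5
    if len(coeffs) != degree + 1:
        raise ValidationError(f"{response_kind} needs {degree + 1} coefficients, got {len(coeffs)}")
    dak = np.asarray(dak_levels, dtype=float)
    if np.any(dak <= 0):
        raise ValidationError("dak_levels must be positive")
    fine = np.linspace(dak.min(), dak.max(), 512)
    means_fine = np.polynomial.polynomial.polyval(fine, coeffs)
    if np.any(np.diff(means_fine) <= 0):
        raise ValidationError("response is not strictly increasing over the dak range")
    rng = np.random.default_rng(seed)
    means = np.polynomial.polynomial.polyval(dak, coeffs)
    out = []
    for mean, level in zip(means, dak):
        pixels = np.full(shape, float(mean))
        pixels = _apply_noise(pixels, noise_sd, "gaussian", rng)
        out.append((RadiographImage(pixels, pitch_mm), float(level)))
    truth = SyntheticGroundTruth(seed=seed, pixel_pitch_mm=pitch_mm, response_coeffs=tuple(coeffs))
    return out, truth


def make_spectrum(
    kvp: float,
    filtration_mm_al: float = 0.0,
    filtration_mm_cu: float = 0.0,
    bin_width_keV: float = 1.0,
    *,
    inherent_filtration_mm_al: float = 2.5,
    e_min_keV: float = 10.0,
) -> Spectrum:
    """Kramers-form filtered bremsstrahlung spectrum (relative fluence scale).

    Unfiltered fluence per energy bin is proportional to (kvp - E)/E,
    truncated at the tube voltage; Al/Cu filtration attenuates with the
    shipped mass-attenuation tables.  The inherent tube filtration defaults
    to the 2.5 mm Al equivalent that diagnostic tube housings must provide
    (IEC minimum total filtration); additional filtration is on top of it.
    A stand-in for a full spectrum calculator: no anode self-filtration
    model or characteristic lines.
    """
    if kvp <= 10.0:
        raise ValidationError("kvp must exceed 10 keV")
    edges = np.arange(e_min_keV, kvp + bin_width_keV, bin_width_keV)
    centers = edges[:-1] + bin_width_keV / 2.0
    fluence = np.clip(kvp - centers, 0.0, None) / centers
    fluence[centers >= kvp] = 0.0
    total_al = inherent_filtration_mm_al + filtration_mm_al
    if total_al > 0:
        mu = load_attenuation_table("al")(centers)
        fluence = fluence * np.exp(-mu * _AL_DENSITY_G_CM3 * total_al / 10.0)
    if filtration_mm_cu > 0:
        mu = load_attenuation_table("cu")(centers)
        fluence = fluence * np.exp(-mu * _CU_DENSITY_G_CM3 * filtration_mm_cu / 10.0)
    return Spectrum(centers, fluence, bin_width_keV)
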