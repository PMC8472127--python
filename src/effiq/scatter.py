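"""Scatter fraction, transmission factor and air-kerma distance corrections.

The scatter fraction is measured with a beam-stop device: an 11 x 11 array
of lead cylinders.  The average signal behind the central 5 x 5 cylinders
(primary blocked, scatter remains) over the average background signal
between them gives

    SF = MPV_lead / MPV_background.

The transmission factor TF = AK+ / AK- is the ratio of air kerma measured
with and without the phantom.  Air-kerma readings taken at the dosimeter
plane (distance SDD from the source) are corrected to the detector plane
(SID): linearly in SDD/SID for a slot-scanned fan beam, whose fluence falls
off only along one axis, and by the inverse square for a cone beam.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .exceptions import EstimationError, ValidationError
from .io import RadiographImage
from .synthetic import BeamStopGridSpec

__all__ = [
    "DoseReadings",
    "ScatterResult",
    "ScatterFraction",
    "measure_scatter_fraction",
    "detect_beam_stop_grid",
    "transmission_factor",
    "incident_air_kerma",
    "detector_air_kerma",
]

_ROI_DIAMETER_FRACTION = 0.6  # measurement disk vs cylinder shadow; avoids penumbra


@dataclass
class DoseReadings:
    """Dosimeter air-kerma pair and the geometry needed to project it."""

    ak_with_phantom_uGy: float
    ak_without_phantom_uGy: float
    sdd_cm: float
    sid_cm: float
    beam_mode: Literal["slot", "cone"] = "cone"

    def __post_init__(self) -> None:
        if self.ak_with_phantom_uGy <= 0 or self.ak_without_phantom_uGy <= 0:
            raise ValidationError("air-kerma readings must be positive")
        if self.ak_with_phantom_uGy > self.ak_without_phantom_uGy:
            raise ValidationError("AK with phantom cannot exceed AK without phantom")
        if self.sdd_cm > self.sid_cm:
            raise ValidationError("SDD cannot exceed SID")
        if self.beam_mode not in ("slot", "cone"):
            raise ValidationError("beam_mode must be 'slot' or 'cone'")


@dataclass
class ScatterResult:
    sf: float
    mpv_lead: float
    mpv_background: float
    n_cylinders_used: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.sf < 1.0):
            raise ValidationError(f"scatter fraction {self.sf:.3f} outside [0, 1)")


def _disk_mean(pixels: np.ndarray, cy_px: float, cx_px: float, radius_px: float) -> float:
    r0 = max(0, int(np.floor(cy_px - radius_px)) - 1)
    r1 = min(pixels.shape[0], int(np.ceil(cy_px + radius_px)) + 2)
    c0 = max(0, int(np.floor(cx_px - radius_px)) - 1)
    c1 = min(pixels.shape[1], int(np.ceil(cx_px + radius_px)) + 2)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask = (yy - cy_px) ** 2 + (xx - cx_px) ** 2 <= radius_px**2
    if not mask.any():
        raise EstimationError("measurement disk contains no pixels")
    return float(pixels[r0:r1, c0:c1][mask].mean())


def detect_beam_stop_grid(
    image: RadiographImage, expected: tuple[int, int] = (11, 11)
) -> BeamStopGridSpec:
    """Locate the cylinder grid by thresholding at half the background level.

    Shadows are segmented, their centroids clustered onto a rectangular
    lattice; raises if the count differs from the expected grid.
    """
    px = image.pixels
    background = float(np.median(px))
    labels, n_found = ndimage.label(px < 0.5 * background)
    n_expected = expected[0] * expected[1]
    if n_found != n_expected:
        raise EstimationError(
            f"detected {n_found} beam-stop shadows, expected {n_expected}"
        )
    centroids = np.array(ndimage.center_of_mass(px < 0.5 * background, labels,
                                                range(1, n_found + 1)))
    areas = ndimage.sum_labels(np.ones_like(px), labels, range(1, n_found + 1))
    diameter_px = 2.0 * np.sqrt(float(np.mean(areas)) / np.pi)
    # lattice pitch from the row-centroid span of the full grid
    pitch_px = (np.max(centroids[:, 0]) - np.min(centroids[:, 0])) / (expected[0] - 1)
    center_r = float(np.mean(centroids[:, 0]))
    center_c = float(np.mean(centroids[:, 1]))
    img_cr = (px.shape[0] - 1) / 2.0
    img_cc = (px.shape[1] - 1) / 2.0
    return BeamStopGridSpec(
        n_rows=expected[0],
        n_cols=expected[1],
        pitch_mm=float(pitch_px) * image.pixel_pitch_mm,
        cylinder_diameter_mm=diameter_px * image.pixel_pitch_mm,
        center_offset_mm=(
            (center_r - img_cr) * image.pixel_pitch_mm,
            (center_c - img_cc) * image.pixel_pitch_mm,
        ),
    )


def measure_scatter_fraction(
    image: RadiographImage, grid: BeamStopGridSpec | str | None = "auto"
) -> ScatterResult:
    """Scatter fraction from the central 5 x 5 cylinders of a beam-stop image.

    Per-cylinder means come from disk ROIs of 60% of the cylinder diameter;
    background means from equal-area disks at the midpoints between
    4-neighbouring central cylinders.
    """
    if grid is None or grid == "auto":
        grid = detect_beam_stop_grid(image)
    pitch = image.pixel_pitch_mm
    px = image.pixels
    img_cr = (px.shape[0] - 1) / 2.0
    img_cc = (px.shape[1] - 1) / 2.0
    roi_radius_mm = _ROI_DIAMETER_FRACTION * grid.cylinder_diameter_mm / 2.0
    if grid.pitch_mm / 2.0 <= grid.cylinder_diameter_mm / 2.0 + roi_radius_mm:
        raise ValidationError(
            "background ROI would overlap a cylinder shadow; grid pitch too tight"
        )
    centers = grid.central_block(5).reshape(5, 5, 2)
    lead_vals = []
    for cy, cx in centers.reshape(-1, 2):
        lead_vals.append(
            _disk_mean(px, img_cr + cy / pitch, img_cc + cx / pitch, roi_radius_mm / pitch)
        )
    bg_vals = []
    mids = []
    for i in range(5):
        for j in range(4):
            mids.append((centers[i, j] + centers[i, j + 1]) / 2.0)
    for i in range(4):
        for j in range(5):
            mids.append((centers[i, j] + centers[i + 1, j]) / 2.0)
    for cy, cx in mids:
        bg_vals.append(
            _disk_mean(px, img_cr + cy / pitch, img_cc + cx / pitch, roi_radius_mm / pitch)
        )
    mpv_lead = float(np.mean(lead_vals))
    mpv_background = float(np.mean(bg_vals))
    if mpv_background <= 0:
        raise EstimationError("non-positive background signal")
    return ScatterResult(
        sf=mpv_lead / mpv_background,
        mpv_lead=mpv_lead,
        mpv_background=mpv_background,
        n_cylinders_used=25,
    )


class ScatterFraction(BaseEstimator):
    """Estimator wrapper around :func:`measure_scatter_fraction`."""

    def __init__(self, grid: BeamStopGridSpec | str | None = "auto"):
        self.grid = grid

    def fit(self, image: RadiographImage, y=None):
        self.result_ = measure_scatter_fraction(image, self.grid)
        self.sf_ = self.result_.sf
        return self

    def transform(self, image=None) -> float:
        check_is_fitted(self, "sf_")
        return self.sf_


# ---------------------------------------------------------------------------
# dose arithmetic


def transmission_factor(readings: DoseReadings) -> float:
    """TF = AK+ / AK-, the phantom's air-kerma transmission, in (0, 1]."""
    return readings.ak_with_phantom_uGy / readings.ak_without_phantom_uGy


def incident_air_kerma(ak_measured_uGy: float, readings: DoseReadings) -> float:
    """Project a dosimeter-plane reading to the detector plane.

    Slot beams fall off linearly with distance along the scan, cone beams by
    the inverse square.
    """
    if ak_measured_uGy < 0:
        raise ValidationError("air kerma must be non-negative")
    ratio = readings.sdd_cm / readings.sid_cm
    if readings.beam_mode == "slot":
        return ak_measured_uGy * ratio
    return ak_measured_uGy * ratio**2


def detector_air_kerma(iak_uGy: float, tf: float) -> float:
    """DAK = IAK * TF: detector-plane air kerma behind the phantom."""
    if not (0.0 < tf <= 1.0):
        raise ValidationError(f"transmission factor {tf} outside (0, 1]")
    if iak_uGy < 0:
        raise ValidationError("air kerma must be non-negative")
    return iak_uGy * tf
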