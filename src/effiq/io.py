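"""Shared domain types and image/config/curve I/O.

The unit every measurement stage consumes is :class:`RadiographImage`: a 2-D
non-negative pixel matrix plus its pixel pitch and acquisition metadata.
Curves (eMTF, eNNPS, eDQE, eNEQ) travel as :class:`FrequencySeries`, tagged
with the reference plane their frequency axis refers to — the detector plane
or the object plane after magnification correction.

Conventions: row index increases downward (the scan / vertical direction),
column index rightward; spatial frequencies are in mm^-1; config files carry
distances in cm (as the protocol tables do) and they are kept in cm on
:class:`GeometrySetup`, whose helpers emit mm where a formula needs mm.

On-disk image format is 16-bit grayscale TIFF; the pixel pitch is carried in
the TIFF resolution tags. DICOM support requires the optional ``pydicom``
dependency and is not available in this build.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
import yaml

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "RadiographImage",
    "AcquisitionMeta",
    "GeometrySetup",
    "FrequencySeries",
    "read_image",
    "write_image",
    "load_protocol_config",
    "write_series",
    "read_series",
]

_PLANES = ("detector", "object")
_QUANTITIES = ("eMTF", "eNNPS", "eDQE", "eNEQ")


@dataclass
class AcquisitionMeta:
    """Acquisition metadata mirroring the exposure-protocol table fields."""

    system_id: str = "unknown"
    protocol: str = "chest"
    tube_voltage_kV: float = 100.0
    tube_load_mAs: float | None = None
    scan_speed: int | None = None
    sid_cm: float = 180.0
    filtration: str = "0/0"

    def __post_init__(self) -> None:
        if self.tube_voltage_kV <= 0:
            raise ValidationError("tube_voltage_kV must be positive")
        if self.sid_cm <= 0:
            raise ValidationError("sid_cm must be positive")


@dataclass
class RadiographImage:
    """A raw or linearized radiograph: pixels + pitch + metadata.

    ``linearized`` is False for raw detector units and True once the pixels
    have been mapped to kerma-proportional units by a detector-response model.
    """

    pixels: np.ndarray
    pixel_pitch_mm: float
    linearized: bool = False
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValidationError("pixels must be a 2-D matrix with >= 2 rows and columns")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixels must be finite")
        if self.pixel_pitch_mm <= 0:
            raise ValidationError("pixel_pitch_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def nyquist_mm(self) -> float:
        """Detector Nyquist frequency, 1/(2 * pitch), in mm^-1."""
        return 1.0 / (2.0 * self.pixel_pitch_mm)

    def with_pixels(self, pixels: np.ndarray, *, linearized: bool | None = None) -> "RadiographImage":
        lin = self.linearized if linearized is None else linearized
        return replace(self, pixels=pixels, linearized=lin)


@dataclass
class GeometrySetup:
    """Beam geometry: source, dosimeter, detector and object-plane distances.

    ``beam_mode`` selects the dose-distance law (slot scanners fall off
    linearly along the scan, cone beams by the inverse square).  The
    magnification m = SID/(SID - offset) maps detector-plane frequencies to
    the object plane; ``magnification_axis='none'`` forces m = 1 (used for
    the slot scan direction, whose magnification is not a simple projection).
    """

    sid_cm: float
    sdd_cm: float
    object_plane_offset_cm: float = 0.0
    beam_mode: Literal["slot", "cone"] = "cone"
    magnification_axis: Literal["measured_axis", "none"] = "measured_axis"

    def __post_init__(self) -> None:
        if not (0 < self.sdd_cm <= self.sid_cm):
            raise ValidationError("require 0 < sdd_cm <= sid_cm")
        if not (0 <= self.object_plane_offset_cm < self.sid_cm):
            raise ValidationError("require 0 <= object_plane_offset_cm < sid_cm")
        if self.beam_mode not in ("slot", "cone"):
            raise ValidationError(f"beam_mode must be 'slot' or 'cone', got {self.beam_mode!r}")

    @property
    def magnification(self) -> float:
        if self.magnification_axis == "none":
            return 1.0
        return self.sid_cm / (self.sid_cm - self.object_plane_offset_cm)


@dataclass
class FrequencySeries:
    """A uniformly sampled curve over spatial frequency.

    Frequencies start at 0, ascend with uniform spacing, in mm^-1; ``plane``
    records whether the axis is detector-plane or object-plane frequency.
    """

    frequencies: np.ndarray
    values: np.ndarray
    plane: Literal["detector", "object"] = "detector"
    quantity: str = "eMTF"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frequencies.ndim != 1 or self.frequencies.shape != self.values.shape:
            raise ValidationError("frequencies and values must be 1-D and the same length")
        if self.frequencies.size < 2:
            raise ValidationError("series needs at least 2 points")
        if abs(self.frequencies[0]) > 1e-12:
            raise ValidationError("frequencies must start at 0")
        steps = np.diff(self.frequencies)
        if steps.min() <= 0 or np.ptp(steps) > 1e-9:
            raise ValidationError("frequencies must be ascending and uniform (within 1e-9)")
        if self.plane not in _PLANES:
            raise ValidationError(f"plane must be one of {_PLANES}")

    @property
    def step(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def __len__(self) -> int:
        return int(self.frequencies.size)

    def interp(self, f: np.ndarray) -> np.ndarray:
        """Linear interpolation; no extrapolation beyond the support."""
        f = np.asarray(f, dtype=float)
        if f.min() < self.frequencies[0] - 1e-12 or f.max() > self.frequencies[-1] + 1e-12:
            from .exceptions import RangeError

            raise RangeError(
                f"requested frequencies outside support [0, {self.frequencies[-1]:g}] "
                f"of {self.quantity} curve"
            )
        return np.interp(f, self.frequencies, self.values)


# ---------------------------------------------------------------------------
# image I/O


def read_image(
    path: str | Path,
    format: str = "tiff",
    *,
    pixel_pitch_mm: float | None = None,
    meta: AcquisitionMeta | None = None,
) -> RadiographImage:
    """Read a for-processing radiograph from disk.

    Pixels are loaded unmodified (raw detector units); linearization is the
    detector-response stage's job.  The pixel pitch is taken from the TIFF
    resolution tags unless ``pixel_pitch_mm`` overrides it.
    """
    path = Path(path)
    if format == "dicom":
        raise ConfigurationError(
            "DICOM reading requires the optional 'pydicom' dependency, which is "
            "not installed; convert to 16-bit TIFF or install pydicom"
        )
    if format != "tiff":
        raise ConfigurationError(f"unsupported image format {format!r}")
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        pixels = page.asarray()
        pitch = pixel_pitch_mm
        if pitch is None:
            pitch = _pitch_from_tags(page)
    if pitch is None:
        raise ConfigurationError(
            f"no pixel pitch in TIFF header of {path.name} and no override given; "
            "pass pixel_pitch_mm explicitly"
        )
    return RadiographImage(np.asarray(pixels, dtype=float), float(pitch),
                           meta=meta or AcquisitionMeta())


def _pitch_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    unit = int(unit)
    per_mm = {2: num / den / 25.4, 3: num / den / 10.0}.get(unit)
    if per_mm is None or per_mm <= 0:
        return None
    return 1.0 / per_mm


def write_image(image: RadiographImage, path: str | Path) -> Path:
    """Write a radiograph as 16-bit grayscale TIFF with the pitch in the header.

    Raw (non-linearized) images are assumed to fit uint16; linearized images
    are stored as 32-bit float to avoid quantising kerma units.
    """
    path = Path(path)
    px = image.pixels
    if not image.linearized and px.min() >= 0 and px.max() <= 65535 and np.allclose(px, np.round(px)):
        data = px.astype(np.uint16)
    else:
        data = px.astype(np.float32)
    # pixels per cm as an exact rational so the pitch round-trips losslessly
    res = (10 * 10**7, round(image.pixel_pitch_mm * 10**7))
    tifffile.imwrite(str(path), data, resolution=(res, res), resolutionunit="CENTIMETER")
    return path


# ---------------------------------------------------------------------------
# protocol config

_MANDATORY_KEYS = ("system_id", "protocol", "tube_voltage_kV", "sid_cm", "sdd_cm", "beam_mode")


def load_protocol_config(path: str | Path) -> tuple[AcquisitionMeta, GeometrySetup]:
    """Load one system/protocol YAML config into (AcquisitionMeta, GeometrySetup).

    The shipped example configs under ``effiq/data/protocols`` replicate the
    published exposure settings for the three systems and two protocols.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path.name} is not a key/value mapping")
    return protocol_from_dict(cfg)


def protocol_from_dict(cfg: dict) -> tuple[AcquisitionMeta, GeometrySetup]:
    for key in _MANDATORY_KEYS:
        if key not in cfg or cfg[key] is None:
            raise ConfigurationError(f"missing mandatory config key: {key!r}")
    meta = AcquisitionMeta(
        system_id=str(cfg["system_id"]),
        protocol=str(cfg["protocol"]),
        tube_voltage_kV=float(cfg["tube_voltage_kV"]),
        tube_load_mAs=None if cfg.get("tube_load_mAs") is None else float(cfg["tube_load_mAs"]),
        scan_speed=None if cfg.get("scan_speed") is None else int(cfg["scan_speed"]),
        sid_cm=float(cfg["sid_cm"]),
        filtration=str(cfg.get("filtration", "0/0")),
    )
    geom = GeometrySetup(
        sid_cm=float(cfg["sid_cm"]),
        sdd_cm=float(cfg["sdd_cm"]),
        object_plane_offset_cm=float(cfg.get("object_plane_offset_cm", 0.0)),
        beam_mode=cfg["beam_mode"],
        magnification_axis=cfg.get("magnification_axis", "measured_axis"),
    )
    return meta, geom


# ---------------------------------------------------------------------------
# curve I/O


def write_series(series: FrequencySeries, path: str | Path) -> Path:
    """Write a FrequencySeries as CSV (lossless at 12 significant digits)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frequency_mm^-1", "value", "plane", "quantity"])
        for f, v in zip(series.frequencies, series.values):
            w.writerow([f"{f:.12g}", f"{v:.12g}", series.plane, series.quantity])
    return path


def read_series(path: str | Path) -> FrequencySeries:
    path = Path(path)
    if not path.exists():
        raise IOError(f"curve file not found: {path}")
    freqs, vals = [], []
    plane, quantity = "detector", "eMTF"
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            freqs.append(float(row["frequency_mm^-1"]))
            vals.append(float(row["value"]))
            plane = row["plane"]
            quantity = row["quantity"]
    return FrequencySeries(np.array(freqs), np.array(vals), plane=plane, quantity=quantity)
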