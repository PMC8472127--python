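"""Composition of eNEQ and eDQE from the measured components.

On a common object-plane frequency grid,

    eNEQ(f) = eMTF(f)^2 * (1 - SF)^2 / eNNPS(f)              [mm^-2]
    eDQE(f) = eNEQ(f) / (TF * AK * q)                        [dimensionless]

where SF is the scatter fraction, TF the phantom transmission factor, AK
the phantom-free air kerma corrected to the detector plane (uGy) and q the
photon fluence per unit air kerma (mm^-2 uGy^-1).  The AK in the eDQE
denominator is the phantom-free reading projected to the detector plane —
per the quantity's definition — not the behind-phantom DAK; pass DAK
explicitly for sensitivity runs if wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import RangeError, ValidationError
from .io import AcquisitionMeta, FrequencySeries

__all__ = ["SystemMeasurement", "resample_common_grid", "eneq", "edqe", "max_peak"]


@dataclass
class SystemMeasurement:
    """The per-system bundle the eDQE formula composes."""

    emtf: FrequencySeries
    ennps: FrequencySeries
    sf: float
    tf: float
    ak_uGy: float
    q_mm2_per_uGy: float
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        if not (0.0 <= self.sf < 1.0):
            raise ValidationError("sf must be in [0, 1)")
        if not (0.0 < self.tf <= 1.0):
            raise ValidationError("tf must be in (0, 1]")
        if self.ak_uGy <= 0 or self.q_mm2_per_uGy <= 0:
            raise ValidationError("ak and q must be positive")

    def on_common_grid(self, step: float = 0.1, fmax: float | None = None) -> "SystemMeasurement":
        emtf, ennps = resample_common_grid([self.emtf, self.ennps], step=step, fmax=fmax)
        return SystemMeasurement(emtf, ennps, self.sf, self.tf, self.ak_uGy,
                                 self.q_mm2_per_uGy, self.meta)


def resample_common_grid(
    curves: list[FrequencySeries], step: float = 0.1, fmax: float | None = None
) -> list[FrequencySeries]:
    """Linear-interpolate curves onto the shared grid {0, step, ..., fmax}.

    No extrapolation: fmax beyond any curve's support raises, naming the
    curve.  The 0.1 mm^-1 step is the statistics stage's reporting grid
    (eleven points over 0.00-1.00 per system).
    """
    if fmax is None:
        fmax = min(float(c.frequencies[-1]) for c in curves)
    n = int(round(fmax / step))
    grid = np.arange(n + 1) * step
    out = []
    for c in curves:
        if grid[-1] > c.frequencies[-1] + 1e-9:
            raise RangeError(
                f"fmax {grid[-1]:g} beyond the support of the {c.quantity} curve "
                f"(max {c.frequencies[-1]:g} mm^-1)"
            )
        out.append(FrequencySeries(grid, c.interp(grid), plane=c.plane, quantity=c.quantity))
    return out


def _check_composable(m: SystemMeasurement) -> None:
    if m.emtf.frequencies.shape != m.ennps.frequencies.shape or not np.allclose(
        m.emtf.frequencies, m.ennps.frequencies
    ):
        raise ValidationError(
            "eMTF and eNNPS must be resampled to the identical grid "
            "(use SystemMeasurement.on_common_grid)"
        )


def eneq(m: SystemMeasurement) -> FrequencySeries:
    """Effective noise equivalent quanta, eMTF^2 (1-SF)^2 / eNNPS, in mm^-2.

    Grid points with zero eNNPS are masked (NaN) with a warning; more than
    20% masked raises.
    """
    _check_composable(m)
    denom = m.ennps.values
    bad = denom <= 0
    if bad.any():
        if bad.mean() > 0.20:
            raise ValidationError(f"{int(bad.sum())} of {bad.size} eNNPS bins are zero")
        warnings.warn(f"masking {int(bad.sum())} zero eNNPS bins", stacklevel=2)
    values = np.full_like(denom, np.nan)
    values[~bad] = m.emtf.values[~bad] ** 2 * (1.0 - m.sf) ** 2 / denom[~bad]
    return FrequencySeries(m.emtf.frequencies, values, plane="object", quantity="eNEQ")


def edqe(m: SystemMeasurement) -> FrequencySeries:
    """Effective detective quantum efficiency, eNEQ / (TF * AK * q)."""
    norm = m.tf * m.ak_uGy * m.q_mm2_per_uGy
    if norm <= 0:
        raise ValidationError("TF * AK * q must be positive")
    neq = eneq(m)
    return FrequencySeries(neq.frequencies, neq.values / norm, plane="object", quantity="eDQE")


def max_peak(curve: FrequencySeries) -> tuple[float, float]:
    """(frequency, value) of the curve maximum; ties go to the lowest frequency."""
    vals = curve.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValidationError("curve has no finite values")
    masked = np.where(finite, vals, -np.inf)
    i = int(np.argmax(masked))
    return float(curve.frequencies[i]), float(vals[i])
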