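"""Detector response: mean pixel value vs air kerma, and image linearization.

The response is measured from an exposure series (ten dose levels in the
reference protocol), fitted either as a straight line (flat-panel detectors)
or a fifth-order polynomial (slot scanners with a non-linear response), and
then inverted to map raw pixel values to kerma-proportional units before any
noise or resolution analysis.

The inversion method is a numerical one: the fitted forward model is sampled
on a fine grid over its valid kerma range and inverted by monotone
piecewise-cubic (PCHIP) interpolation, which works identically for the
linear and quintic kinds.  Monotonicity of the fit is enforced by rejection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ValidationError
from .io import RadiographImage

__all__ = ["ResponseModel", "DetectorResponse", "fit_response", "linearize"]

_KINDS = {"linear": 1, "polynomial5": 5}
_N_INVERSE_SAMPLES = 1000


@dataclass
class ResponseModel:
    """A fitted pixel-value-vs-kerma model (coefficients intercept-first)."""

    kind: str
    coefficients: tuple[float, ...]
    valid_range_uGy: tuple[float, float]
    r_squared: float

    def forward(self, dak_uGy: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(dak_uGy, dtype=float), self.coefficients)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "kind": self.kind,
                "coefficients": list(self.coefficients),
                "valid_range_uGy": list(self.valid_range_uGy),
                "r_squared": self.r_squared,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ResponseModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(d["kind"], tuple(d["coefficients"]), tuple(d["valid_range_uGy"]), d["r_squared"])


class DetectorResponse(TransformerMixin, BaseEstimator):
    """Scikit-learn style estimator for the detector response.

    ``fit(dak, mpv)`` performs the least-squares fit; ``transform`` maps a
    raw :class:`RadiographImage` (or bare array) through the inverse response
    into kerma-proportional units (uGy).

    Parameters
    ----------
    kind : {'linear', 'polynomial5'}
        Polynomial degree of the response model.
    clamp_tolerance : float
        Maximum fraction of pixels allowed to fall outside the invertible
        output range before ``transform`` raises (they are clamped and
        counted otherwise).

    Attributes
    ----------
    model_ : ResponseModel
    coefficients_ : ndarray, intercept first
    r_squared_ : float
    valid_range_ : (min_dak, max_dak) in uGy
    n_clamped_ : int, pixels clamped by the most recent transform
    """

    def __init__(self, kind: str = "linear", clamp_tolerance: float = 0.01):
        self.kind = kind
        self.clamp_tolerance = clamp_tolerance

    # -- fitting ------------------------------------------------------------

    def fit(self, dak_uGy, mpv=None) -> "DetectorResponse":
        if self.kind not in _KINDS:
            raise ValidationError(f"kind must be one of {sorted(_KINDS)}, got {self.kind!r}")
        degree = _KINDS[self.kind]
        if mpv is None:  # accept a list of (dak, mpv) pairs
            pairs = np.asarray(dak_uGy, dtype=float)
            dak_uGy, mpv = pairs[:, 0], pairs[:, 1]
        x = np.asarray(dak_uGy, dtype=float).ravel()
        y = np.asarray(mpv, dtype=float).ravel()
        n_min = degree + 1
        if x.size < n_min:
            raise ValidationError(f"{self.kind} fit needs at least {n_min} samples, got {x.size}")
        if np.unique(x).size != x.size:
            raise ValidationError("dak values must be distinct")
        poly = np.polynomial.Polynomial.fit(x, y, degree).convert()
        coeffs = np.zeros(degree + 1)
        coeffs[: poly.coef.size] = poly.coef
        yhat = np.polynomial.polynomial.polyval(x, coeffs)
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        lo, hi = float(x.min()), float(x.max())
        grid = np.linspace(lo, hi, _N_INVERSE_SAMPLES)
        fwd = np.polynomial.polynomial.polyval(grid, coeffs)
        d = np.diff(fwd)
        if np.any(d <= 0):
            turn = grid[int(np.argmax(d <= 0))]
            raise ValidationError(
                f"fitted {self.kind} response is non-monotone over [{lo:g}, {hi:g}] uGy "
                f"(turning point near {turn:.4g} uGy)"
            )
        self.coefficients_ = coeffs
        self.r_squared_ = r2
        self.valid_range_ = (lo, hi)
        self.model_ = ResponseModel(self.kind, tuple(coeffs), (lo, hi), r2)
        self._inverse = PchipInterpolator(fwd, grid, extrapolate=False)
        self._output_range = (float(fwd[0]), float(fwd[-1]))
        self.n_clamped_ = 0
        return self

    # -- application --------------------------------------------------------

    def predict(self, dak_uGy) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.forward(dak_uGy)

    def inverse(self, mpv) -> np.ndarray:
        """Map pixel values back to kerma (uGy), clamping outside the range."""
        check_is_fitted(self, "model_")
        v = np.asarray(mpv, dtype=float)
        lo, hi = self._output_range
        clipped = np.clip(v, lo, hi)
        self.n_clamped_ = int(np.sum((v < lo) | (v > hi)))
        return self._inverse(clipped)

    def transform(self, image):
        check_is_fitted(self, "model_")
        if isinstance(image, RadiographImage):
            if image.linearized:
                raise ValidationError("image is already linearized")
            pixels = image.pixels
        else:
            pixels = np.asarray(image, dtype=float)
        out = self.inverse(pixels)
        frac = self.n_clamped_ / out.size
        if frac > self.clamp_tolerance:
            raise ValidationError(
                f"{frac:.1%} of pixels fall outside the invertible response range "
                f"(tolerance {self.clamp_tolerance:.1%})"
            )
        if isinstance(image, RadiographImage):
            return image.with_pixels(out, linearized=True)
        return out


# -- spec-surface wrappers ---------------------------------------------------


def fit_response(samples, kind: str = "linear") -> ResponseModel:
    """Fit the response from (dak_uGy, mean_pixel_value) pairs."""
    return DetectorResponse(kind=kind).fit(samples).model_


def linearize(image: RadiographImage, model: ResponseModel) -> RadiographImage:
    """Map a raw image to kerma-proportional units through ``model``'s inverse."""
    est = DetectorResponse(kind=model.kind)
    lo, hi = model.valid_range_uGy
    grid = np.linspace(lo, hi, _N_INVERSE_SAMPLES)
    est.coefficients_ = np.asarray(model.coefficients)
    est.r_squared_ = model.r_squared
    est.valid_range_ = model.valid_range_uGy
    est.model_ = model
    fwd = model.forward(grid)
    if np.any(np.diff(fwd) <= 0):
        raise ValidationError("model is non-monotone; cannot invert")
    est._inverse = PchipInterpolator(fwd, grid, extrapolate=False)
    est._output_range = (float(fwd[0]), float(fwd[-1]))
    est.n_clamped_ = 0
    return est.transform(image)
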