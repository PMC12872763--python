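"""Pixel-to-millimetre calibration.

A scale bar imaged at a fixed working distance maps 0 px to 0 mm, so the
conversion coefficient ``c`` (mm per pixel) is estimated by least squares
through the origin over (pixel count, true length) observations:

    c = sum(mm_i * px_i) / sum(px_i ** 2)

Lengths scale as ``v * c``, areas as ``v * c**2`` and per-pixel curvatures as
``v / c``.  The rig default used throughout the package is 0.042 mm/px.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

#: mm-per-pixel coefficient of the reference acquisition rig.
DEFAULT_MM_PER_PX = 0.042


@dataclass(frozen=True)
class ScaleObservation:
    """One scale-bar reading: a known physical length and its pixel extent."""

    true_length_mm: float
    pixel_count: float

    def __post_init__(self) -> None:
        if not (self.true_length_mm > 0 and self.pixel_count > 0):
            raise ValueError(
                "scale observation requires strictly positive length and pixel count, "
                f"got ({self.true_length_mm} mm, {self.pixel_count} px)"
            )


@dataclass(frozen=True)
class CalibrationModel:
    """The mm-per-pixel conversion coefficient ``c``."""

    c: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c) and self.c > 0):
            raise ValueError(f"conversion coefficient must be finite and > 0, got {self.c}")


def fit_conversion(observations: Sequence[ScaleObservation]) -> CalibrationModel:
    """Fit the through-origin linear model mm = c * px.

    Parameters
    ----------
    observations
        At least one :class:`ScaleObservation`.  For exactly proportional
        data the fit is exact (zero residuals).

    Returns
    -------
    CalibrationModel
        The least-squares coefficient ``c = Σ mm_i·px_i / Σ px_i²``.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("fit_conversion requires at least one observation")
    num = sum(o.true_length_mm * o.pixel_count for o in obs)
    den = sum(o.pixel_count**2 for o in obs)
    return CalibrationModel(c=num / den)


def px_to_mm(value: float, model: CalibrationModel, power: int = 1) -> float:
    """Convert a pixel-space quantity to physical units.

    ``power`` selects the dimension: 1 for lengths (``v·c``), 2 for areas
    (``v·c²``), -1 for per-pixel curvatures (``v/c`` gives mm⁻¹).
    """
    if power == 1:
        return value * model.c
    if power == 2:
        return value * model.c**2
    if power == -1:
        return value / model.c
    raise ValueError(f"power must be one of {{1, 2, -1}}, got {power}")


def reference_error(measured_mm: float, true_mm: float) -> tuple[float, float]:
    """Signed and absolute error of a measurement against a reference object.

    Returns ``(true - measured, |true - measured|)``; the signed convention
    is "true value minus measured value".
    """
    if not (math.isfinite(measured_mm) and math.isfinite(true_mm)):
        raise ValueError("reference_error requires finite inputs")
    signed = true_mm - measured_mm
    return signed, abs(signed)
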