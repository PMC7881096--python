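"""Non-uniform illumination correction on the CIELAB lightness channel.

Shading is modeled as a smooth multiplicative field: the illumination
estimate ``I(x, y)`` is a wide Gaussian blur of the L* channel (standard
deviation defaulting to half the largest image dimension — a low-pass filter
that keeps only the global trend), and the corrected lightness is

    G(x, y) = F(x, y) / I(x, y) * C,      C = mean(F) / mean(F / I)

so the overall luminosity of the corrected image matches the original.
The correction touches only L*; dividing a* / b* (or raw RGB) by a shading
field would shift hue and chroma unpredictably, so those channels are
returned untouched. The step is optional in the calibration pipeline:
it helps when vignetting or side lighting is visible and is a no-op (to
within numerical noise) under uniform illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "IlluminationField",
    "DegenerateInputError",
    "estimate_illumination",
    "correct_illumination",
    "correct_lab_image",
]

_DIV_EPS = 1e-6  # guards division where the estimated field is ~0


class DegenerateInputError(ValueError):
    """The luminosity channel carries no signal (all zero)."""


@dataclass
class IlluminationField:
    """Estimated illumination surface with its blur scale and the
    renormalization constant that preserves mean luminosity."""

    I: np.ndarray
    sigma: float
    C: float

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=float)
        if self.I.ndim != 2:
            raise ValueError("illumination field must be 2-D")
        if not (np.isfinite(self.C) and self.C > 0):
            raise ValueError("renormalization constant must be positive and finite")


def estimate_illumination(L: np.ndarray, sigma: "float | None" = None) -> IlluminationField:
    """Estimate the illumination surface of a lightness channel.

    Gaussian blur with reflective boundaries and a normalized kernel, so a
    constant field is its own estimate and the mean of L is preserved.
    ``sigma`` defaults to ``max(H, W) / 2``.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2:
        raise ValueError("L must be a 2-D channel")
    if not np.all(np.isfinite(L)) or np.any(L < 0):
        raise ValueError("L must be finite and non-negative")
    if not np.any(L > 0):
        raise DegenerateInputError("luminosity channel is identically zero")
    if sigma is None:
        sigma = max(L.shape) / 2.0
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    I = gaussian_filter(L, sigma=float(sigma), mode="reflect")
    C = float(np.mean(L) / np.mean(L / np.maximum(I, _DIV_EPS)))
    return IlluminationField(I=I, sigma=float(sigma), C=C)


def correct_illumination(lab_image: np.ndarray, field: IlluminationField) -> np.ndarray:
    """Divide L* by the illumination field and renormalize; a*/b* untouched.

    The corrected L* is clipped to [0, 100]; before clipping its mean equals
    the original mean exactly (that is what C is for).
    """
    lab = np.asarray(lab_image, dtype=float)
    if lab.ndim != 3 or lab.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) LAB image")
    if lab.shape[:2] != field.I.shape:
        raise ValueError(
            f"field shape {field.I.shape} does not match image {lab.shape[:2]}"
        )
    out = lab.copy()
    corrected = lab[..., 0] / np.maximum(field.I, _DIV_EPS) * field.C
    out[..., 0] = np.clip(corrected, 0.0, 100.0)
    return out


def correct_lab_image(lab_image: np.ndarray, sigma: "float | None" = None) -> np.ndarray:
    """Convenience one-step correction: estimate the field from the image's
    own L* channel, then apply it."""
    lab = np.asarray(lab_image, dtype=float)
    field = estimate_illumination(lab[..., 0], sigma=sigma)
    return correct_illumination(lab, field)
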