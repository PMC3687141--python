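"""Rendering of stimulus fields to calibrated grayscale images.

A Gabor micropattern is a sine grating (positive sine phase at the
envelope center) under a circular Gaussian envelope.  Element
modulations sum linearly on a mean-luminance background, are clipped to
[0, 1] and quantized to the display bit depth.  Luminance is handled as
a normalized mean level; no gamma model is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .field_fill import StimulusField

__all__ = [
    "GaborSpec",
    "DisplaySpec",
    "render_gabor",
    "compose_field_image",
    "frames_for_duration",
    "save_png",
    "load_png",
]


@dataclass(frozen=True)
class GaborSpec:
    """Gabor carrier/envelope parameters (deg, Michelson contrast)."""

    wavelength: float = 0.30
    sigma: float = 0.11
    contrast: float = 0.90
    phase: float = 0.0  # radians; 0 = positive sine at the center

    def __post_init__(self) -> None:
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must be in (0, 1]")
        if self.sigma <= 0 or self.wavelength <= 0:
            raise ValueError("sigma and wavelength must be positive")

    @property
    def spatial_frequency(self) -> float:
        """Carrier frequency in cycles/deg."""
        return 1.0 / self.wavelength


@dataclass(frozen=True)
class DisplaySpec:
    """Display model.  pixels_per_degree defaults to 20 px per 0.30 deg
    carrier cycle; mean luminance is a normalized 0.5."""

    pixels_per_degree: float = 20.0 / 0.30
    refresh_rate: float = 75.0
    mean_level: float = 0.5
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0 or self.refresh_rate <= 0:
            raise ValueError("pixels_per_degree and refresh_rate must be > 0")


TRUNCATION_SIGMAS = 4.0  # envelope < 4e-4 of peak beyond this radius


def render_gabor(gspec: GaborSpec, ppd: float,
                 orientation_deg: float = 0.0) -> np.ndarray:
    """Luminance-modulation patch m(x, y) for one element.

    m = contrast * sin(2 pi u / lambda + phase) * exp(-(x^2+y^2)/(2 sigma^2))
    with u the coordinate perpendicular to the stripe axis.  The patch is
    truncated at radius 4 sigma and has odd side length so that its
    center pixel sits exactly on the element center.
    """
    radius_px = int(math.ceil(TRUNCATION_SIGMAS * gspec.sigma * ppd))
    ax = np.arange(-radius_px, radius_px + 1) / ppd
    x, y = np.meshgrid(ax, ax)
    th = math.radians(orientation_deg)
    u = -x * math.sin(th) + y * math.cos(th)
    r2 = x * x + y * y
    envelope = np.exp(-r2 / (2.0 * gspec.sigma ** 2))
    envelope[r2 > (TRUNCATION_SIGMAS * gspec.sigma) ** 2] = 0.0
    carrier = np.sin(2.0 * math.pi * u / gspec.wavelength + gspec.phase)
    return gspec.contrast * carrier * envelope


def compose_field_image(field: StimulusField, display: DisplaySpec,
                        gspec: GaborSpec | None = None) -> np.ndarray:
    """Quantized grayscale image of a stimulus field.

    Degrees map to pixels at ``pixels_per_degree`` with +y up (raster row
    0 is the top of the field).  Returns a uint8 (or wider) integer array
    of side round(extent * ppd).
    """
    gspec = gspec or GaborSpec()
    ppd = display.pixels_per_degree
    side = int(round(field.field_spec.extent * ppd))
    canvas = np.zeros((side, side))
    center = (side - 1) / 2.0
    for e in field.elements:
        patch = render_gabor(gspec, ppd, e.orientation)
        rad = patch.shape[0] // 2
        col = int(round(center + e.x * ppd))
        row = int(round(center - e.y * ppd))
        r0, r1 = row - rad, row + rad + 1
        c0, c1 = col - rad, col + rad + 1
        pr0, pc0 = max(0, -r0), max(0, -c0)
        r0, c0 = max(0, r0), max(0, c0)
        r1, c1 = min(side, r1), min(side, c1)
        if r1 <= r0 or c1 <= c0:
            continue
        canvas[r0:r1, c0:c1] += patch[pr0:pr0 + (r1 - r0), pc0:pc0 + (c1 - c0)]
    levels = (1 << display.bit_depth) - 1
    lum = np.clip(display.mean_level * (1.0 + canvas), 0.0, 1.0)
    quantized = np.floor(lum * levels + 0.5).astype(
        np.uint8 if display.bit_depth <= 8 else np.uint16)
    return quantized


def frames_for_duration(seconds: float, refresh_rate: float = 75.0) -> int:
    """Frame count for a nominal duration (round half up, minimum 1)."""
    if seconds <= 0:
        raise ValueError("duration must be positive")
    return max(1, int(math.floor(seconds * refresh_rate + 0.5)))


def save_png(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(image, mode="L" if image.dtype == np.uint8 else "I;16").save(path)
    return path


def load_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path))
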