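"""Color-signal extraction from titration beaker images.

A webcam frame of the reaction beaker is reduced to a single color reading by
averaging the R, G and B channels over an operator-chosen rectangular sampling
region, then converting the averaged triple to the Hue angle of the HSI
(hue-saturation-intensity) color model.  Hue is the analytical signal of
choice in turbid dairy dispersions because it depends only on channel
*differences*: it is invariant to a uniform illumination gain and to the
additive achromatic ("whitening") offset that milk turbidity introduces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ImageFrame",
    "SamplingRegion",
    "ColorReading",
    "SmallRegionWarning",
    "rgb_to_hue",
    "average_rgb",
    "make_reading",
]


class SmallRegionWarning(UserWarning):
    """Sampling region below the recommended 8 x 8 pixel minimum."""


@dataclass(frozen=True)
class ImageFrame:
    """One 8-bit RGB frame of the titration beaker.

    Parameters
    ----------
    pixels:
        ``(H, W, 3)`` uint8 array.  An alpha channel, if present in the source
        file, must be stripped before construction.
    frame_id:
        Opaque label, typically the source file name.
    capture_index:
        Ordinal position of the frame in the run.
    """

    pixels: np.ndarray
    frame_id: str = ""
    capture_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("frame must contain at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class SamplingRegion:
    """Rectangular color-sampling area, 0-based top-left origin.

    ``x0``/``y0`` are inclusive; the region spans ``width`` columns and
    ``height`` rows in the usual half-open raster sense.  Regions smaller than
    8 x 8 pixels are allowed but trigger :class:`SmallRegionWarning` when
    sampled, since small areas are vulnerable to specular reflections and
    floating bubbles.
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("region width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("region origin must be non-negative")

    @property
    def too_small(self) -> bool:
        return self.width < 8 or self.height < 8

    def validate_within(self, frame: ImageFrame) -> None:
        if self.x0 + self.width > frame.width or self.y0 + self.height > frame.height:
            raise ValueError(
                f"region {self} exceeds frame bounds "
                f"({frame.height} x {frame.width})"
            )


@dataclass(frozen=True)
class ColorReading:
    """Region-averaged R, G, B (0-255 scale) and the derived HSI hue.

    ``hue`` is in degrees in [0, 360) and is present iff the reading is not
    achromatic (r = g = b gives zero chroma and no defined hue).
    """

    r: float
    g: float
    b: float
    hue: Optional[float] = field(default=None)
    achromatic: bool = field(default=False)

    def __post_init__(self) -> None:
        for name, v in (("r", self.r), ("g", self.g), ("b", self.b)):
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.achromatic and self.hue is not None:
            raise ValueError("achromatic reading cannot carry a hue")
        if not self.achromatic and self.hue is None:
            raise ValueError("chromatic reading must carry a hue")


def rgb_to_hue(r: float, g: float, b: float) -> Optional[float]:
    """HSI-model hue in degrees, or ``None`` for achromatic input.

    theta = arccos( ((r-g) + (r-b)) / (2 sqrt((r-g)^2 + (r-b)(g-b))) );
    hue = theta when b <= g, else 360 - theta.  Pure red maps to 0 degrees,
    green to 120, blue to 240.  The formula uses channel differences only,
    hence hue is invariant under a common additive offset and a common
    multiplicative gain -- the property that makes it robust to lighting
    drift and matrix whitening.
    """
    for name, v in (("r", r), ("g", g), ("b", b)):
        if not 0.0 <= v <= 255.0:
            raise ValueError(f"{name}={v} outside [0, 255]")
    rg = r - g
    rb = r - b
    gb = g - b
    den_sq = rg * rg + rb * gb
    if den_sq <= 0.0:
        # r = g = b: zero chroma, hue undefined.  (den_sq > 0 otherwise.)
        return None
    cos_theta = 0.5 * (rg + rb) / math.sqrt(den_sq)
    theta = math.degrees(math.acos(min(1.0, max(-1.0, cos_theta))))
    hue = theta if b <= g else 360.0 - theta
    return hue % 360.0


def make_reading(r: float, g: float, b: float) -> ColorReading:
    """Build a :class:`ColorReading` from mean channel values."""
    hue = rgb_to_hue(r, g, b)
    return ColorReading(r=r, g=g, b=b, hue=hue, achromatic=hue is None)


def average_rgb(frame: ImageFrame, region: SamplingRegion) -> ColorReading:
    """Average R, G, B over the sampling region, then derive the hue.

    Averaging precedes hue conversion: hue is computed on the mean triple,
    never averaged over per-pixel hues (circular means of angles near the
    0/360 wrap are ill-behaved).  Means are kept in floating point.
    """
    region.validate_within(frame)
    if region.too_small:
        warnings.warn(
            f"sampling region {region.width}x{region.height} is below the "
            "recommended 8x8 pixel minimum",
            SmallRegionWarning,
            stacklevel=2,
        )
    patch = frame.pixels[
        region.y0 : region.y0 + region.height,
        region.x0 : region.x0 + region.width,
    ].astype(np.float64)
    r, g, b = patch.reshape(-1, 3).mean(axis=0)
    return make_reading(float(r), float(g), float(b))
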