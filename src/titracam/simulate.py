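"""Synthetic titration runs with known ground truth.

Replaces the physical apparatus (burette + beaker + webcam) with a generative
model: each RGB channel follows a logistic transition between the indicator's
start and end colors, centered at the stoichiometric endpoint
``V* = blank + amount / (molarity x 1000)`` with shared steepness ``k``.  An
optional mid-transition anchor bends the path so it passes through the
printed transition color at ``V*``.  On top of the clean trajectory the
generator applies, in camera order: turbid-matrix whitening (affine blend
toward white — hue-preserving), a multiplicative illumination gain drift,
additive Gaussian sensor noise, clamping to [0, 255] and 8-bit quantization.

Built-in indicator profiles are anchored at measured beaker colors:

* ``calcein_milk`` — yellow-green (206, 223, 89) -> dirty orange (205, 168, 114);
  the Green channel carries the jump (~55 units), Red barely moves.
* ``hnb_water``   — pink (117, 33, 114) -> blue (13, 31, 130) through purple
  (76, 29, 118); Red and Hue carry the jump, Green is nearly flat.
* ``hnb_milk``    — light pink (193, 132, 164) -> light blue (104, 152, 178)
  through gray-purple (143, 136, 154): the whitened (pastel) milk-matrix
  variant of the HNB transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import expit

from .color import ImageFrame, SamplingRegion, make_reading
from .endpoint import DosePoint, TitrationCurve

__all__ = [
    "IndicatorProfile",
    "SimulationConfig",
    "FrameLayout",
    "SimulationResult",
    "PROFILES",
    "true_endpoint",
    "simulate_curve",
    "render_frames",
]

RGB = Tuple[float, float, float]


@dataclass(frozen=True)
class IndicatorProfile:
    """Color anchors and transition steepness driving the simulator.

    ``steepness`` is the logistic rate k in 1/mL; the default 40/mL gives a
    10-90% transition width of ~0.11 mL, comparable to the step-like jumps
    seen on real curves.  ``jump_scale`` rescales the start->end color span
    about the transition midpoint, a stand-in for indicator-concentration
    effects on jump magnitude.
    """

    name: str
    color_start: RGB
    color_end: RGB
    mid_anchor: Optional[RGB] = None
    steepness: float = 40.0
    indicator: str = "custom"
    jump_scale: float = 1.0

    def __post_init__(self) -> None:
        for anchor in (self.color_start, self.color_end, self.mid_anchor):
            if anchor is None:
                continue
            if len(anchor) != 3 or any(not 0 <= c <= 255 for c in anchor):
                raise ValueError(f"color anchor {anchor} outside [0, 255]^3")
        if self.color_start == self.color_end:
            raise ValueError("start and end colors must differ in at least one channel")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")


PROFILES: Dict[str, IndicatorProfile] = {
    "calcein_milk": IndicatorProfile(
        name="calcein_milk",
        color_start=(206.0, 223.0, 89.0),
        color_end=(205.0, 168.0, 114.0),
        indicator="calcein",
    ),
    "hnb_water": IndicatorProfile(
        name="hnb_water",
        color_start=(117.0, 33.0, 114.0),
        color_end=(13.0, 31.0, 130.0),
        mid_anchor=(76.0, 29.0, 118.0),
        indicator="hnb",
    ),
    "hnb_milk": IndicatorProfile(
        name="hnb_milk",
        color_start=(193.0, 132.0, 164.0),
        color_end=(104.0, 152.0, 178.0),
        mid_anchor=(143.0, 136.0, 154.0),
        indicator="hnb",
    ),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth chemistry plus camera imperfections for one run.

    ``gain_drift`` is the (start, end) multiplicative illumination factor,
    interpolated linearly over the run; ``whitening`` is the affine blend
    fraction toward pure white emulating matrix turbidity; ``quantize``
    rounds the final signal to the 8-bit grid as a camera would (disable for
    continuous-signal analyses).  ``max_volume`` defaults to 1 mL past the
    stoichiometric endpoint.
    """

    ca_amount: float  # µmol
    molarity: float = 0.025  # mol/L EDTA
    blank_volume: float = 0.0  # mL consumed by matrix + indicator
    increment: float = 0.02  # mL per dose step
    max_volume: Optional[float] = None
    noise_sd: float = 0.0  # channel units
    gain_drift: Tuple[float, float] = (1.0, 1.0)
    whitening: float = 0.0
    seed: int = 0
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.ca_amount < 0:
            raise ValueError("calcium amount must be non-negative")
        if self.molarity <= 0:
            raise ValueError("molarity must be positive")
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.whitening < 1.0:
            raise ValueError("whitening must lie in [0, 1)")
        if any(g <= 0 for g in self.gain_drift):
            raise ValueError("gain factors must be positive")


def true_endpoint(config: SimulationConfig) -> float:
    """Stoichiometric endpoint V* = blank + amount / (molarity x 1000), in mL."""
    v_star = config.blank_volume + config.ca_amount / (config.molarity * 1000.0)
    if config.max_volume is not None and v_star > config.max_volume:
        raise ValueError(
            f"true endpoint {v_star:.3f} mL exceeds max_volume {config.max_volume} mL"
        )
    return v_star


@dataclass(frozen=True)
class SimulationResult:
    curve: TitrationCurve
    true_endpoint: float
    profile: IndicatorProfile
    config: SimulationConfig


def _clean_trajectory(
    profile: IndicatorProfile, volumes: np.ndarray, v_star: float
) -> np.ndarray:
    """Noise-free (n, 3) color path: logistic blend plus optional mid-anchor bump."""
    s = expit(profile.steepness * (volumes - v_star))[:, None]
    start = np.asarray(profile.color_start, dtype=float)
    end = np.asarray(profile.color_end, dtype=float)
    mid_nominal = 0.5 * (start + end)
    if profile.jump_scale != 1.0:
        half = 0.5 * profile.jump_scale * (end - start)
        start, end = mid_nominal - half, mid_nominal + half
    path = start + (end - start) * s
    if profile.mid_anchor is not None:
        # 4 s (1 - s) equals 1 exactly at V* and vanishes on both plateaus,
        # so the path passes through the printed transition color at V*.
        bump = np.asarray(profile.mid_anchor, dtype=float) - 0.5 * (start + end)
        path = path + bump * 4.0 * s * (1.0 - s)
    return path


def simulate_curve(profile: IndicatorProfile, config: SimulationConfig) -> SimulationResult:
    """Generate a full titration curve with known ground truth.

    Camera-order post-processing: whitening blend, gain drift, Gaussian noise
    (seeded), clamp to [0, 255], optional 8-bit rounding.  Identical seeds
    give bit-identical curves.
    """
    v_star = true_endpoint(config)
    max_v = config.max_volume if config.max_volume is not None else v_star + 1.0
    n_steps = int(round(max_v / config.increment))
    volumes = np.arange(n_steps + 1) * config.increment
    signal = _clean_trajectory(profile, volumes, v_star)

    w = config.whitening
    signal = w * 255.0 + (1.0 - w) * signal
    g0, g1 = config.gain_drift
    gain = np.linspace(g0, g1, len(volumes))[:, None]
    signal = signal * gain
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    signal = np.clip(signal, 0.0, 255.0)
    if config.quantize:
        signal = np.rint(signal)

    points = [
        DosePoint(volume=float(v), reading=make_reading(*map(float, rgb)))
        for v, rgb in zip(volumes, signal)
    ]
    curve = TitrationCurve(
        points=points,
        indicator=profile.indicator,
        increment=config.increment,
        metadata={
            "profile": profile.name,
            "seed": config.seed,
            "noise_sd": config.noise_sd,
            "whitening": config.whitening,
            "gain_drift": list(config.gain_drift),
        },
    )
    return SimulationResult(curve=curve, true_endpoint=v_star, profile=profile, config=config)


@dataclass(frozen=True)
class FrameLayout:
    """Geometry and imperfections of rendered beaker frames.

    The recommended ROI is written to the layout manifest; speckle (saturated
    white pixels emulating specular reflections and bubbles) is confined to
    the area *outside* the ROI.
    """

    width: int = 48
    height: int = 48
    roi: SamplingRegion = field(default_factory=lambda: SamplingRegion(12, 12, 24, 24))
    noise_sd: float = 0.0
    speckle_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.roi.x0 + self.roi.width > self.width or self.roi.y0 + self.roi.height > self.height:
            raise ValueError("ROI must lie inside the frame")
        if not 0.0 <= self.speckle_fraction < 1.0:
            raise ValueError("speckle_fraction must lie in [0, 1)")


def render_frames(
    curve: TitrationCurve, layout: FrameLayout, seed: int = 0
) -> List[ImageFrame]:
    """Render each dose point as a flat color rectangle plus camera artifacts.

    With zero noise and zero speckle, averaging the ROI of frame *i*
    reproduces the curve's i-th color exactly (8-bit curves only).  Per-frame
    randomness is spawned from ``seed`` so stacks are reproducible.
    """
    h, wd = layout.height, layout.width
    outside = np.ones((h, wd), dtype=bool)
    outside[
        layout.roi.y0 : layout.roi.y0 + layout.roi.height,
        layout.roi.x0 : layout.roi.x0 + layout.roi.width,
    ] = False
    outside_idx = np.flatnonzero(outside.ravel())

    frames: List[ImageFrame] = []
    child_seeds = np.random.SeedSequence(seed).spawn(len(curve.points))
    for i, (point, ss) in enumerate(zip(curve.points, child_seeds)):
        rng = np.random.default_rng(ss)
        base = np.array([point.reading.r, point.reading.g, point.reading.b])
        pixels = np.broadcast_to(base, (h, wd, 3)).astype(float).copy()
        if layout.noise_sd > 0:
            pixels += rng.normal(0.0, layout.noise_sd, size=pixels.shape)
        if layout.speckle_fraction > 0 and outside_idx.size:
            n_speckle = int(round(layout.speckle_fraction * outside_idx.size))
            if n_speckle:
                chosen = rng.choice(outside_idx, size=n_speckle, replace=False)
                flat = pixels.reshape(-1, 3)
                flat[chosen] = 255.0
        pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
        frames.append(
            ImageFrame(pixels=pixels, frame_id=f"frame_{i:04d}", capture_index=i)
        )
    return frames
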