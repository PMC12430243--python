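"""Titration-curve assembly and endpoint detection.

A titration curve pairs cumulative titrant volume with the color reading of
the corresponding beaker frame.  The equivalence point manifests as a sharp
jump in one or more color signals; this module locates it either by fitting a
four-parameter logistic and reporting its inflection volume (default:
increment-independent and noise-averaging) or by the midpoint of the steepest
adjacent volume pair after smoothing (``max_slope``, the graphical reading a
human operator would make).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .color import ColorReading
from .errors import FitFailureError, NoSignalError, NoTransitionError

__all__ = [
    "DosePoint",
    "TitrationCurve",
    "EndpointResult",
    "ChannelScore",
    "ChannelRanking",
    "CHANNELS",
    "RECOMMENDED_CHANNELS",
    "extract_channel",
    "smooth",
    "detect_endpoint",
    "rank_channels",
]

CHANNELS = ("R", "G", "B", "Hue")

#: Per-indicator channel recommendation: calcein's yellow-green -> orange
#: transition moves mostly Green; HNB's pink -> blue transition moves mostly
#: Red; Hue works for both and is lighting-robust.
RECOMMENDED_CHANNELS: Dict[str, Tuple[str, str]] = {
    "calcein": ("G", "Hue"),
    "hnb": ("R", "Hue"),
}


@dataclass(frozen=True)
class DosePoint:
    """One dose step: cumulative titrant volume (mL) and the color reading."""

    volume: float
    reading: ColorReading

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("volume must be non-negative")


@dataclass
class TitrationCurve:
    """Ordered (volume, color) series for one titration run.

    Volumes must be strictly increasing.  ``indicator`` is ``"calcein"`` or
    ``"hnb"`` when known; ``increment`` is the nominal dose step in mL.
    """

    points: List[DosePoint]
    indicator: Optional[str] = None
    indicator_conc: Optional[float] = None
    increment: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vols = [p.volume for p in self.points]
        if any(b <= a for a, b in zip(vols, vols[1:])):
            raise ValueError("dose volumes must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([p.volume for p in self.points], dtype=float)

    def rgb(self) -> np.ndarray:
        return np.array(
            [(p.reading.r, p.reading.g, p.reading.b) for p in self.points],
            dtype=float,
        )

    def step(self) -> float:
        """Dose increment: declared if available, else the median volume step."""
        if self.increment is not None:
            return float(self.increment)
        if len(self.points) < 2:
            raise ValueError("cannot infer increment from < 2 points")
        return float(np.median(np.diff(self.volumes)))


@dataclass(frozen=True)
class EndpointResult:
    """Detected endpoint volume and the shape of the jump that produced it."""

    v_endpoint: float
    channel: str
    jump: float
    sharpness: float
    method: str
    baseline_noise: float
    warnings: Tuple[str, ...] = ()


def extract_channel(curve: TitrationCurve, channel: str) -> Tuple[np.ndarray, np.ndarray]:
    """Return the ``(volumes, signal)`` series for one channel.

    The Hue series is unwrapped: a step between consecutive points larger
    than 180 degrees is interpreted as a wrap and the later values are
    shifted by a multiple of 360 to restore continuity, so unwrapped hues
    may leave [0, 360).  Achromatic points carry the last defined hue
    forward; leading achromatic points are dropped together with their
    volumes.
    """
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
    vols = curve.volumes
    if channel != "Hue":
        idx = {"R": 0, "G": 1, "B": 2}[channel]
        return vols, curve.rgb()[:, idx]

    hues = [p.reading.hue for p in curve.points]
    first = next((i for i, h in enumerate(hues) if h is not None), None)
    if first is None:
        raise NoSignalError("all points are achromatic: no hue signal")
    vols = vols[first:]
    filled = []
    last = hues[first]
    for h in hues[first:]:
        if h is not None:
            last = h
        filled.append(last)
    unwrapped = np.unwrap(np.asarray(filled, dtype=float), period=360.0)
    return vols, unwrapped


def smooth(series: Sequence[float], window: int) -> np.ndarray:
    """Centered moving average with shrinking symmetric windows at the ends.

    ``window`` must be odd; ``window=1`` is the identity.  Near the series
    ends the half-width shrinks so the window stays symmetric and inside the
    data (the first and last points are returned unchanged).
    """
    values = np.asarray(series, dtype=float)
    n = values.size
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h : i + h + 1].mean()
    return out


def _logistic(v: np.ndarray, a: float, d: float, k: float, v0: float) -> np.ndarray:
    return a + (d - a) * expit(k * (v - v0))


def _plateau_stats(
    vols: np.ndarray, sig: np.ndarray, v_ep: float, step: float
) -> Tuple[float, float, float]:
    """(pre-plateau mean, post-plateau mean, pre-plateau SD about its mean)."""
    margin = 2.0 * step
    pre = sig[vols <= v_ep - margin]
    post = sig[vols >= v_ep + margin]
    if pre.size < 3:
        pre = sig[:3]
    if post.size < 3:
        post = sig[-3:]
    sd = float(np.std(pre, ddof=1)) if pre.size >= 2 else 0.0
    return float(pre.mean()), float(post.mean()), sd


def _max_slope_candidate(vols: np.ndarray, sig: np.ndarray) -> Tuple[int, float]:
    """Index and midpoint volume of the steepest adjacent pair (earliest on ties)."""
    slopes = np.abs(np.diff(sig) / np.diff(vols))
    # earliest slope within float tolerance of the max: ties break toward
    # the smallest volume (under-titration bias is the conservative error)
    i = int(np.argmax(slopes >= slopes.max() * (1.0 - 1e-9)))
    return i, float(0.5 * (vols[i] + vols[i + 1]))


def _half_height_bracket(smoothed: np.ndarray) -> Optional[int]:
    """Index of the first pair where the signal crosses its half-height.

    The plateau levels are the medians of the first/last five smoothed
    points; the transition is where the signal first crosses their midpoint
    coming from the starting plateau.  Localizing on the level crossing
    rather than the derivative argmax keeps narrow noise spikes on a
    low-chroma plateau from hijacking the endpoint.  Returns ``None`` when
    no crossing exists (degenerate series).
    """
    a = float(np.median(smoothed[:5]))
    d = float(np.median(smoothed[-5:]))
    mid = 0.5 * (a + d)
    rel = smoothed - mid
    start_side = rel[0]
    if start_side == 0.0:
        return None
    crossings = np.flatnonzero((rel[:-1] * start_side > 0) & (rel[1:] * start_side <= 0))
    return int(crossings[0]) if crossings.size else None


def _slope_peak_endpoint(
    vols: np.ndarray, smoothed: np.ndarray, window: int, frac: float = 0.3
) -> Tuple[float, float]:
    """Max-slope endpoint: steepest pair near the half-height crossing,
    refined to the slope-weighted centroid of the derivative peak.

    Smoothing spreads the jump over several adjacent pairs, so the centroid
    of the contiguous region where |dS/dV| stays above ``frac`` of its local
    peak reads the derivative maximum more precisely than the raw argmax;
    it reduces to the plain pair midpoint when a single pair carries the
    whole jump.  Ties in the steepest pair break toward the smallest volume
    (under-titration is the conservative error).  Returns (endpoint volume,
    transition width).
    """
    slopes = np.abs(np.diff(smoothed) / np.diff(vols))
    mids = 0.5 * (vols[:-1] + vols[1:])
    c = _half_height_bracket(smoothed)
    if c is None:
        lo, hi = 0, slopes.size
    else:
        lo, hi = max(0, c - window), min(slopes.size, c + window + 1)
    local = slopes[lo:hi]
    i = lo + int(np.argmax(local >= local.max() * (1.0 - 1e-9)))
    half = frac * slopes[i]
    left = i
    while left - 1 >= 0 and slopes[left - 1] >= half:
        left -= 1
    right = i
    while right + 1 < slopes.size and slopes[right + 1] >= half:
        right += 1
    w = slopes[left : right + 1]
    centroid = float(np.sum(mids[left : right + 1] * w) / np.sum(w))
    width = float(max(mids[right] - mids[left], vols[i + 1] - vols[i]))
    return centroid, width


def detect_endpoint(
    curve: TitrationCurve,
    channel: str = "Hue",
    method: str = "sigmoid",
    *,
    smooth_window: Optional[int] = None,
    noise_threshold: float = 5.0,
    allow_fallback: bool = True,
) -> EndpointResult:
    """Locate the endpoint of the color-signal jump on one channel.

    Parameters
    ----------
    method:
        ``"sigmoid"`` fits ``A + (D - A) / (1 + exp(-k (V - V0)))`` by least
        squares and reports ``V0``; rising and falling transitions are
        handled identically through ``|D - A|``.  ``"max_slope"`` locates
        the adjacent volume pair with the largest absolute slope after
        smoothing (ties broken toward the smallest volume) and refines it
        to the centroid of the derivative peak.
    smooth_window:
        Odd moving-average window.  Defaults to 7 for ``max_slope`` and no
        smoothing for ``sigmoid`` (the fit already averages noise).
    noise_threshold:
        The jump must exceed this multiple of the pre-transition plateau SD,
        otherwise :class:`NoTransitionError` is raised.
    allow_fallback:
        When the sigmoid fit fails or places ``V0`` outside the dosed range,
        fall back to ``max_slope`` instead of raising.

    Raises
    ------
    NoTransitionError
        Constant signal, or jump indistinguishable from plateau noise.
    FitFailureError
        Sigmoid fit failure with ``allow_fallback=False``.
    """
    if method not in ("sigmoid", "max_slope"):
        raise ValueError(f"unknown method {method!r}")
    if len(curve) < 5:
        raise ValueError("endpoint detection requires at least 5 dose points")
    vols, sig = extract_channel(curve, channel)
    step = curve.step()
    notes: List[str] = []

    if smooth_window is None:
        window = 7 if method == "max_slope" else 1
        window = min(window, len(sig) if len(sig) % 2 == 1 else len(sig) - 1)
    else:
        window = smooth_window

    if np.ptp(sig) == 0.0:
        raise NoTransitionError(f"channel {channel}: constant signal, no transition detected")

    if method == "max_slope":
        smoothed = smooth(sig, window)
        v_ep, width = _slope_peak_endpoint(vols, smoothed, window)
        pre_mean, post_mean, noise = _plateau_stats(vols, smoothed, v_ep, step)
        jump = abs(post_mean - pre_mean)
        sharpness = jump / width if width > 0 else np.inf
    else:
        smoothed = smooth(sig, window) if window > 1 else sig
        _, v_guess = _max_slope_candidate(vols, smoothed)
        a0 = float(np.mean(smoothed[:3]))
        d0 = float(np.mean(smoothed[-3:]))
        k0 = min(2.0 / step, 1e4)
        span = float(np.ptp(smoothed)) or 1.0
        lo = min(smoothed.min(), a0, d0) - 10 * span
        hi = max(smoothed.max(), a0, d0) + 10 * span
        try:
            popt, _ = curve_fit(
                _logistic,
                vols,
                smoothed,
                p0=[a0, d0, k0, v_guess],
                bounds=([lo, lo, 1e-6, vols[0]], [hi, hi, 1e7, vols[-1]]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                maxfev=20000,
            )
            a, d, k, v0 = map(float, popt)
            interior = vols[0] + 0.25 * step <= v0 <= vols[-1] - 0.25 * step
            if not interior:
                raise FitFailureError(
                    f"fitted endpoint {v0:.4f} mL sits on the edge of the dosed range"
                )
        except FitFailureError:
            if not allow_fallback:
                raise
            notes.append("sigmoid fit failed; fell back to max_slope")
            return _with_notes(
                detect_endpoint(
                    curve,
                    channel,
                    "max_slope",
                    smooth_window=smooth_window,
                    noise_threshold=noise_threshold,
                ),
                notes,
            )
        except RuntimeError as exc:
            if not allow_fallback:
                raise FitFailureError(str(exc)) from exc
            notes.append("sigmoid fit did not converge; fell back to max_slope")
            return _with_notes(
                detect_endpoint(
                    curve,
                    channel,
                    "max_slope",
                    smooth_window=smooth_window,
                    noise_threshold=noise_threshold,
                ),
                notes,
            )
        v_ep = v0
        jump = abs(d - a)
        # 10-90% transition width of the logistic is ln(81)/k.
        width = float(np.log(81.0) / k)
        sharpness = jump / width if width > 0 else np.inf
        residuals = sig - _logistic(vols, a, d, k, v0)
        pre_res = residuals[vols <= v0 - np.log(81.0) / (2 * k)]
        if pre_res.size < 3:
            pre_res = residuals
        noise = float(np.std(pre_res, ddof=1)) if pre_res.size >= 2 else 0.0

    if jump <= noise_threshold * noise or jump <= 1e-12:
        raise NoTransitionError(
            f"channel {channel}: jump {jump:.3g} does not exceed "
            f"{noise_threshold} x plateau noise ({noise:.3g}); no transition detected"
        )
    return EndpointResult(
        v_endpoint=float(v_ep),
        channel=channel,
        jump=float(jump),
        sharpness=float(sharpness),
        method=method,
        baseline_noise=float(noise),
        warnings=tuple(notes),
    )


def _with_notes(res: EndpointResult, notes: List[str]) -> EndpointResult:
    return EndpointResult(
        v_endpoint=res.v_endpoint,
        channel=res.channel,
        jump=res.jump,
        sharpness=res.sharpness,
        method=res.method,
        baseline_noise=res.baseline_noise,
        warnings=tuple(notes) + res.warnings,
    )


@dataclass(frozen=True)
class ChannelScore:
    channel: str
    score: float
    result: Optional[EndpointResult]


@dataclass(frozen=True)
class ChannelRanking:
    """Channels ordered by jump-to-noise score, with the indicator prior."""

    scores: Tuple[ChannelScore, ...]
    recommended: Tuple[str, ...]

    def order(self) -> Tuple[str, ...]:
        return tuple(s.channel for s in self.scores)


def rank_channels(
    curve: TitrationCurve,
    method: str = "sigmoid",
    *,
    noise_threshold: float = 5.0,
) -> ChannelRanking:
    """Score every channel by jump / plateau-noise and rank them.

    Channels whose detection fails (no transition, no signal) score 0.  The
    per-indicator recommendation is attached as a prior: Green and Hue for
    calcein, Red and Hue for HNB; empty when the indicator is unknown.
    """
    scores = []
    for ch in CHANNELS:
        try:
            res = detect_endpoint(curve, ch, method, noise_threshold=noise_threshold)
            score = res.jump / max(res.baseline_noise, 1e-9)
        except (NoTransitionError, NoSignalError, FitFailureError, ValueError):
            res, score = None, 0.0
        scores.append(ChannelScore(channel=ch, score=float(score), result=res))
    scores.sort(key=lambda s: -s.score)
    recommended = RECOMMENDED_CHANNELS.get(curve.indicator or "", ())
    return ChannelRanking(scores=tuple(scores), recommended=tuple(recommended))
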