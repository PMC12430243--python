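"""File formats: frame stacks, dose logs, curve/replicate CSVs, result JSON.

Column names and JSON keys are fixed:

* dose log CSV — ``frame_id, volume_mL``
* curve CSV    — ``volume_mL, R, G, B, Hue`` (Hue empty when achromatic;
  recomputed from R/G/B when the column is absent)
* replicates CSV — ``label, value[, nominal]``
* endpoint JSON — ``v_endpoint_mL, channel, method, jump, sharpness,
  baseline_noise, warnings``
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .color import ImageFrame, SamplingRegion, average_rgb, make_reading
from .endpoint import DosePoint, EndpointResult, TitrationCurve
from .errors import RunLoadError
from .quantify import QuantResult
from .simulate import FrameLayout, SimulationResult, render_frames
from .validation import ReplicateSet

__all__ = [
    "curve_to_frame",
    "curve_to_csv",
    "curve_from_csv",
    "write_run",
    "load_run",
    "read_image",
    "replicates_from_csv",
    "endpoint_to_json",
    "quant_to_json",
]

PathLike = Union[str, Path]


def curve_to_frame(curve: TitrationCurve) -> pd.DataFrame:
    rows = []
    for p in curve.points:
        rows.append(
            {
                "volume_mL": p.volume,
                "R": p.reading.r,
                "G": p.reading.g,
                "B": p.reading.b,
                "Hue": p.reading.hue if not p.reading.achromatic else np.nan,
            }
        )
    return pd.DataFrame(rows)


def curve_to_csv(curve: TitrationCurve, path: PathLike) -> None:
    curve_to_frame(curve).to_csv(path, index=False)


def curve_from_csv(
    path: PathLike,
    indicator: Optional[str] = None,
    increment: Optional[float] = None,
    metadata: Optional[dict] = None,
) -> TitrationCurve:
    """Read a pre-extracted curve CSV; Hue is recomputed when absent."""
    df = pd.read_csv(path)
    required = {"volume_mL", "R", "G", "B"}
    missing = required - set(df.columns)
    if missing:
        raise RunLoadError(f"curve CSV {path} missing columns: {sorted(missing)}")
    points: List[DosePoint] = []
    for _, row in df.iterrows():
        reading = make_reading(float(row["R"]), float(row["G"]), float(row["B"]))
        points.append(DosePoint(volume=float(row["volume_mL"]), reading=reading))
    return TitrationCurve(
        points=points,
        indicator=indicator,
        increment=increment,
        metadata=metadata or {},
    )


def read_image(path: PathLike, capture_index: int = 0) -> ImageFrame:
    """Read a PNG/JPEG frame; an alpha channel, if present, is dropped."""
    try:
        px = np.asarray(iio.imread(path))
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise RunLoadError(f"unreadable image {path}: {exc}") from exc
    if px.ndim == 2:  # grayscale -> replicate to three channels
        px = np.stack([px] * 3, axis=-1)
    if px.shape[-1] == 4:
        px = px[..., :3]
    return ImageFrame(pixels=px, frame_id=Path(path).name, capture_index=capture_index)


def write_run(
    out_dir: PathLike,
    sim: SimulationResult,
    layout: Optional[FrameLayout] = None,
    *,
    render: bool = True,
) -> Path:
    """Write a synthetic run directory: frames/, dose_log.csv, curve.csv,
    truth.json and layout.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = layout or FrameLayout()

    curve_to_csv(sim.curve, out / "curve.csv")
    dose_rows = []
    if render:
        frames = render_frames(sim.curve, layout, seed=sim.config.seed)
        frames_dir = out / "frames"
        frames_dir.mkdir(exist_ok=True)
        for frame, point in zip(frames, sim.curve.points):
            name = f"{frame.frame_id}.png"
            iio.imwrite(frames_dir / name, frame.pixels)
            dose_rows.append({"frame_id": name, "volume_mL": point.volume})
    else:
        for i, point in enumerate(sim.curve.points):
            dose_rows.append({"frame_id": f"frame_{i:04d}.png", "volume_mL": point.volume})
    pd.DataFrame(dose_rows).to_csv(out / "dose_log.csv", index=False)

    truth = {
        "v_endpoint_true_mL": sim.true_endpoint,
        "profile": sim.profile.name,
        "indicator": sim.profile.indicator,
        "ca_amount_umol": sim.config.ca_amount,
        "molarity_M": sim.config.molarity,
        "blank_volume_mL": sim.config.blank_volume,
        "increment_mL": sim.config.increment,
        "noise_sd": sim.config.noise_sd,
        "seed": sim.config.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    roi = layout.roi
    layout_doc = {
        "frame_width": layout.width,
        "frame_height": layout.height,
        "roi": {"x0": roi.x0, "y0": roi.y0, "width": roi.width, "height": roi.height},
        "noise_sd": layout.noise_sd,
        "speckle_fraction": layout.speckle_fraction,
    }
    (out / "layout.json").write_text(json.dumps(layout_doc, indent=2))
    return out


def load_run(
    frames_dir: PathLike,
    dose_log_csv: PathLike,
    roi: SamplingRegion,
    *,
    indicator: Optional[str] = None,
    increment: Optional[float] = None,
    metadata: Optional[dict] = None,
) -> TitrationCurve:
    """Assemble a titration curve from a frame directory and a dose log.

    Rows are sorted by volume; duplicate volumes and missing or unreadable
    frames raise :class:`RunLoadError` naming the offending row.
    """
    frames_dir = Path(frames_dir)
    try:
        log = pd.read_csv(dose_log_csv)
    except FileNotFoundError as exc:
        raise RunLoadError(f"dose log not found: {dose_log_csv}") from exc
    for col in ("frame_id", "volume_mL"):
        if col not in log.columns:
            raise RunLoadError(f"dose log {dose_log_csv} missing column {col!r}")
    log = log.sort_values("volume_mL", kind="stable").reset_index(drop=True)
    dup = log["volume_mL"].duplicated()
    if dup.any():
        bad = log.loc[dup.idxmax()]
        raise RunLoadError(
            f"duplicate volume {bad['volume_mL']} mL at dose-log row for "
            f"frame {bad['frame_id']!r}"
        )
    points: List[DosePoint] = []
    for i, row in log.iterrows():
        frame_path = frames_dir / str(row["frame_id"])
        if not frame_path.exists():
            raise RunLoadError(f"missing frame {row['frame_id']!r} (dose-log row {i})")
        frame = read_image(frame_path, capture_index=i)
        reading = average_rgb(frame, roi)
        points.append(DosePoint(volume=float(row["volume_mL"]), reading=reading))
    return TitrationCurve(
        points=points, indicator=indicator, increment=increment, metadata=metadata or {}
    )


def replicates_from_csv(path: PathLike) -> List[ReplicateSet]:
    """Read ``label, value[, nominal]`` rows into labelled replicate sets."""
    df = pd.read_csv(path)
    for col in ("label", "value"):
        if col not in df.columns:
            raise RunLoadError(f"replicates CSV {path} missing column {col!r}")
    sets: List[ReplicateSet] = []
    for label, group in df.groupby("label", sort=False):
        nominal = None
        if "nominal" in group.columns:
            nominals = group["nominal"].dropna().unique()
            if len(nominals) > 1:
                raise RunLoadError(f"conflicting nominal values for label {label!r}")
            if len(nominals) == 1:
                nominal = float(nominals[0])
        sets.append(
            ReplicateSet(values=group["value"].tolist(), nominal=nominal, label=str(label))
        )
    return sets


def endpoint_to_json(result: EndpointResult, path: Optional[PathLike] = None) -> Dict:
    doc = {
        "v_endpoint_mL": result.v_endpoint,
        "channel": result.channel,
        "method": result.method,
        "jump": result.jump,
        "sharpness": result.sharpness,
        "baseline_noise": result.baseline_noise,
        "warnings": list(result.warnings),
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def quant_to_json(result: QuantResult, path: Optional[PathLike] = None) -> Dict:
    doc = {
        "v_endpoint_mL": result.v_endpoint,
        "ca_umol": result.ca_amount,
        "ca_content": result.ca_content,
        "basis": result.basis,
        "content_units": "mg/100 mL" if result.basis == "volume" else "mg/100 g",
        "route": result.route,
    }
    if result.model is not None:
        doc["model"] = asdict(result.model)
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc
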