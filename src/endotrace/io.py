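"""Reading and writing the pipeline's on-disk formats.

Movies travel as multi-page TIFF (16-bit unsigned, ImageJ-compatible
metadata carrying pixel size in um and frame interval in s); traces,
titrations, transients, ROI tables and event tables as headed CSV;
ground truth and fit results as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from endotrace.containers import IntensityTrace, Movie
from endotrace.detection import EventROI
from endotrace.sim.models import GroundTruth
from endotrace.traces import EventMeasurement


def write_movie_tiff(path, movie: Movie) -> None:
    """Write a movie as an ImageJ-compatible 16-bit multi-page TIFF."""
    frames = np.clip(np.round(movie.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        path,
        frames,
        imagej=True,
        resolution=(1.0 / movie.pixel_size, 1.0 / movie.pixel_size),
        metadata={"unit": "um", "finterval": movie.frame_interval, "axes": "TYX"},
    )


def read_movie_tiff(path, pixel_size: float | None = None, frame_interval: float | None = None) -> Movie:
    """Read a (single-channel) TIFF stack, recovering calibration metadata.

    Explicit ``pixel_size``/``frame_interval`` arguments override, and
    are required for generic TIFFs lacking ImageJ metadata.
    """
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray().astype(float)
        meta = tif.imagej_metadata or {}
        if frame_interval is None:
            frame_interval = meta.get("finterval")
        if pixel_size is None:
            try:
                xres = tif.pages[0].tags["XResolution"].value
                pixel_size = xres[1] / xres[0]
            except (KeyError, ZeroDivisionError, TypeError):
                pixel_size = None
    if frames.ndim == 2:
        frames = frames[None]
    if pixel_size is None or frame_interval is None:
        raise ValueError(f"{path}: pixel_size/frame_interval not in metadata; pass them explicitly")
    return Movie(frames=frames, pixel_size=float(pixel_size), frame_interval=float(frame_interval))


def write_trace_csv(path, trace: IntensityTrace) -> None:
    pd.DataFrame({"time_s": trace.time, "intensity_au": trace.intensity}).to_csv(path, index=False)


def read_trace_csv(path) -> IntensityTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: trace needs at least 2 samples")
    return IntensityTrace(
        time=t,
        intensity=df["intensity_au"].to_numpy(dtype=float),
        frame_interval=float(np.median(np.diff(t))),
        source=str(path),
    )


def write_roi_csv(path, rois: list[EventROI]) -> None:
    pd.DataFrame(
        {
            "x_px": [r.center[1] for r in rois],
            "y_px": [r.center[0] for r in rois],
            "flags": [";".join(sorted(r.flags)) for r in rois],
        }
    ).to_csv(path, index=False)


def write_measurements_csv(path, measurements: list[EventMeasurement]) -> None:
    rows = []
    for m in measurements:
        rows.append(
            {
                "t_start_s": m.t_start,
                "t_end_s": m.t_end,
                "t_dur_s": m.t_dur,
                "a_av_au": m.a_av,
                "rise_au_per_s": m.rise_gradient,
                "fall_au_per_s": m.fall_gradient,
                "t_scis_s": m.t_scis if m.t_scis is not None else np.nan,
                "molecules": m.molecules if m.molecules is not None else np.nan,
                "flags": ";".join(sorted(m.flags)),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_titration_csv(path, x, signal, x_name: str = "concentration_uM") -> None:
    pd.DataFrame({x_name: np.asarray(x), "signal_au": np.asarray(signal)}).to_csv(path, index=False)


def read_titration_csv(path) -> tuple[np.ndarray, np.ndarray, str]:
    """Returns (x, signal, x_kind); x may be concentration_uM or pCa."""
    df = pd.read_csv(path)
    for x_name in ("concentration_uM", "pCa", "time_s"):
        if x_name in df.columns:
            return df[x_name].to_numpy(dtype=float), df["signal_au"].to_numpy(dtype=float), x_name
    raise ValueError(f"{path}: expected a concentration_uM, pCa or time_s column")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonify(payload), indent=2, default=str) + "\n")


def write_ground_truth_json(path, truth: GroundTruth) -> None:
    write_json(
        path,
        {
            "events": [dataclasses.asdict(e) for e in truth.events],
            "tracks": [
                {"t_on": t.t_on, "dwell": t.dwell, "frames": t.frames, "x_um": t.x_um, "y_um": t.y_um}
                for t in truth.tracks
            ],
            "params": {k: str(v) for k, v in truth.params.items()},
        },
    )
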