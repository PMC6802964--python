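"""Rendering of synthetic TIRF movies with exported ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from endotrace.containers import Movie
from endotrace.sim.models import (
    CameraModel,
    EventKinetics,
    EventTruth,
    GroundTruth,
    SingleMoleculeKinetics,
    TrackTruth,
)

# Events whose centres are closer than this multiple of the background
# region radius are flagged overlap-contaminated in the ground truth.
_OVERLAP_DIAMETER_UM = 1.5


def _add_psf(frame: np.ndarray, x_px: float, y_px: float, amplitude: float, sigma_px: float) -> None:
    """Add a pixel-integrated 2-D Gaussian of total mass ``amplitude``.

    Pixel (i, j) covers [j-0.5, j+0.5] x [i-0.5, i+0.5] in (x, y); the
    Gaussian is integrated analytically over each pixel so that the total
    rendered intensity (over an infinite frame) equals ``amplitude``
    exactly.
    """
    if amplitude <= 0:
        return
    half = int(np.ceil(5 * sigma_px))
    iy0 = max(0, int(np.floor(y_px)) - half)
    iy1 = min(frame.shape[0], int(np.floor(y_px)) + half + 1)
    ix0 = max(0, int(np.floor(x_px)) - half)
    ix1 = min(frame.shape[1], int(np.floor(x_px)) + half + 1)
    if iy0 >= iy1 or ix0 >= ix1:
        return
    s = sigma_px * np.sqrt(2.0)
    xe = np.arange(ix0, ix1 + 1) - 0.5
    ye = np.arange(iy0, iy1 + 1) - 0.5
    fx = 0.5 * np.diff(erf((xe - x_px) / s))
    fy = 0.5 * np.diff(erf((ye - y_px) / s))
    frame[iy0:iy1, ix0:ix1] += amplitude * np.outer(fy, fx)


@dataclass(frozen=True)
class PlacedEvent:
    """An endocytic event placed in the field at a given start time."""

    x_um: float
    y_um: float
    kinetics: EventKinetics
    t_start: float = 0.0


def _simulate_singles(
    singles: SingleMoleculeKinetics,
    camera: CameraModel,
    field_size: tuple[float, float],
    duration: float,
    rng: np.random.Generator,
) -> list[TrackTruth]:
    """Draw single-molecule binding events and their Brownian paths."""
    width_um, height_um = field_size
    area = width_um * height_um
    n_events = rng.poisson(singles.on_rate_density * area * duration)
    dt = camera.frame_interval
    n_frames = int(round(duration / dt))
    step_sd = np.sqrt(2.0 * singles.diffusion_coefficient * dt)
    tracks: list[TrackTruth] = []
    for _ in range(n_events):
        t_on = rng.uniform(0.0, duration)
        dwell = rng.exponential(1.0 / singles.off_rate)
        first = int(np.ceil(t_on / dt))
        last = int(np.floor((t_on + dwell) / dt))
        last = min(last, n_frames - 1)
        if last < first:
            # Molecule bound and released between two frame captures;
            # it is never imaged but is still part of the ground truth.
            tracks.append(TrackTruth(t_on=t_on, dwell=dwell))
            continue
        n = last - first + 1
        x0 = rng.uniform(0.0, width_um)
        y0 = rng.uniform(0.0, height_um)
        if step_sd > 0:
            dx = rng.normal(0.0, step_sd, size=n - 1) if n > 1 else np.empty(0)
            dy = rng.normal(0.0, step_sd, size=n - 1) if n > 1 else np.empty(0)
            x = x0 + np.concatenate([[0.0], np.cumsum(dx)])
            y = y0 + np.concatenate([[0.0], np.cumsum(dy)])
        else:
            x = np.full(n, x0)
            y = np.full(n, y0)
        tracks.append(
            TrackTruth(t_on=t_on, dwell=dwell, frames=np.arange(first, last + 1), x_um=x, y_um=y)
        )
    return tracks


def generate_movie(
    events: list[PlacedEvent],
    singles: SingleMoleculeKinetics | None,
    camera: CameraModel,
    field_size: tuple[float, float],
    duration: float,
    seed: int | None = 0,
    *,
    n_molecules_noise: float = 0.0,
    background_gradient: tuple[float, float] = (0.0, 0.0),
    channel: str = "",
) -> tuple[Movie, GroundTruth]:
    """Render a movie of endocytic events and/or diffusing single molecules.

    Each fluorophore population is rendered as a pixel-integrated 2-D
    Gaussian PSF: endocytic sites are immobile with trapezoidal molecule
    counts; single molecules appear with Poisson arrivals, diffuse with
    the configured coefficient and disappear with exponential dwell
    times. Baseline offset, optional planar background gradient, Poisson
    shot noise and Gaussian read noise are added per pixel.

    Parameters
    ----------
    events : list of PlacedEvent
        Endocytic events; positions must lie inside the field.
    singles : SingleMoleculeKinetics or None
        Single-molecule arrival/dwell/mobility model (None for none).
    field_size : (width_um, height_um)
        Physical size of the rendered field in micrometres.
    duration : float
        Movie length in seconds; must cover the longest event.
    background_gradient : (gx, gy)
        Additive planar background in AU per micrometre along x and y.

    Returns
    -------
    (Movie, GroundTruth)
        The rendered stack and a complete ground-truth record (one entry
        per event and per single-molecule binding event; events whose
        background regions overlap are flagged).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width_um, height_um = field_size
    px = camera.pixel_size
    nx = int(round(width_um / px))
    ny = int(round(height_um / px))
    n_frames = int(round(duration / camera.frame_interval))
    if n_frames < 1:
        raise ValueError("duration must cover at least one frame")
    for ev in events:
        if not (0 <= ev.x_um < width_um and 0 <= ev.y_um < height_um):
            raise ValueError("event position outside the field")
        if ev.t_start + ev.kinetics.total_duration > duration:
            raise ValueError("duration must cover every event")

    truth = GroundTruth(params={"camera": camera, "field_size": field_size, "duration": duration})
    for ev in events:
        kin = ev.kinetics
        t_scis = ev.t_start + kin.total_duration if kin.scission_mode == "abrupt" else None
        truth.events.append(
            EventTruth(
                t_start=ev.t_start,
                t_end=ev.t_start + kin.total_duration,
                t_scis=t_scis,
                position=(ev.x_um, ev.y_um),
                channel=channel,
                kinetics=kin,
            )
        )
    # Overlap contamination: background regions touching another event.
    for i, a in enumerate(truth.events):
        for b in truth.events[i + 1 :]:
            d = np.hypot(a.position[0] - b.position[0], a.position[1] - b.position[1])
            if d < _OVERLAP_DIAMETER_UM:
                a.overlap_contaminated = True
                b.overlap_contaminated = True

    if singles is not None:
        truth.tracks = _simulate_singles(singles, camera, field_size, duration, rng)
        truth.params["singles"] = singles

    # Per-frame molecule counts for each event (with optional occupancy noise).
    times = np.arange(n_frames) * camera.frame_interval
    event_counts = []
    for ev in events:
        n = ev.kinetics.molecules(times - ev.t_start)
        if n_molecules_noise > 0:
            n = np.clip(n * (1.0 + rng.normal(0.0, n_molecules_noise, size=n.shape)), 0.0, None)
        event_counts.append(n)

    # Frame-indexed lookup of active single molecules.
    singles_by_frame: list[list[tuple[float, float]]] = [[] for _ in range(n_frames)]
    for tr in truth.tracks:
        for k, f in enumerate(tr.frames):
            singles_by_frame[f].append((tr.x_um[k], tr.y_um[k]))

    base = np.full((ny, nx), camera.baseline_offset, dtype=float)
    gx, gy = background_gradient
    if gx != 0.0 or gy != 0.0:
        xs = (np.arange(nx) + 0.5) * px
        ys = (np.arange(ny) + 0.5) * px
        base = base + gx * xs[None, :] + gy * ys[:, None]

    sigma_px = camera.psf_sigma_px
    sfi = camera.single_fluorophore_intensity
    frames = np.empty((n_frames, ny, nx), dtype=float)
    for t in range(n_frames):
        expected = base.copy()
        for ev, counts in zip(events, event_counts):
            _add_psf(expected, ev.x_um / px - 0.5, ev.y_um / px - 0.5, counts[t] * sfi, sigma_px)
        for x_um, y_um in singles_by_frame[t]:
            _add_psf(expected, x_um / px - 0.5, y_um / px - 0.5, sfi, sigma_px)
        if camera.shot_noise:
            frame = rng.poisson(np.clip(expected, 0.0, None)).astype(float)
        else:
            frame = expected
        if camera.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, camera.read_noise_sd, size=frame.shape)
        frames[t] = frame

    movie = Movie(frames=frames, pixel_size=px, frame_interval=camera.frame_interval, channel=channel)
    return movie, truth
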