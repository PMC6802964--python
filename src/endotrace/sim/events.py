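"""Simulated background-corrected intensity traces of endocytic events.

These generators produce traces on the same footing as the output of
:func:`endotrace.traces.correct_background` applied to a 5x5-pixel ROI:
the baseline is zero and the event signal is the summed intensity of all
fluorophores at the site. Shot noise therefore includes the Poisson
contribution of the baseline photons that the background subtraction
removed in expectation but not in variance.
"""

from __future__ import annotations

import numpy as np

from endotrace.containers import IntensityTrace
from endotrace.sim.models import CameraModel, EventKinetics, EventTruth

CORE_PIXELS = 25  # 5x5 measurement core, matches the ROI extraction


def _sample_trace(
    kinetics: EventKinetics,
    camera: CameraModel,
    rng: np.random.Generator,
    times: np.ndarray,
    t_start: float,
    n_molecules_noise: float,
) -> np.ndarray:
    """Sample one noisy trace on the given time grid (event starts at t_start)."""
    n = kinetics.molecules(times - t_start)
    if n_molecules_noise > 0:
        n = n * (1.0 + rng.normal(0.0, n_molecules_noise, size=n.shape))
        n = np.clip(n, 0.0, None)
    expected = n * camera.single_fluorophore_intensity
    if camera.shot_noise:
        # Background-corrected trace: Poisson counts of signal + baseline,
        # minus the (deterministic) expected baseline contribution.
        floor = CORE_PIXELS * camera.baseline_offset
        signal = rng.poisson(expected + floor).astype(float) - floor
    else:
        signal = expected.copy()
    if camera.read_noise_sd > 0:
        signal = signal + rng.normal(0.0, camera.read_noise_sd * np.sqrt(CORE_PIXELS), size=signal.shape)
    return signal


def generate_event_trace(
    kinetics: EventKinetics,
    camera: CameraModel,
    n_molecules_noise: float = 0.0,
    seed: int | None = 0,
    *,
    pre_roll: float = 3.0,
    post_roll: float = 3.0,
    channel: str = "",
) -> tuple[IntensityTrace, EventTruth]:
    """Render a single endocytic event as a background-corrected trace.

    Parameters
    ----------
    kinetics : EventKinetics
        Trapezoid (or abruptly truncated) molecule-count kinetics.
    camera : CameraModel
        Sampling rate, fluorophore brightness and noise model.
    n_molecules_noise : float
        Fractional (CV) Gaussian noise applied per frame to the molecule
        count, modelling occupancy fluctuations at the site.
    seed : int or numpy Generator
        Seed for all randomness; identical inputs give identical traces.
    pre_roll, post_roll : float
        Baseline padding (s) before the event start and after its end.

    Returns
    -------
    (IntensityTrace, EventTruth)
        The sampled trace and the true event timing (``t_start``,
        ``t_end`` and, for abrupt events, ``t_scis``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pre_roll < 0 or post_roll < 0:
        raise ValueError("pre_roll and post_roll must be non-negative")
    duration = pre_roll + kinetics.total_duration + post_roll
    n_frames = int(round(duration / camera.frame_interval))
    if n_frames < 2:
        raise ValueError("trace would have fewer than 2 frames")
    times = np.arange(n_frames) * camera.frame_interval
    t_start = pre_roll
    signal = _sample_trace(kinetics, camera, rng, times, t_start, n_molecules_noise)
    t_scis = None
    if kinetics.scission_mode == "abrupt":
        t_scis = t_start + kinetics.total_duration
    truth = EventTruth(
        t_start=t_start,
        t_end=t_start + kinetics.total_duration,
        t_scis=t_scis,
        channel=channel,
        kinetics=kinetics,
    )
    trace = IntensityTrace(
        time=times,
        intensity=signal,
        frame_interval=camera.frame_interval,
        channel=channel,
        source="simulated",
    )
    return trace, truth


def generate_two_color_event(
    kinetics_a: EventKinetics,
    kinetics_b: EventKinetics,
    offset_b: float,
    camera: CameraModel,
    seed: int | None = 0,
    *,
    n_molecules_noise: float = 0.0,
    pre_roll: float = 3.0,
    post_roll: float = 3.0,
    channels: tuple[str, str] = ("a", "b"),
) -> tuple[tuple[IntensityTrace, IntensityTrace], tuple[EventTruth, EventTruth]]:
    """Render a two-colour event pair sharing one endocytic site.

    Channel b's event timings are shifted by ``offset_b`` relative to
    channel a: positive values advance channel b (it starts earlier),
    negative values delay it. Both traces share one time grid so that
    frame indices are directly comparable across channels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_start_a = pre_roll + max(0.0, offset_b)
    t_start_b = t_start_a - offset_b
    end = max(t_start_a + kinetics_a.total_duration, t_start_b + kinetics_b.total_duration)
    duration = end + post_roll
    n_frames = int(round(duration / camera.frame_interval))
    times = np.arange(n_frames) * camera.frame_interval

    traces = []
    truths = []
    for kin, t0, label in ((kinetics_a, t_start_a, channels[0]), (kinetics_b, t_start_b, channels[1])):
        signal = _sample_trace(kin, camera, rng, times, t0, n_molecules_noise)
        t_scis = t0 + kin.total_duration if kin.scission_mode == "abrupt" else None
        truths.append(
            EventTruth(t_start=t0, t_end=t0 + kin.total_duration, t_scis=t_scis, channel=label, kinetics=kin)
        )
        traces.append(
            IntensityTrace(
                time=times,
                intensity=signal,
                frame_interval=camera.frame_interval,
                channel=label,
                source="simulated",
            )
        )
    return (traces[0], traces[1]), (truths[0], truths[1])
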