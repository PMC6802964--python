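"""End-to-end study workflows built from the pipeline stages.

Each function reproduces one complete measurement as performed in the
underlying study: simulate the scene with a named preset, run the
analysis stages, and return summary statistics. They are used by the
command-line tools, the acceptance script and the test suite, so that
every headline number is produced by exactly one code path.
"""

from __future__ import annotations

import numpy as np

from endotrace import detection, tracking
from endotrace import traces as trace_analysis
from endotrace.binding import fit_pca, fit_titration
from endotrace.sim import PlacedEvent, generate_event_trace, generate_movie, generate_two_color_event
from endotrace.sim import presets as preset_lib
from endotrace.sim.curves import generate_pca_titration, generate_titration, generate_transient, split_timebase
from endotrace.transients import fit_multiexp, select_n_phases


def simulate_event_traces(preset: str, n: int, rng: np.random.Generator):
    """n single-event traces drawn from a preset's kinetic distribution."""
    camera = preset_lib.event_camera(preset)
    out = []
    for _ in range(n):
        kin = preset_lib.sample_event_kinetics(preset, rng)
        out.append(generate_event_trace(kin, camera, seed=rng, channel=preset))
    return [t for t, _ in out], [g for _, g in out]


def measure_event_traces(traces, scission: bool = False):
    """Ramp-intercept measurement of a batch of traces; malformed events
    are dropped (mirroring the exclusion of unanalysable ROIs)."""
    measurements = []
    for trace in traces:
        try:
            measurements.append(trace_analysis.measure_event(trace, detect_scission_drop=scission))
        except trace_analysis.MalformedEventError:
            continue
    return measurements


def event_duration_stats(preset: str, n: int, rng: np.random.Generator) -> dict:
    """Mean event duration (s) with SEM for n simulated preset events."""
    traces, _ = simulate_event_traces(preset, n, rng)
    t_dur = np.array([m.t_dur for m in measure_event_traces(traces)])
    return {
        "mean_t_dur": float(t_dur.mean()),
        "sem_t_dur": float(t_dur.std(ddof=1) / np.sqrt(len(t_dur))),
        "n": len(t_dur),
    }


def _grid_positions(n_events: int, spacing: float = 4.0, margin: float = 3.0):
    n_cols = int(np.ceil(np.sqrt(n_events)))
    n_rows = int(np.ceil(n_events / n_cols))
    pos = [
        (margin + spacing * c, margin + spacing * r) for r in range(n_rows) for c in range(n_cols)
    ][:n_events]
    field = (2 * margin + spacing * (n_cols - 1), 2 * margin + spacing * (n_rows - 1))
    return pos, field


def single_molecule_scene(
    rng: np.random.Generator,
    duration: float = 20.0,
    field: tuple[float, float] = (20.0, 20.0),
    min_dwell_frames: int = 2,
    edge_margin: float = 1.0,
) -> dict:
    """Simulate, track and summarise a single-molecule membrane scene.

    Returns the truncation-corrected off-rate, the MSD diffusion
    coefficient, and a single-fluorophore calibration from the tracked
    intensities (tracks near the field edge are excluded: their dwells
    are censored and their spots cannot be measured).
    """
    kin, camera = preset_lib.single_molecule_preset()
    movie, _ = generate_movie([], kin, camera, field_size=field, duration=duration, seed=rng)
    all_tracks = tracking.track_movie(movie)
    tracks = tracking.filter_interior_tracks(all_tracks, field, edge_margin)
    dt = camera.frame_interval
    min_duration = min_dwell_frames * dt
    rate = tracking.estimate_off_rate([t.duration for t in tracks], dt, min_duration, n_boot=200, seed=rng.integers(2**31))
    diff = tracking.estimate_diffusion(tracks, n_boot=100, seed=rng.integers(2**31))
    calibration = trace_analysis.estimate_single_fluorophore_intensity(
        [t for t in tracks if t.n_frames >= 3], excitation_scale=preset_lib.excitation_scale()
    )
    return {
        "off_rate": rate.rate,
        "off_rate_ci": (rate.ci_low, rate.ci_high),
        "n_dwells": rate.n,
        "D": diff.D,
        "D_ci": (diff.ci_low, diff.ci_high),
        "n_tracks": diff.n_tracks,
        "calibration": calibration,
    }


def event_movie_molecule_count(
    preset: str,
    n_events: int,
    rng: np.random.Generator,
    calibration: trace_analysis.CalibrationModel,
) -> dict:
    """Full imaging pipeline: event movie -> detection -> molecule counts.

    Events are placed on a grid (well separated, staggered starts), the
    movie is rendered with the preset's endocytosis camera, candidate
    sites come from the standard-deviation projection, ROI traces are
    background-corrected and measured, and the plateau amplitude (the
    pre-scission amplitude for abrupt presets) is converted to a
    fluorophore count with the supplied single-molecule calibration.
    """
    camera = preset_lib.event_camera(preset)
    positions, field = _grid_positions(n_events)
    scission = preset_lib.event_kinetics_preset(preset).scission_mode == "abrupt"
    events = []
    for x, y in positions:
        kin = preset_lib.sample_event_kinetics(preset, rng)
        # sub-pixel jitter: real sites are not pixel-aligned, and the
        # calibration scene samples sub-pixel positions uniformly
        jx, jy = rng.uniform(-0.5, 0.5, 2) * camera.pixel_size
        events.append(PlacedEvent(x + jx, y + jy, kin, t_start=float(rng.uniform(2.0, 6.0))))
    duration = max(e.t_start + e.kinetics.total_duration for e in events) + 3.0
    movie, _ = generate_movie(events, None, camera, field_size=field, duration=duration, seed=rng)

    projection = detection.std_projection(movie)
    rois = detection.detect_event_sites(projection, movie.pixel_size)
    amplitudes = []
    for roi in rois:
        if roi.overlap_contaminated:
            continue
        core, background = detection.extract_roi_trace(movie, roi)
        trace = trace_analysis.correct_background(core, background, frame_interval=movie.frame_interval)
        try:
            m = trace_analysis.measure_event(trace, detect_scission_drop=scission)
        except trace_analysis.MalformedEventError:
            continue
        # quality gate: a genuine accumulation/disassembly event has
        # well-fitting ramps; spurious detections from projection noise
        # do not (automated counterpart of manual trace exclusion)
        if m.rise_fit.r_squared < 0.5 or m.fall_fit.r_squared < 0.5:
            continue
        amp = m.a_pre_scis if scission and m.a_pre_scis is not None else m.a_av
        amplitudes.append(amp)
    molecules = [trace_analysis.to_molecules(a, calibration) for a in amplitudes]
    return {"mean_molecules": float(np.mean(molecules)), "n": len(molecules)}


def two_color_scission_stats(n_pairs: int, rng: np.random.Generator, preset: str = "cam1_cam2") -> dict:
    """Mean vesicle scission time relative to channel-a T_start.

    Channel a (Cam1) timing comes from the ramp intercept; channel b
    (Cam2) scission from the abrupt-drop detector against its measured
    plateau amplitude.
    """
    spec = preset_lib.two_color_preset(preset)
    camera = preset_lib.event_camera(spec["channel_a"])
    offsets = []
    for _ in range(n_pairs):
        kin_a = preset_lib.sample_event_kinetics(spec["channel_a"], rng)
        kin_b = preset_lib.sample_event_kinetics(spec["channel_b"], rng)
        (trace_a, trace_b), _ = generate_two_color_event(
            kin_a, kin_b, spec["offset_b"], camera, seed=rng, channels=(spec["channel_a"], spec["channel_b"])
        )
        try:
            m_a = trace_analysis.measure_event(trace_a)
            m_b = trace_analysis.measure_event(trace_b, detect_scission_drop=True)
        except trace_analysis.MalformedEventError:
            continue
        if m_b.t_scis is None:
            continue
        offsets.append(m_b.t_scis - m_a.t_start)
    offsets = np.array(offsets)
    return {
        "mean_t_scis": float(offsets.mean()),
        "sem_t_scis": float(offsets.std(ddof=1) / np.sqrt(len(offsets))),
        "n": len(offsets),
    }


def titration_recovery(preset: str, rng: np.random.Generator, multistart: int = 32) -> dict:
    """Generate a preset titration and fit the sequential two-site model."""
    model, concentrations, noise_cv = preset_lib.titration_preset(preset)
    curve = generate_titration(model, concentrations, noise_cv, seed=rng)
    fit = fit_titration(
        curve.x,
        curve.signal,
        reporter_total=model.reporter_total,
        model_spec="two_site",
        multistart=multistart,
        seed=rng.integers(2**31),
    )
    return {
        "K1": fit.model.K1,
        "K1_report": fit.K1_report,
        "K2": fit.model.K2,
        "amp_fraction_2": fit.model.dF2 / (fit.model.dF1 + fit.model.dF2),
        "n": len(curve.x),
    }


def pca_recovery(rng: np.random.Generator, preset: str = "pca_titration") -> dict:
    """Generate a preset pCa titration and fit the Hill model."""
    model, pca_values, noise_cv = preset_lib.titration_preset(preset)
    curve = generate_pca_titration(model, pca_values, noise_cv, seed=rng)
    fit = fit_pca(curve.x, curve.signal, seed=rng.integers(2**31))
    return {"pCa50": fit.model.pCa50, "hill_n": fit.model.hill_n, "n": len(curve.x)}


def transient_recovery(rng: np.random.Generator, preset: str = "ca_release") -> dict:
    """Generate the calcium-release transient, select the phase count and
    fit the three-exponential model."""
    p = preset_lib.transient_preset(preset)
    times = split_timebase(p["dense_until"], p["dense_rate"], p["sparse_rate"], p["duration"])
    t, y = generate_transient(
        p["amplitudes"], p["rates"], 0.0, 0.0, p["noise_sd"], seed=rng, offset=p["offset"], times=times
    )
    seed = int(rng.integers(2**31))
    selection = select_n_phases(t, y, seed=seed)
    fit = fit_multiexp(t, y, 3, seed=seed)
    return {
        "rates": fit.rates,
        "amplitudes": fit.amplitudes,
        "recommended_n": selection.recommended_n,
        "n": len(t),
    }
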