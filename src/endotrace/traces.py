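"""Event quantification from background-corrected intensity traces.

The timing method is deliberately simple and matches standard practice
for endocytic TIRF traces: the rising and falling flanks are each fitted
with a straight line in the 60-point (3 s at 20 fps) contiguous window of
maximum (respectively minimum) slope, and the intercepts of those lines
with the zero-intensity baseline define the event start ``T_start`` and
end ``T_end``. Event duration is ``T_dur = T_end - T_start``; the plateau
amplitude ``A_av`` averages the 60 samples between 5 s and 8 s after
``T_start``. Amplitudes convert to molecule counts through a
single-fluorophore intensity calibration measured in a single-molecule
scene, corrected for the illumination difference between the two
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from endotrace.containers import IntensityTrace


class MalformedEventError(ValueError):
    """Raised when a trace does not contain a measurable event."""


def correct_background(
    core_trace,
    background_trace,
    core_pixel_count: int = 25,
    *,
    frame_interval: float,
    channel: str = "",
    source: str = "",
) -> IntensityTrace:
    """Subtract the local background from a raw ROI core trace.

    corrected = core - core_pixel_count * background, per frame, where
    ``background_trace`` is the mean per-pixel intensity of the
    surrounding annular region. After correction the baseline of a
    no-event trace sits at approximately zero.
    """
    core = np.asarray(core_trace, dtype=float)
    bg = np.asarray(background_trace, dtype=float)
    if core.shape != bg.shape:
        raise ValueError("core and background traces must have the same length")
    corrected = core - core_pixel_count * bg
    times = np.arange(len(corrected)) * frame_interval
    return IntensityTrace(
        time=times, intensity=corrected, frame_interval=frame_interval, channel=channel, source=source
    )


@dataclass(frozen=True)
class RampFit:
    """A straight-line fit to one flank of an event."""

    slope: float  # AU/s
    intercept: float  # AU at t=0
    window_start: int  # index of the first sample in the fitted window
    window_points: int
    r_squared: float

    @property
    def t_zero(self) -> float:
        """Time at which the fitted line crosses zero intensity."""
        return -self.intercept / self.slope


def fit_ramp(trace: IntensityTrace, window_points: int = 60, direction: str = "rising") -> RampFit:
    """Maximum-gradient straight-line fit over all contiguous windows.

    A least-squares line is fitted in every contiguous ``window_points``
    window (stride 1); the window with the maximum slope (``rising``) or
    minimum slope (``falling``) is returned, ties broken by the earliest
    window.
    """
    if direction not in ("rising", "falling"):
        raise ValueError(f"direction must be 'rising' or 'falling', got {direction!r}")
    y = trace.intensity
    t = trace.time
    n = window_points
    if len(y) < n:
        raise ValueError(f"trace has {len(y)} points; ramp fit needs at least {n}")
    dt = trace.frame_interval
    # Window-local regressors: x_i = i*dt, identical in every window.
    x = np.arange(n) * dt
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    # slope_k = sum_i xc_i * y[k+i] / sxx  for every window k, via convolution
    slopes = np.convolve(y, xc[::-1], mode="valid") / sxx
    means = np.convolve(y, np.ones(n) / n, mode="valid")
    # earliest window within numerical jitter of the extreme slope
    tol = 1e-9 * max(1.0, float(np.abs(slopes).max()))
    if direction == "rising":
        k = int(np.argmax(slopes >= slopes.max() - tol))
    else:
        k = int(np.argmax(slopes <= slopes.min() + tol))
    slope = float(slopes[k])
    mean_y = float(means[k])
    t_mid = float(t[k] + x.mean())
    intercept = mean_y - slope * t_mid
    yw = y[k : k + n]
    fitted = mean_y + slope * (t[k : k + n] - t_mid)
    ss_res = float(np.sum((yw - fitted) ** 2))
    ss_tot = float(np.sum((yw - mean_y) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RampFit(slope=slope, intercept=intercept, window_start=k, window_points=n, r_squared=r2)


@dataclass
class EventMeasurement:
    """Derived quantities of one endocytic event."""

    t_start: float
    t_end: float
    t_dur: float
    a_av: float
    rise_gradient: float
    fall_gradient: float
    t_scis: float | None = None
    a_pre_scis: float | None = None
    molecules: float | None = None
    rise_fit: RampFit | None = None
    fall_fit: RampFit | None = None
    flags: set = field(default_factory=set)


def detect_scission(
    trace: IntensityTrace,
    plateau: float,
    *,
    high_frac: float = 0.5,
    low_frac: float = 0.2,
    max_drop_time: float = 0.5,
) -> float | None:
    """Time of an abrupt (vesicle-scission) intensity drop, or None.

    Scission is the first transition where the signal falls from above
    ``high_frac`` of the plateau amplitude to below ``low_frac`` of it
    within ``max_drop_time`` seconds; the returned time is that of the
    first frame below the low threshold. A gradual disassembly ramp never
    produces such a fast transition and yields None.
    """
    if plateau <= 0:
        raise ValueError("plateau amplitude must be positive")
    y = trace.intensity
    dt = trace.frame_interval
    w = max(1, int(round(max_drop_time / dt)))
    high = y > high_frac * plateau
    low = y < low_frac * plateau
    for i in np.flatnonzero(high):
        seg = low[i + 1 : i + 1 + w]
        if seg.any():
            j = i + 1 + int(np.argmax(seg))
            return float(trace.time[j])
    return None


def measure_event(
    trace: IntensityTrace,
    window_points: int = 60,
    amplitude_window: tuple[float, float] = (5.0, 8.0),
    *,
    detect_scission_drop: bool = False,
    pre_scission_window: float = 1.0,
) -> EventMeasurement:
    """Measure timing and amplitude of the single event in a trace.

    ``T_start`` and ``T_end`` are the zero-intensity intercepts of the
    maximum-gradient rising and falling ramp lines; ``A_av`` averages the
    samples in ``[T_start + 5 s, T_start + 8 s)`` (truncated, and
    flagged, if the trace ends first). With ``detect_scission_drop`` the
    abrupt-drop detector runs against the measured plateau amplitude and,
    when scission is found, the pre-scission amplitude is averaged over
    the second preceding it.

    Raises
    ------
    MalformedEventError
        If the trace never rises or falls, or the falling intercept
        precedes the rising one.
    """
    rise = fit_ramp(trace, window_points=window_points, direction="rising")
    fall = fit_ramp(trace, window_points=window_points, direction="falling")
    if rise.slope <= 0:
        raise MalformedEventError("trace never rises: no positive-gradient window")
    if fall.slope >= 0:
        raise MalformedEventError("trace never falls: no negative-gradient window")
    t_start = rise.t_zero
    t_end = fall.t_zero
    if t_end <= t_start:
        raise MalformedEventError(
            f"falling intercept ({t_end:.3f} s) precedes rising intercept ({t_start:.3f} s)"
        )
    flags: set = set()
    lo = t_start + amplitude_window[0]
    hi = t_start + amplitude_window[1]
    if hi > trace.time[-1]:
        flags.add("amplitude-window-truncated")
    in_window = (trace.time >= lo) & (trace.time < hi)
    if not in_window.any():
        raise MalformedEventError("amplitude window lies entirely outside the trace")
    a_av = float(trace.intensity[in_window].mean())

    t_scis = None
    a_pre = None
    if detect_scission_drop and a_av > 0:
        t_scis = detect_scission(trace, plateau=a_av)
        if t_scis is not None:
            pre = (trace.time >= t_scis - pre_scission_window) & (trace.time < t_scis)
            if pre.any():
                a_pre = float(trace.intensity[pre].mean())
    return EventMeasurement(
        t_start=float(t_start),
        t_end=float(t_end),
        t_dur=float(t_end - t_start),
        a_av=a_av,
        rise_gradient=rise.slope,
        fall_gradient=fall.slope,
        t_scis=t_scis,
        a_pre_scis=a_pre,
        rise_fit=rise,
        fall_fit=fall,
        flags=flags,
    )


@dataclass
class AveragedProfile:
    """Point-wise average of event traces synchronised on an anchor."""

    time: np.ndarray  # s, relative to the anchor (t=0 at the anchor)
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    anchor: str
    mean_t_dur: float | None = None
    n_excluded: int = 0


def synchronize_and_average(
    traces: list[IntensityTrace],
    measurements: list[EventMeasurement | None],
    anchor: str = "T_start",
    external_anchors=None,
    *,
    min_count: int = 1,
) -> AveragedProfile:
    """Align traces on a per-event anchor and average them point-wise.

    Each trace is shifted so its anchor (``T_start``, ``T_end`` or an
    externally supplied time, e.g. the co-imaged second channel's
    ``T_start``) sits at t = 0, aligned to the nearest frame, then
    averaged on the common frame grid with per-point n and SEM. Traces
    with a missing anchor are excluded and counted in ``n_excluded``.
    The mean event duration of the included traces is recorded for
    profile reconstruction.
    """
    if len(traces) < 2:
        raise ValueError("averaging needs at least 2 traces")
    if anchor not in ("T_start", "T_end", "external"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if anchor == "external":
        if external_anchors is None or len(external_anchors) != len(traces):
            raise ValueError("external anchor requires one anchor time per trace")
    dt = traces[0].frame_interval
    shifted = []
    durations = []
    n_excluded = 0
    for i, trace in enumerate(traces):
        if abs(trace.frame_interval - dt) > 1e-9:
            raise ValueError("all traces must share one frame interval")
        m = measurements[i] if measurements is not None else None
        if anchor == "external":
            t0 = external_anchors[i]
        elif m is None:
            t0 = None
        else:
            t0 = m.t_start if anchor == "T_start" else m.t_end
        if t0 is None or not np.isfinite(t0):
            n_excluded += 1
            continue
        offset = int(round(t0 / dt))  # nearest-frame alignment, no interpolation
        idx = np.arange(len(trace)) - offset
        shifted.append((idx, trace.intensity))
        if m is not None:
            durations.append(m.t_dur)
    if len(shifted) < 2:
        raise ValueError("fewer than 2 traces have a usable anchor")
    lo = min(idx[0] for idx, _ in shifted)
    hi = max(idx[-1] for idx, _ in shifted)
    width = hi - lo + 1
    total = np.zeros(width)
    total_sq = np.zeros(width)
    count = np.zeros(width, dtype=int)
    for idx, y in shifted:
        sl = slice(idx[0] - lo, idx[0] - lo + len(y))
        total[sl] += y
        total_sq[sl] += y**2
        count[sl] += 1
    keep = count >= max(1, min_count)
    mean = np.full(width, np.nan)
    sem = np.full(width, np.nan)
    mean[keep] = total[keep] / count[keep]
    multi = count > 1
    var = np.full(width, np.nan)
    var[multi] = (total_sq[multi] - total[multi] ** 2 / count[multi]) / (count[multi] - 1)
    sem[multi] = np.sqrt(np.clip(var[multi], 0.0, None) / count[multi])
    times = (np.arange(lo, hi + 1)) * dt
    return AveragedProfile(
        time=times[keep],
        mean=mean[keep],
        sem=sem[keep],
        n=count[keep],
        anchor=anchor,
        mean_t_dur=float(np.mean(durations)) if durations else None,
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class CalibrationModel:
    """Single-fluorophore intensity calibration.

    ``single_fluorophore_intensity`` is measured in a dedicated
    single-molecule scene; ``excitation_scale`` is the illumination ratio
    between the event measurement and the calibration scene (events are
    typically imaged at reduced laser power, assumed linear).
    """

    single_fluorophore_intensity: float
    excitation_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.single_fluorophore_intensity <= 0 or self.excitation_scale <= 0:
            raise ValueError("calibration parameters must be positive")


def to_molecules(amplitude: float, calibration: CalibrationModel) -> float:
    """Convert an event amplitude (AU) to a fluorophore count.

    count = amplitude / (single_fluorophore_intensity * excitation_scale);
    returned as a real number, rounding left to callers.
    """
    return amplitude / (calibration.single_fluorophore_intensity * calibration.excitation_scale)


def estimate_single_fluorophore_intensity(
    tracks, excitation_scale: float = 1.0, min_tracks: int = 20
) -> CalibrationModel:
    """Calibrate the single-fluorophore intensity from molecule tracks.

    Takes the median of the per-track mean intensities (robust to the
    occasional double-occupancy or mis-linked track). ``tracks`` may be
    :class:`~endotrace.tracking.Trajectory` objects or plain per-track
    intensity arrays.
    """
    means = []
    for tr in tracks:
        intensities = getattr(tr, "intensities", tr)
        intensities = np.asarray(intensities, dtype=float)
        if len(intensities):
            means.append(intensities.mean())
    if len(means) < min_tracks:
        raise ValueError(f"calibration needs at least {min_tracks} tracks, got {len(means)}")
    return CalibrationModel(
        single_fluorophore_intensity=float(np.median(means)), excitation_scale=excitation_scale
    )
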