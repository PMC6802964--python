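"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Movie:
    """A time-ordered fluorescence image stack with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, Y, X)
        Pixel intensities in arbitrary camera units, one 2-D image per
        time point.
    pixel_size : float
        Lateral pixel size in micrometres.
    frame_interval : float
        Time between consecutive frames in seconds.
    channel : str
        Free-form channel label (e.g. ``"mNeonGreen"``).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be a (T, Y, X) stack, got ndim={self.frames.ndim}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, columns) of a single frame."""
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        """Total movie duration in seconds (n_frames * frame_interval)."""
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class IntensityTrace:
    """A uniformly sampled, background-corrected fluorescence time series.

    The trace is the substrate of all event-level analysis: after local
    background subtraction the pre- and post-event baseline sits at zero by
    construction, so ramp-line intercepts with zero intensity define event
    timing.
    """

    time: np.ndarray
    intensity: np.ndarray
    frame_interval: float
    channel: str = ""
    source: str = ""
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have identical shape")
        if self.time.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if len(self.time) > 1:
            steps = np.diff(self.time)
            if not np.allclose(steps, self.frame_interval, rtol=1e-6, atol=1e-9):
                raise ValueError("trace is not uniformly sampled at frame_interval")

    def __len__(self) -> int:
        return len(self.time)
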