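"""Parameter models and ground-truth records for the simulators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class EventKinetics:
    """Trapezoidal kinetics of a single endocytic accumulation event.

    The fluorophore count at an immobile membrane site rises linearly at
    ``rise_rate`` to ``peak_molecules``, persists for ``plateau_duration``
    and falls linearly at ``fall_rate``. With ``scission_mode="abrupt"``
    the event instead terminates with a single-frame loss of the whole
    population ``scission_offset`` seconds after the event start, the
    signature of a vesicle leaving the evanescent field.

    Units: rates in molecules/s, durations and offsets in seconds.
    """

    rise_rate: float
    peak_molecules: float
    plateau_duration: float
    fall_rate: float
    scission_mode: str = "none"
    scission_offset: float | None = None

    def __post_init__(self) -> None:
        if self.rise_rate <= 0 or self.fall_rate <= 0:
            raise ValueError("rise_rate and fall_rate must be positive")
        if self.peak_molecules <= 0:
            raise ValueError("peak_molecules must be positive")
        if self.plateau_duration < 0:
            raise ValueError("plateau_duration must be non-negative")
        if self.scission_mode not in ("none", "abrupt"):
            raise ValueError(f"unknown scission_mode {self.scission_mode!r}")
        if self.scission_mode == "abrupt":
            if self.scission_offset is None or self.scission_offset <= 0:
                raise ValueError("abrupt scission requires a positive scission_offset")
        if not np.isfinite(self.total_duration) or self.total_duration <= 0:
            raise ValueError("implied event duration must be finite and positive")

    @property
    def rise_time(self) -> float:
        return self.peak_molecules / self.rise_rate

    @property
    def fall_time(self) -> float:
        return self.peak_molecules / self.fall_rate

    @property
    def total_duration(self) -> float:
        """Event duration implied by the kinetics, in seconds.

        For an abrupt-scission event the trapezoid is truncated at the
        scission time.
        """
        full = self.rise_time + self.plateau_duration + self.fall_time
        if self.scission_mode == "abrupt" and self.scission_offset is not None:
            return min(full, self.scission_offset)
        return full

    def molecules(self, t: np.ndarray | float) -> np.ndarray:
        """Expected fluorophore count at time ``t`` after the event start."""
        t = np.asarray(t, dtype=float)
        up = self.rise_rate * t
        down = self.peak_molecules - self.fall_rate * (t - self.rise_time - self.plateau_duration)
        n = np.clip(np.minimum(np.minimum(up, self.peak_molecules), down), 0.0, None)
        if self.scission_mode == "abrupt" and self.scission_offset is not None:
            n = np.where(t >= self.scission_offset, 0.0, n)
        return n


@dataclass(frozen=True)
class SingleMoleculeKinetics:
    """Membrane binding kinetics of freely arriving single molecules.

    ``on_rate_density`` is the Poisson arrival rate of new binding events
    per square micrometre per second; bound molecules diffuse laterally
    with coefficient ``diffusion_coefficient`` (um^2/s) and unbind with
    exponential rate ``off_rate`` (1/s).
    """

    on_rate_density: float
    off_rate: float
    diffusion_coefficient: float

    def __post_init__(self) -> None:
        if self.on_rate_density < 0:
            raise ValueError("on_rate_density must be non-negative")
        if self.off_rate <= 0:
            raise ValueError("off_rate must be positive")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be non-negative")


@dataclass(frozen=True)
class CameraModel:
    """Idealised EMCCD camera and optics.

    ``single_fluorophore_intensity`` is the mean integrated signal (AU)
    contributed by one fluorophore per frame at the illumination used for
    that scene; shot noise is Poisson on expected counts, read noise is
    additive Gaussian per pixel, and the point-spread function is an
    isotropic 2-D Gaussian of width ``psf_sigma``.
    """

    pixel_size: float = 0.1
    frame_interval: float = 0.05
    psf_sigma: float = 0.12
    single_fluorophore_intensity: float = 52.7
    read_noise_sd: float = 10.0
    shot_noise: bool = True
    baseline_offset: float = 100.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.psf_sigma < self.pixel_size / 2:
            raise ValueError("psf_sigma must be at least half a pixel")
        if self.single_fluorophore_intensity <= 0:
            raise ValueError("single_fluorophore_intensity must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size


@dataclass
class EventTruth:
    """Ground truth for one rendered endocytic event."""

    t_start: float
    t_end: float
    t_scis: float | None = None
    position: tuple[float, float] | None = None  # (x_um, y_um)
    channel: str = ""
    kinetics: EventKinetics | None = None
    overlap_contaminated: bool = False


@dataclass
class TrackTruth:
    """Ground truth for one rendered single-molecule binding event."""

    t_on: float
    dwell: float
    frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    x_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    y_um: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class GroundTruth:
    """Complete ground truth for one generated dataset.

    Every rendered object appears exactly once: ``events`` holds one
    record per endocytic event, ``tracks`` one record per single-molecule
    binding event, and ``params`` the dataset-level model parameters.
    """

    events: list[EventTruth] = field(default_factory=list)
    tracks: list[TrackTruth] = field(default_factory=list)
    params: dict = field(default_factory=dict)
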