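"""Synthetic equilibrium titrations and stopped-flow transients."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from endotrace.binding import CaTitrationModel, SequentialBindingModel, predict_signal


@dataclass
class TitrationCurve:
    """A concentration-response table: x-axis values against signal (AU).

    ``x`` holds total ligand concentrations in uM for binding titrations,
    or pCa values for calcium titrations (``x_kind`` distinguishes them).
    """

    x: np.ndarray
    signal: np.ndarray
    x_kind: str = "concentration_uM"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.x.shape != self.signal.shape:
            raise ValueError("x and signal must have identical shape")


def generate_titration(
    model: SequentialBindingModel,
    ligand_concentrations,
    noise_cv: float = 0.0,
    seed: int | None = 0,
) -> TitrationCurve:
    """Simulate an equilibrium binding titration with multiplicative noise.

    The noiseless signal is the depletion-corrected sequential-binding
    prediction at each total ligand concentration; multiplicative
    Gaussian noise of coefficient of variation ``noise_cv`` is applied
    point-wise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conc = np.asarray(ligand_concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("ligand concentrations must be non-negative")
    signal = predict_signal(conc, model)
    if noise_cv > 0:
        signal = signal * (1.0 + rng.normal(0.0, noise_cv, size=signal.shape))
    return TitrationCurve(x=conc, signal=signal, x_kind="concentration_uM")


def generate_pca_titration(
    model: CaTitrationModel,
    pca_values,
    noise_cv: float = 0.0,
    seed: int | None = 0,
) -> TitrationCurve:
    """Simulate a pCa (calcium) titration from a Hill model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pca = np.asarray(pca_values, dtype=float)
    signal = model.predict(pca)
    if noise_cv > 0:
        signal = signal * (1.0 + rng.normal(0.0, noise_cv, size=signal.shape))
    return TitrationCurve(x=pca, signal=signal, x_kind="pCa")


def generate_transient(
    amplitudes,
    rates,
    duration: float,
    sample_rate: float,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    *,
    offset: float = 0.0,
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a multi-exponential stopped-flow record.

    y(t) = offset + sum_i A_i * exp(-k_i t) + Gaussian noise, sampled
    uniformly at ``sample_rate`` over ``duration`` — or on an explicit
    ``times`` axis (e.g. a split time base with dense early sampling),
    in which case ``duration``/``sample_rate`` are ignored.

    Returns ``(time_s, signal_au)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    amplitudes = np.asarray(amplitudes, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if amplitudes.shape != rates.shape:
        raise ValueError("amplitudes and rates must have the same length")
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    if len(np.unique(rates)) != len(rates):
        raise ValueError("duplicate rates are not identifiable")
    if times is None:
        if duration <= 0 or sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        times = np.arange(0.0, duration, 1.0 / sample_rate)
    else:
        times = np.asarray(times, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
    y = offset + np.sum(amplitudes[:, None] * np.exp(-np.outer(rates, times)), axis=0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return times, y


def split_timebase(dense_until: float, dense_rate: float, sparse_rate: float, duration: float) -> np.ndarray:
    """Two-regime stopped-flow time axis: dense early, sparse late.

    Mimics split-timebase acquisition so that a single record resolves
    both a >100 1/s phase and a ~2 1/s phase.
    """
    t_dense = np.arange(0.0, dense_until, 1.0 / dense_rate)
    t_sparse = np.arange(dense_until, duration, 1.0 / sparse_rate)
    return np.concatenate([t_dense, t_sparse])
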