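"""Multi-exponential fitting of stopped-flow transients.

Calcium release from calmodulin monitored by Quin-2 fluorescence (and
stopped-flow records generally) is described by a sum of exponentials,

    y(t) = offset + sum_i A_i exp(-k_i t),

one phase per kinetically distinct process. Fitting uses variable
projection: for any candidate rate set the amplitudes and offset are the
exact linear least-squares solution, so the nonlinear search runs only
over the rates, seeded from a log-spaced multistart grid. The number of
phases is chosen by a sequential F-test with AIC reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class TransientFit:
    """An N-exponential fit to a stopped-flow record.

    Rates are strictly positive and sorted descending; ``amplitudes[i]``
    belongs to ``rates[i]``. Amplitudes may take either sign (indicator
    signals can rise or fall).
    """

    n_phases: int
    amplitudes: np.ndarray
    rates: np.ndarray
    offset: float
    rss: float
    n_points: int
    stderr_rates: np.ndarray | None = None
    stderr_amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.rates) != self.n_phases or len(self.amplitudes) != self.n_phases:
            raise ValueError("n_phases must equal the number of rates and amplitudes")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be strictly positive")
        if self.n_phases > 1 and np.any(np.diff(self.rates) >= 0):
            raise ValueError("rates must be strictly descending")

    @property
    def n_params(self) -> int:
        return 2 * self.n_phases + 1

    @property
    def aic(self) -> float:
        """Akaike information criterion under iid Gaussian residuals."""
        n = self.n_points
        return n * np.log(self.rss / n) + 2 * self.n_params

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.offset + np.sum(self.amplitudes[:, None] * np.exp(-np.outer(self.rates, t)), axis=0)


def _linear_solve(t: np.ndarray, y: np.ndarray, rates: np.ndarray):
    """Best amplitudes/offset for fixed rates, plus residual vector."""
    design = np.column_stack([np.exp(-k * t) for k in rates] + [np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = design @ coef - y
    return coef[:-1], coef[-1], resid


def fit_multiexp(
    time_s,
    signal_au,
    n_phases: int,
    multistart: int = 16,
    seed: int | None = 0,
) -> TransientFit:
    """Fit an ``n_phases``-exponential decay by multistart least squares.

    Rate seeds are drawn log-uniformly between 0.5/t_max and 2/t_min
    (t_min = first nonzero sample time), plus a deterministic log-spaced
    start; amplitudes are profiled out exactly at every step. Standard
    errors come from the Gauss-Newton covariance at the optimum.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(signal_au, dtype=float)
    if t.shape != y.shape:
        raise ValueError("time and signal must have the same shape")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if not 1 <= n_phases <= 4:
        raise ValueError("n_phases must be between 1 and 4")
    if len(t) < 2 * n_phases + 2:
        raise ValueError("not enough points for the requested number of phases")
    rng = np.random.default_rng(seed)
    t_pos = t[t > 0]
    k_lo = 0.5 / t.max()
    k_hi = 2.0 / max(t_pos.min(), 1e-12) if len(t_pos) else 1e3 / t.max()

    log_span = (np.log(k_lo) - 6.0, np.log(k_hi) + 6.0)

    def objective(log_rates):
        # clamp so unconstrained LM steps cannot overflow the exponentials
        rates = np.exp(np.clip(log_rates, *log_span))
        _, _, resid = _linear_solve(t, y, rates)
        return resid

    starts = [np.linspace(np.log(k_lo * 2), np.log(k_hi / 2), n_phases)]
    for _ in range(max(0, multistart - 1)):
        starts.append(np.sort(rng.uniform(np.log(k_lo), np.log(k_hi), size=n_phases)))

    best = None
    for s0 in starts:
        try:
            sol = optimize.least_squares(objective, s0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("multi-exponential fit failed to converge from any start")

    rates = np.exp(best.x)
    amps, offset, resid = _linear_solve(t, y, rates)
    order = np.argsort(rates)[::-1]
    rates, amps = rates[order], amps[order]
    rss = float(resid @ resid)

    # Gauss-Newton covariance over the full parameter set (A_i, k_i, offset).
    stderr_k = stderr_a = None
    dof = len(t) - (2 * n_phases + 1)
    if dof > 0:
        cols = []
        for A, k in zip(amps, rates):
            e = np.exp(-k * t)
            cols.append(e)  # d/dA
            cols.append(-A * t * e)  # d/dk
        cols.append(np.ones_like(t))
        J = np.column_stack(cols)
        try:
            cov = np.linalg.inv(J.T @ J) * rss / dof
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            stderr_a = se[0 : 2 * n_phases : 2]
            stderr_k = se[1 : 2 * n_phases : 2]
        except np.linalg.LinAlgError:
            pass
    return TransientFit(
        n_phases=n_phases,
        amplitudes=amps,
        rates=rates,
        offset=float(offset),
        rss=rss,
        n_points=len(t),
        stderr_rates=stderr_k,
        stderr_amplitudes=stderr_a,
    )


@dataclass
class PhaseSelection:
    """Outcome of sequential phase-count selection."""

    recommended_n: int
    fits: dict[int, TransientFit]
    f_tests: dict[int, tuple[float, float]] = field(default_factory=dict)  # n -> (F, p) for n vs n+1

    @property
    def criteria_table(self) -> list[dict]:
        rows = []
        for n, fit in sorted(self.fits.items()):
            F, p = self.f_tests.get(n, (np.nan, np.nan))
            rows.append({"n_phases": n, "rss": fit.rss, "aic": fit.aic, "F_vs_next": F, "p_vs_next": p})
        return rows


def select_n_phases(
    time_s,
    signal_au,
    max_n: int = 4,
    alpha: float = 0.01,
    multistart: int = 16,
    seed: int | None = 0,
) -> PhaseSelection:
    """Choose the number of exponential phases by sequential F-testing.

    Fits n = 1..max_n and recommends the smallest n that is not rejected
    against n+1 by an extra-sum-of-squares F-test at level ``alpha``;
    AIC for every candidate is reported alongside in the criteria table.
    """
    if not 1 <= max_n <= 4:
        raise ValueError("max_n must be between 1 and 4")
    fits: dict[int, TransientFit] = {}
    for n in range(1, max_n + 1):
        try:
            fits[n] = fit_multiexp(time_s, signal_au, n, multistart=multistart, seed=seed)
        except (RuntimeError, ValueError):
            break
    sel = PhaseSelection(recommended_n=max(fits), fits=fits)
    n_pts = len(np.asarray(time_s))
    for n in sorted(fits):
        if n + 1 not in fits:
            break
        simple, complex_ = fits[n], fits[n + 1]
        extra = simple.rss - complex_.rss
        dof2 = n_pts - complex_.n_params
        if complex_.rss <= 0 or dof2 <= 0:
            F, p = np.inf, 0.0
        else:
            F = (extra / 2.0) / (complex_.rss / dof2)
            p = float(stats.f.sf(F, 2, dof2))
        sel.f_tests[n] = (float(F), p)
        if p >= alpha:
            sel.recommended_n = n
            break
    else:
        sel.recommended_n = max(fits)
        return sel
    return sel
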