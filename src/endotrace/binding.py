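"""Equilibrium models of calmodulin binding to the myosin-1 IQ neck.

The core model is a sequential (ordered) two-site binding scheme: a
calmodulin light chain binds the first IQ motif (IQ1) with dissociation
constant ``K1``, and only an IQ1-occupied neck can accept a second light
chain at IQ2 with constant ``K2``. The ordering is structural — there is
no IQ2-only species — encoding the observation that stable residency at
IQ1 is a prerequisite for IQ2 occupancy. Each binding step changes the
FRET reporter signal by its own amplitude.

Because titrations are performed at reporter concentrations comparable to
the dissociation constants, free-ligand depletion is handled explicitly:
the free calmodulin concentration is recovered from total concentration
by numerically inverting the mass-conservation relation.

The module also provides Hill fits of pCa titrations and the standard
FRET efficiency <-> distance conversion through the Forster radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class SequentialBindingModel:
    """Ordered two-site binding of a ligand to a tandem-IQ reporter.

    Parameters
    ----------
    K1, K2 : float
        Step dissociation constants in uM for the first (IQ1) and second
        (IQ2) site. A one-site model is the ``K2 = inf`` limit.
    dF1, dF2 : float
        Signal change (AU) contributed by the first and second binding
        step at full occupancy.
    F0 : float
        Baseline signal at zero ligand.
    reporter_total : float
        Total reporter (IQ construct) concentration in uM, used for the
        depletion correction.
    """

    K1: float
    K2: float
    dF1: float
    dF2: float
    F0: float
    reporter_total: float

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.reporter_total <= 0:
            raise ValueError("reporter_total must be positive")


def occupancy(free_ligand_uM, model: SequentialBindingModel):
    """Fractional occupancies (f1, f2) at a given free-ligand concentration.

    ``f1`` is the fraction of reporter with at least one site occupied,
    ``f2`` the fraction with both sites occupied. With partition function
    Z = 1 + L/K1 + L^2/(K1 K2):

        f1 = (L/K1 + L^2/(K1 K2)) / Z,   f2 = (L^2/(K1 K2)) / Z

    so 0 <= f2 <= f1 <= 1 everywhere and both rise monotonically with L.
    """
    L = np.asarray(free_ligand_uM, dtype=float)
    if np.any(L < 0):
        raise ValueError("free ligand concentration must be non-negative")
    x1 = L / model.K1
    x2 = x1 * (L / model.K2) if np.isfinite(model.K2) else np.zeros_like(L)
    Z = 1.0 + x1 + x2
    f1 = (x1 + x2) / Z
    f2 = x2 / Z
    return f1, f2


def _bound_ligand(L, model: SequentialBindingModel):
    """Ligand concentration sequestered by the reporter at free conc L."""
    f1, f2 = occupancy(L, model)
    # singly bound fraction carries 1 ligand, doubly bound carries 2
    return model.reporter_total * ((f1 - f2) + 2.0 * f2)


def free_ligand(ligand_total_uM, model: SequentialBindingModel, rtol: float = 1e-10):
    """Free ligand concentration after depletion by the reporter.

    Solves L + bound(L) = total for the unique root L in [0, total] by
    Brent bracketing to relative tolerance ``rtol``. The left-hand side
    is strictly increasing in L, so the root is unique.
    """
    totals = np.atleast_1d(np.asarray(ligand_total_uM, dtype=float))
    if np.any(totals < 0):
        raise ValueError("total ligand concentration must be non-negative")
    out = np.empty_like(totals)
    for i, total in enumerate(totals):
        if total == 0.0:
            out[i] = 0.0
            continue
        fun = lambda L: L + _bound_ligand(L, model) - total  # noqa: E731
        out[i] = optimize.brentq(fun, 0.0, total, rtol=rtol, xtol=1e-300, maxiter=200)
    if np.isscalar(ligand_total_uM) or np.asarray(ligand_total_uM).ndim == 0:
        return float(out[0])
    return out


def predict_signal(ligand_totals_uM, model: SequentialBindingModel):
    """Depletion-corrected signal at the given total ligand concentrations.

    F = F0 + dF1 * f1 + dF2 * f2, evaluated at the free-ligand
    concentration implied by mass conservation.
    """
    L = free_ligand(ligand_totals_uM, model)
    f1, f2 = occupancy(L, model)
    return model.F0 + model.dF1 * f1 + model.dF2 * f2


@dataclass
class TitrationFit:
    """Result of fitting a binding titration."""

    model: SequentialBindingModel
    model_spec: str
    k1_is_upper_bound: bool
    chisqr: float
    conf_intervals: dict = field(default_factory=dict)
    n_multistart: int = 0

    @property
    def K1_report(self) -> str:
        """K1 as the paper-style report: a point value, or an upper bound
        when binding is too tight to resolve at the working reporter
        concentration."""
        if self.k1_is_upper_bound:
            return f"K1 < {self.model.reporter_total:g} uM"
        return f"K1 = {self.model.K1:.3g} uM"


def fit_titration(
    concentrations_uM,
    signal_au,
    reporter_total: float,
    model_spec: str = "two_site",
    bounds: tuple[float, float] = (1e-3, 1e3),
    multistart: int = 32,
    seed: int | None = 0,
    n_boot: int = 0,
) -> TitrationFit:
    """Fit the depletion-corrected sequential binding model to a titration.

    Least squares over (K1, K2, dF1, dF2, F0) — or (K1, dF1, F0) for
    ``model_spec="one_site"`` — with ``multistart`` restarts drawn
    log-uniformly over ``bounds`` for the dissociation constants.
    When the fitted K1 is tighter than a fifth of the reporter
    concentration the result is flagged as an upper bound
    (``k1_is_upper_bound``): at such stoichiometric conditions the data
    constrain only "binding is tight", not the constant itself.

    Bootstrap confidence intervals (residual resampling, refit from the
    best point) are computed when ``n_boot`` > 0.
    """
    conc = np.asarray(concentrations_uM, dtype=float)
    y = np.asarray(signal_au, dtype=float)
    if conc.shape != y.shape:
        raise ValueError("concentration and signal arrays must match")
    if len(conc) < 8:
        raise ValueError("need at least 8 titration points spanning the transition")
    if model_spec not in ("two_site", "one_site"):
        raise ValueError(f"unknown model_spec {model_spec!r}")
    rng = np.random.default_rng(seed)
    two_site = model_spec == "two_site"

    # Fluorimeter noise scales with the signal, so residuals are weighted
    # by 1/|y| (floored to avoid blowing up near-zero points).
    w = 1.0 / np.clip(np.abs(y), 0.05 * np.abs(y).max(), None)

    span = float(y.max() - y.min())
    rising = y[np.argmax(conc)] >= y[np.argmin(conc)]
    amp0 = span if rising else -span

    def build_model(p) -> SequentialBindingModel:
        return SequentialBindingModel(
            K1=10.0 ** p["logK1"].value,
            K2=10.0 ** p["logK2"].value if two_site else np.inf,
            dF1=p["dF1"].value,
            dF2=p["dF2"].value if two_site else 0.0,
            F0=p["F0"].value,
            reporter_total=reporter_total,
        )

    def residual(p):
        return (predict_signal(conc, build_model(p)) - y) * w

    lo, hi = bounds
    # A dissociation constant far above the titrated range is not
    # measurable from the data; cap the search accordingly.
    hi = min(hi, 10.0 * conc.max())
    # Each phase amplitude is bounded by (twice) the total observed
    # change, which excludes degenerate huge-K/huge-amplitude solutions.
    amp_lo, amp_hi = (0.0, 2.0 * span) if rising else (-2.0 * span, 0.0)
    best = None
    for _ in range(max(1, multistart)):
        p = lmfit.Parameters()
        # Dissociation constants are fitted on a log10 scale: Kd is a
        # scale parameter, and the log parameterisation keeps the search
        # well conditioned across the bounded decades.
        k_starts = np.sort(rng.uniform(np.log10(lo), np.log10(hi), size=2))
        p.add("logK1", value=k_starts[0], min=np.log10(lo), max=np.log10(hi))
        if two_site:
            p.add("logK2", value=k_starts[1], min=np.log10(lo), max=np.log10(hi))
        p.add("dF1", value=amp0 / (2.0 if two_site else 1.0), min=amp_lo, max=amp_hi)
        if two_site:
            p.add("dF2", value=amp0 / 2.0, min=amp_lo, max=amp_hi)
        p.add("F0", value=float(y[np.argmin(conc)]))
        try:
            res = lmfit.minimize(residual, p, method="least_squares")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("titration fit failed to converge from any start")

    model = build_model(best.params)
    fit = TitrationFit(
        model=model,
        model_spec=model_spec,
        k1_is_upper_bound=model.K1 < reporter_total / 5.0,
        chisqr=float(best.chisqr),
        n_multistart=multistart,
    )
    if n_boot > 0:
        resid = residual(best.params)
        samples = {name: [] for name in best.params}
        for _ in range(n_boot):
            y_boot = predict_signal(conc, model) + rng.choice(resid / w, size=len(resid), replace=True)

            def residual_boot(p, y_boot=y_boot):
                return (predict_signal(conc, build_model(p)) - y_boot) * w

            try:
                res_b = lmfit.minimize(residual_boot, best.params.copy(), method="least_squares")
            except Exception:
                continue
            for name in samples:
                samples[name].append(res_b.params[name].value)
        fit.conf_intervals = {
            name: tuple(np.percentile(vals, [2.5, 97.5])) for name, vals in samples.items() if vals
        }
    return fit


@dataclass(frozen=True)
class CaTitrationModel:
    """Phenomenological Hill description of a calcium (pCa) titration.

    Y(pCa) = Ymin + (Ymax - Ymin) / (1 + 10^(hill_n * (pCa50 - pCa)))

    so the signal approaches ``Ymax`` at high pCa (low calcium) and
    ``Ymin`` at low pCa; a falling curve simply has Ymax < Ymin.
    """

    pCa50: float
    hill_n: float
    Ymax: float
    Ymin: float

    def __post_init__(self) -> None:
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")
        if not (4.0 <= self.pCa50 <= 9.0):
            raise ValueError("pCa50 outside the physiological range [4, 9]")

    def predict(self, pca):
        pca = np.asarray(pca, dtype=float)
        return self.Ymin + (self.Ymax - self.Ymin) / (1.0 + 10.0 ** (self.hill_n * (self.pCa50 - pca)))


@dataclass
class CaTitrationFit:
    model: CaTitrationModel
    chisqr: float
    stderr: dict = field(default_factory=dict)


def fit_pca(pca_values, signal_au, hill_n: float | None = None, seed: int | None = 0) -> CaTitrationFit:
    """Fit a Hill pCa curve; the transition direction is inferred from data.

    Parameters
    ----------
    hill_n : float, optional
        Fix the Hill coefficient to this value instead of floating it.

    Raises
    ------
    ValueError
        If the data do not bracket the fitted midpoint (the titration
        must span the transition for pCa50 to be identifiable).
    """
    pca = np.asarray(pca_values, dtype=float)
    y = np.asarray(signal_au, dtype=float)
    if pca.shape != y.shape:
        raise ValueError("pCa and signal arrays must match")
    if len(pca) < 6:
        raise ValueError("need at least 6 pCa points bracketing the transition")

    order = np.argsort(pca)
    y_low, y_high = y[order[0]], y[order[-1]]
    p = lmfit.Parameters()
    p.add("pCa50", value=float(np.median(pca)), min=4.0, max=9.0)
    p.add("hill_n", value=hill_n if hill_n is not None else 2.0, min=0.05, max=10.0, vary=hill_n is None)
    p.add("Ymax", value=float(y_high))
    p.add("Ymin", value=float(y_low))

    def residual(p):
        m = CaTitrationModel(p["pCa50"].value, p["hill_n"].value, p["Ymax"].value, p["Ymin"].value)
        return m.predict(pca) - y

    res = lmfit.minimize(residual, p, method="least_squares")
    model = CaTitrationModel(
        res.params["pCa50"].value, res.params["hill_n"].value, res.params["Ymax"].value, res.params["Ymin"].value
    )
    if not (pca.min() <= model.pCa50 <= pca.max()):
        raise ValueError("pCa data do not bracket the transition midpoint")
    stderr = {k: (v.stderr if v.stderr is not None else np.nan) for k, v in res.params.items()}
    return CaTitrationFit(model=model, chisqr=float(res.chisqr), stderr=stderr)


@dataclass(frozen=True)
class ForsterPair:
    """A FRET donor/acceptor pair characterised by its Forster radius.

    Default is the CyPet-YPet pair, R0 = 5.301 nm.
    """

    R0: float = 5.301

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")


def efficiency_to_distance(E: float, pair: ForsterPair = ForsterPair()) -> float:
    """Inter-fluorophore distance (nm) from FRET efficiency.

    R = R0 * (1/E - 1)^(1/6); E = 0.5 gives R = R0 by definition.
    """
    if not (0.0 < E < 1.0):
        raise ValueError("FRET efficiency must lie strictly between 0 and 1")
    return pair.R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)


def distance_to_efficiency(R: float, pair: ForsterPair = ForsterPair()) -> float:
    """FRET efficiency from inter-fluorophore distance (nm)."""
    if R <= 0:
        raise ValueError("distance must be positive")
    return 1.0 / (1.0 + (R / pair.R0) ** 6)
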