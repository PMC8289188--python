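"""Nonlinear least-squares estimation of every model in :mod:`.models`.

Each fitter consumes one measured (or synthetic) curve and returns the
model parameters with covariance-based standard errors and residual
diagnostics.  Conventions shared by all fitters:

* data-driven starting values (half-plateau time for the kinetic rate,
  half-signal-change concentration for Kd, initial Stern–Volmer slope
  for Ksv), with five log-spaced multi-start perturbations if the first
  attempt does not converge;
* physical bounds (rates, amplitudes, Kd, Ksv, V all nonnegative);
* cost tolerance 1e-10, at most 2000 function evaluations per start;
* degenerate inputs raise :class:`FitFailureError` or
  :class:`InputError` rather than returning garbage estimates.

Replicates are fitted separately by default; condition-level summaries
(mean ± SD over replicates) are assembled by the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import lmfit
import numpy as np
from numpy.typing import NDArray

from .models import (
    BindingParams,
    QuenchParams,
    RateConcParams,
    action_volume_to_radius,
    isodesmic_extent,
    rate_vs_conc,
    titration_signal,
)

__all__ = [
    "KineticTrace",
    "KineticFit",
    "TitrationCurve",
    "QuenchCurve",
    "BindingFit",
    "QuenchFit",
    "RateConcFit",
    "InputError",
    "FitFailureError",
    "ConfigurationError",
    "normalize_panel",
    "fit_kinetic_trace",
    "fit_rate_concentration",
    "fit_titration",
    "fit_quenching",
]

_MAX_NFEV = 2000
_COST_TOL = 1e-10
# multiplicative perturbations applied to the primary start on retry
_MULTISTART = (0.1, 0.31623, 3.1623, 10.0, 100.0)


class InputError(ValueError):
    """Input data violate a fitter's preconditions."""


class ConfigurationError(ValueError):
    """A requested condition or option is absent from the data."""


class FitFailureError(RuntimeError):
    """The optimiser failed on all starts; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class KineticTrace:
    """One ThT fluorescence time series with its condition metadata."""

    times: NDArray[np.float64]  # hours, strictly increasing
    signal: NDArray[np.float64]  # ThT fluorescence, a.u.
    protein_conc: float = 75.0  # μM
    pom_id: str = "none"  # none | Nb10 | TiNb9
    pom_conc: float = 0.0  # μM
    replicate: int = 0
    well: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise InputError("times and signal must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise InputError("signal contains non-finite values")


@dataclass(frozen=True)
class KineticFit:
    """Isodesmic fit of one kinetic trace: signal = baseline + amplitude·p(t; k)."""

    k: float  # apparent rate, h⁻¹
    amplitude: float  # a.u.
    baseline: float  # a.u.
    se_k: float
    se_amplitude: float
    se_baseline: float
    rss: float
    nfev: int
    trace: KineticTrace | None = None


@dataclass
class TitrationCurve:
    """Fluorescence titration: signal versus ligand concentration."""

    conc: NDArray[np.float64]  # μM, nonnegative increasing
    signal: NDArray[np.float64]  # a.u.
    probe: str = "intrinsic-Trp"  # intrinsic-Trp | ANS | ThT

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.conc.shape != self.signal.shape:
            raise InputError("conc and signal must have equal length")
        if np.any(self.conc < 0):
            raise InputError("concentrations must be nonnegative")
        if np.any(np.diff(self.conc) < 0):
            raise InputError("concentrations must be sorted increasing")


@dataclass
class QuenchCurve:
    """Acrylamide quenching: fluorescence versus quencher concentration."""

    Q: NDArray[np.float64]  # M, nonnegative increasing
    F: NDArray[np.float64]  # a.u., positive

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.Q.shape != self.F.shape:
            raise InputError("Q and F must have equal length")
        if np.any(self.Q < 0) or np.any(np.diff(self.Q) < 0):
            raise InputError("Q must be nonnegative and sorted increasing")
        if np.any(self.F <= 0):
            raise InputError("fluorescence must be strictly positive")


@dataclass(frozen=True)
class BindingFit:
    """One-site isotherm fit with uncertainties."""

    params: BindingParams
    se_Kd: float
    se_S0: float
    se_Sinf: float
    rss: float
    unidentifiable: bool = False
    bootstrap_se_Kd: float | None = None


@dataclass(frozen=True)
class QuenchFit:
    """Sphere-of-action fit: Stern–Volmer constant, action volume, radius."""

    params: QuenchParams
    r: float  # Å, derived from V
    se_Ksv: float
    se_V: float
    rss: float


@dataclass(frozen=True)
class RateConcFit:
    """Exponential dose-response fit of apparent rates versus POM concentration."""

    params: RateConcParams
    se_alpha: float
    se_beta: float
    se_gamma: float
    rss: float
    beta_pinned: bool = False  # beta driven to its lower bound (model mismatch)
    parameterization: str = "rate"


def _is_reference(trace: KineticTrace, reference_condition: str) -> bool:
    if reference_condition in ("none", "protein-alone"):
        return trace.pom_conc == 0.0 or trace.pom_id == "none"
    return trace.pom_id == reference_condition


def normalize_panel(
    traces: list[KineticTrace], reference_condition: str = "none"
) -> list[KineticTrace]:
    """Scale a kinetic panel to the POM-free reference maximum.

    Every trace's signal is divided by the maximum ThT intensity of the
    reference (inhibitor-free) condition, averaged over its replicates,
    so the reference plateau maps to 1.0.  Idempotent up to floating
    point: a second pass divides by 1.0.
    """
    ref_maxima = [
        float(np.max(tr.signal)) for tr in traces if _is_reference(tr, reference_condition)
    ]
    if not ref_maxima:
        raise ConfigurationError(
            f"reference condition {reference_condition!r} not present in panel"
        )
    scale = float(np.mean(ref_maxima))
    if scale <= 0:
        raise ConfigurationError("reference maximum is nonpositive; cannot normalize")
    return [replace(tr, signal=tr.signal / scale) for tr in traces]


def _run_lmfit(model, params, starts, x, y, start_name):
    """Fit with multi-start fallback; return the best converged result."""
    best = None
    tried = []
    for s in starts:
        p = params.copy()
        p[start_name].value = s
        try:
            res = model.fit(
                y, p, x=x, max_nfev=_MAX_NFEV, fit_kws={"ftol": _COST_TOL, "xtol": _COST_TOL}
            )
        except Exception as exc:  # singular Jacobian, nan cost, ...
            tried.append((s, repr(exc)))
            continue
        tried.append((s, res.chisqr))
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    return best, tried


def _stderr(result, name: str) -> float:
    p = result.params[name]
    return float(p.stderr) if p.stderr is not None else float("nan")


def fit_kinetic_trace(trace: KineticTrace) -> KineticFit:
    """Fit signal(t) = baseline + amplitude · k·t/(1 + k·t) to one trace.

    The start value of k is taken from the time at which the signal
    crosses half of its total change (p = 1/2 at t = 1/k).  Raises
    :class:`FitFailureError` on degenerate traces (constant or
    monotonically decreasing signal) and on non-convergence.
    """
    t, y = trace.times, trace.signal
    if t.size < 8:
        raise InputError("kinetic fit requires at least 8 time points")
    span = float(np.ptp(y))
    if span == 0.0:
        raise FitFailureError("constant signal: no kinetics to fit")
    if np.all(np.diff(y) <= 0) and y[-1] < y[0]:
        raise FitFailureError("monotonically decreasing signal: not polymerization kinetics")

    base0 = float(np.min(y))
    half = base0 + span / 2.0
    above = np.nonzero(y >= half)[0]
    t_half = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1]) / 2.0
    k0 = 1.0 / t_half

    model = lmfit.Model(lambda x, k, amplitude, baseline: baseline + amplitude * isodesmic_extent(x, k))
    params = model.make_params(k=k0, amplitude=span, baseline=base0)
    params["k"].min = 1e-12
    params["amplitude"].min = 0.0

    starts = [k0] + [k0 * m for m in _MULTISTART]
    best, tried = _run_lmfit(model, params, starts, t, y, "k")
    if best is None:
        raise FitFailureError("kinetic fit did not converge", {"starts": tried})
    return KineticFit(
        k=float(best.params["k"].value),
        amplitude=float(best.params["amplitude"].value),
        baseline=float(best.params["baseline"].value),
        se_k=_stderr(best, "k"),
        se_amplitude=_stderr(best, "amplitude"),
        se_baseline=_stderr(best, "baseline"),
        rss=float(best.chisqr),
        nfev=int(best.nfev),
        trace=trace,
    )


def fit_rate_concentration(
    points: list[tuple[float, float]], parameterization: str = "rate"
) -> RateConcFit:
    """Fit k(c) = α·e^(−βc) + γ to (POM concentration, apparent rate) pairs.

    Requires at least four distinct concentrations including zero.
    β is bounded at 0; data with rates increasing in concentration pin
    β at the bound, which is reported in ``beta_pinned`` (the
    exponential-inhibition model does not describe such data).
    """
    pts = sorted((float(c), float(k)) for c, k in points)
    c = np.array([p[0] for p in pts])
    k = np.array([p[1] for p in pts])
    if np.unique(c).size < 4:
        raise InputError("rate-concentration fit requires >= 4 distinct concentrations")
    if c[0] != 0.0:
        raise InputError("rate-concentration fit requires a zero-POM point")

    gamma0 = max(float(np.min(k)), 0.0)
    alpha0 = max(float(k[0]) - gamma0, 1e-6 + float(np.ptp(k)))
    # decay scale from where the rate has lost half its amplitude
    below = np.nonzero(k <= gamma0 + alpha0 / 2.0)[0]
    c_half = float(c[below[0]]) if below.size and c[below[0]] > 0 else float(np.mean(c[1:]))
    beta0 = math.log(2.0) / c_half if parameterization == "rate" else c_half / math.log(2.0)

    def f(x, alpha, beta, gamma):
        return rate_vs_conc(x, RateConcParams(alpha, beta, gamma), parameterization)

    model = lmfit.Model(f)
    params = model.make_params(alpha=alpha0, beta=beta0, gamma=gamma0)
    params["alpha"].min = 0.0
    params["gamma"].min = 0.0
    params["beta"].min = 1e-9 if parameterization == "scale" else 0.0

    best, tried = _run_lmfit(model, params, [beta0] + [beta0 * m for m in _MULTISTART], c, k, "beta")
    if best is None:
        raise FitFailureError("rate-concentration fit did not converge", {"starts": tried})
    beta_hat = float(best.params["beta"].value)
    alpha_hat = float(best.params["alpha"].value)
    # model mismatch (non-decreasing rates) drives either beta or the
    # whole exponential amplitude to the zero bound
    pinned = beta_hat <= max(1e-8, 1e-6 * beta0) or alpha_hat <= 1e-9 * max(alpha0, 1.0)
    return RateConcFit(
        params=RateConcParams(
            float(best.params["alpha"].value), beta_hat, float(best.params["gamma"].value)
        ),
        se_alpha=_stderr(best, "alpha"),
        se_beta=_stderr(best, "beta"),
        se_gamma=_stderr(best, "gamma"),
        rss=float(best.chisqr),
        beta_pinned=pinned,
        parameterization=parameterization,
    )


def fit_titration(
    curve: TitrationCurve,
    depletion: bool = False,
    protein_conc: float | None = None,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> BindingFit:
    """Fit the one-site isotherm S(c) = S0 + (S∞ − S0)·θ(c) to a titration.

    θ is the Langmuir bound fraction by default, or the
    depletion-corrected exact solution when ``depletion`` is set (then
    ``protein_conc`` in μM is required).  A curve whose fitted signal
    change does not exceed the residual noise is flagged
    ``unidentifiable``.  Optional seeded residual bootstrap adds
    ``bootstrap_se_Kd``.
    """
    c, y = curve.conc, curve.signal
    if np.unique(c).size < 5:
        raise InputError("titration fit requires >= 5 distinct concentrations")

    S0_0, Sinf_0 = float(y[0]), float(y[-1])
    if np.ptp(y) == 0.0:
        return BindingFit(
            params=BindingParams(Kd=float(np.median(c[c > 0])), S0=S0_0, Sinf=Sinf_0),
            se_Kd=float("nan"), se_S0=float("nan"), se_Sinf=float("nan"),
            rss=0.0, unidentifiable=True,
        )
    half = (S0_0 + Sinf_0) / 2.0
    crossed = np.nonzero((y - half) * (y[0] - half) <= 0)[0]
    Kd0 = float(c[crossed[0]]) if crossed.size and c[crossed[0]] > 0 else float(np.median(c[c > 0]))

    def f(x, Kd, S0, Sinf):
        return titration_signal(x, BindingParams(Kd, S0, Sinf), depletion, protein_conc)

    model = lmfit.Model(f)
    params = model.make_params(Kd=Kd0, S0=S0_0, Sinf=Sinf_0)
    params["Kd"].min = 1e-9

    best, tried = _run_lmfit(model, params, [Kd0] + [Kd0 * m for m in _MULTISTART], c, y, "Kd")
    if best is None:
        raise FitFailureError("titration fit did not converge", {"starts": tried})

    fitted = BindingParams(
        float(best.params["Kd"].value),
        float(best.params["S0"].value),
        float(best.params["Sinf"].value),
    )
    resid_sd = math.sqrt(best.chisqr / max(len(y) - 3, 1))
    unident = abs(fitted.S0 - fitted.Sinf) <= 3.0 * resid_sd

    boot_se = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        yhat = f(c, fitted.Kd, fitted.S0, fitted.Sinf)
        resid = y - yhat
        kds = []
        for _ in range(n_bootstrap):
            yb = yhat + rng.choice(resid, size=resid.size, replace=True)
            try:
                rb = model.fit(yb, best.params.copy(), x=c, max_nfev=_MAX_NFEV)
            except Exception:
                continue
            if rb.success:
                kds.append(float(rb.params["Kd"].value))
        if kds:
            boot_se = float(np.std(kds, ddof=1))

    return BindingFit(
        params=fitted,
        se_Kd=_stderr(best, "Kd"),
        se_S0=_stderr(best, "S0"),
        se_Sinf=_stderr(best, "Sinf"),
        rss=float(best.chisqr),
        unidentifiable=unident,
        bootstrap_se_Kd=boot_se,
    )


def fit_quenching(curve: QuenchCurve) -> QuenchFit:
    """Fit the sphere-of-action model to an acrylamide quenching curve.

    F0 is the measured zero-quencher fluorescence (not a fitted
    parameter, matching the plotted F0/F convention); the Stern–Volmer
    ratio F0/F is then fitted with (1 + Ksv·Q)·exp(V·Q), both
    parameters bounded nonnegative, and the action volume converted to
    the equivalent radius.
    """
    Q, F = curve.Q, curve.F
    if Q.size < 6:
        raise InputError("quenching fit requires >= 6 quencher concentrations")
    if Q[0] != 0.0:
        raise InputError("quenching fit requires a Q = 0 point for F0")
    slope, _ = np.polyfit(Q, F, 1)
    if slope > 0:
        raise FitFailureError("fluorescence increases with quencher: not quenching data")

    F0 = float(F[0])
    ratio = F0 / F
    # start Ksv at the initial Stern-Volmer slope, V at (near) zero
    ksv0 = max(float((ratio[1] - 1.0) / Q[1]), 1e-3)

    def f(x, Ksv, V):
        return (1.0 + Ksv * x) * np.exp(V * x)

    model = lmfit.Model(f)
    params = model.make_params(Ksv=ksv0, V=1e-6)
    params["Ksv"].min = 0.0
    params["V"].min = 0.0
    # cap the action volume so exp(V*Q) cannot overflow during search;
    # V = 100 M^-1 is a ~34 A radius, far beyond any Trp environment
    params["V"].max = 100.0
    params["Ksv"].max = 1e4

    best, tried = _run_lmfit(model, params, [ksv0] + [ksv0 * m for m in _MULTISTART], Q, ratio, "Ksv")
    if best is None:
        raise FitFailureError("quenching fit did not converge", {"starts": tried})
    qp = QuenchParams(float(best.params["Ksv"].value), float(best.params["V"].value))
    return QuenchFit(
        params=qp,
        r=float(action_volume_to_radius(qp.V)),
        se_Ksv=_stderr(best, "Ksv"),
        se_V=_stderr(best, "V"),
        rss=float(best.chisqr),
    )
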