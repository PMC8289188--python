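"""Seeded generators for every input the analysis consumes.

The generators emulate the statistical structure of the study's
instrument data so that the whole pipeline is testable without any
instrument files:

* ThT kinetic panels: lag-free hyperbolic growth whose apparent rate
  and plateau both decay exponentially with POM concentration, in
  triplicate, with multiplicative plate-reader-like noise;
* fluorescence titrations: decreasing one-site binding curves with Kd
  in the low-μM range;
* acrylamide quenching curves: upward-curving Stern–Volmer behaviour
  from the sphere-of-action model;
* CD-like spectra as sums of Gaussian bands with per-repeat noise;
* AFM fibril height samples from a log-normal law parameterized by its
  median and median absolute deviation (log-normal guarantees
  positivity).

Every generator is a deterministic function of its parameters and the
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import brentq
from scipy.stats import norm

from .fitting import KineticTrace, QuenchCurve, TitrationCurve
from .models import (
    BindingParams,
    QuenchParams,
    RateConcParams,
    isodesmic_extent,
    radius_to_action_volume,
    rate_vs_conc,
    sphere_of_action_ratio,
    titration_signal,
)
from .spectra import Spectrum

__all__ = [
    "PanelDesign",
    "DEFAULT_RATE_MODEL",
    "DEFAULT_PLATEAU_MODEL",
    "gen_kinetic_panel",
    "gen_titration_curve",
    "gen_quenching_curve",
    "gen_spectrum",
    "gen_heights",
]

# Dose-response of the apparent rate and of the ThT plateau used by the
# default panel.  Chosen once so that the highest-dose condition (750 μM
# POM at 75 μM protein, 1:10) retains a few percent of the reference
# rate and ~10% of the reference plateau, mirroring strong but
# incomplete inhibition.
DEFAULT_RATE_MODEL = RateConcParams(alpha=0.2, beta=0.005, gamma=0.01)
DEFAULT_PLATEAU_MODEL = RateConcParams(alpha=0.9, beta=0.003, gamma=0.1)
_DEFAULT_RATIOS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0)


def _default_time_grid() -> NDArray[np.float64]:
    # 150 h sampled every 10 min
    return np.arange(0.0, 150.0 + 1e-9, 1.0 / 6.0)


@dataclass
class PanelDesign:
    """Design of a synthetic ThT kinetic panel.

    Defaults mirror the aggregation assay: 75 μM protein, protein:POM
    molar ratios 1:0 through 1:10, 150 h sampled every 10 min, three
    replicates per condition, 2% multiplicative Gaussian noise.
    """

    protein_conc: float = 75.0  # μM
    ratios: tuple[float, ...] = _DEFAULT_RATIOS  # POM:protein molar ratios
    time_grid: NDArray[np.float64] = field(default_factory=_default_time_grid)  # h
    noise_fraction: float = 0.02  # multiplicative Gaussian sd
    n_replicates: int = 3
    baseline: float = 0.02  # a.u.
    pom_id: str = "TiNb9"
    seed: int = 0

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be nonnegative")
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be nonnegative")
        if self.protein_conc <= 0:
            raise ValueError("protein concentration must be positive")


def gen_kinetic_panel(
    design: PanelDesign,
    rate_model: RateConcParams = DEFAULT_RATE_MODEL,
    plateau_model: RateConcParams = DEFAULT_PLATEAU_MODEL,
) -> list[KineticTrace]:
    """Generate a full ThT kinetic panel over a POM dose series.

    For each molar ratio the POM concentration is ratio × protein
    concentration; the apparent rate k(c) and the plateau amplitude
    A(c) both follow exponential dose-response models.  Each replicate
    is baseline + A(c)·p(t; k(c)) with multiplicative Gaussian noise.
    """
    rng = np.random.default_rng(design.seed)
    t = design.time_grid
    traces: list[KineticTrace] = []
    for ratio in design.ratios:
        c = ratio * design.protein_conc
        k = float(rate_vs_conc(c, rate_model))
        amplitude = float(rate_vs_conc(c, plateau_model))
        clean = design.baseline + amplitude * isodesmic_extent(t, k)
        for rep in range(design.n_replicates):
            noisy = clean * (1.0 + design.noise_fraction * rng.standard_normal(t.size))
            traces.append(
                KineticTrace(
                    times=t.copy(),
                    signal=noisy,
                    protein_conc=design.protein_conc,
                    pom_id=design.pom_id if ratio > 0 else "none",
                    pom_conc=c,
                    replicate=rep,
                )
            )
    return traces


def gen_titration_curve(
    Kd: float,
    S0: float,
    Sinf: float,
    conc_grid: NDArray[np.float64],
    noise_fraction: float = 0.02,
    seed: int = 0,
    probe: str = "intrinsic-Trp",
) -> TitrationCurve:
    """Generate a one-site titration curve with multiplicative noise."""
    conc = np.asarray(conc_grid, dtype=float)
    rng = np.random.default_rng(seed)
    clean = titration_signal(conc, BindingParams(Kd=Kd, S0=S0, Sinf=Sinf))
    signal = clean * (1.0 + noise_fraction * rng.standard_normal(conc.size))
    return TitrationCurve(conc=conc, signal=signal, probe=probe)


def gen_quenching_curve(
    Ksv: float,
    r: float,
    Q_grid: NDArray[np.float64],
    F0: float = 100.0,
    noise_fraction: float = 0.01,
    seed: int = 0,
) -> QuenchCurve:
    """Generate an acrylamide quenching curve from the sphere-of-action model.

    ``r`` is the action radius in Å; the fluorescence is
    F = F0 / [(1 + Ksv·Q)·exp(V(r)·Q)] with multiplicative noise.  The
    grid must include Q = 0 so the fitter can form F0/F ratios.
    """
    Q = np.asarray(Q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    qp = QuenchParams(Ksv=Ksv, V=float(radius_to_action_volume(r)))
    clean = F0 / sphere_of_action_ratio(Q, qp)
    F = clean * (1.0 + noise_fraction * rng.standard_normal(Q.size))
    return QuenchCurve(Q=Q, F=F)


def gen_spectrum(
    peaks: list[tuple[float, float, float]],
    grid: NDArray[np.float64],
    noise_sd: float = 0.0,
    n_repeats: int = 0,
    seed: int = 0,
) -> Spectrum:
    """Generate a sum-of-Gaussians spectrum, optionally with repeat scans.

    ``peaks`` is a list of (centre nm, width nm, amplitude) bands;
    ``noise_sd`` is the absolute per-point Gaussian noise of each scan.
    With ``n_repeats`` ≥ 1 the returned spectrum carries the individual
    noisy scans and its working values are their mean.
    """
    wl = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    clean = np.zeros_like(wl)
    for centre, width, amplitude in peaks:
        clean += amplitude * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    if n_repeats >= 1:
        reps = clean + noise_sd * rng.standard_normal((n_repeats, wl.size))
        return Spectrum.from_repeats(wl, reps)
    values = clean + noise_sd * rng.standard_normal(wl.size)
    return Spectrum(wl, values)


def _lognormal_sigma_for_mad_ratio(ratio: float) -> float:
    """Shape parameter σ such that MAD/median of a log-normal equals ``ratio``.

    For h = exp(μ + σZ) the median is exp(μ) and
    MAD/median = m(σ) = median(|e^{σZ} − 1|); m is strictly increasing,
    so σ is found by bisection, with m(σ) itself solved from
    Φ(ln(1+x)/σ) − Φ(ln(1−x)/σ) = 1/2.
    """

    def mad_ratio(sigma: float) -> float:
        def cdf_half(x: float) -> float:
            upper = norm.cdf(np.log1p(x) / sigma)
            lower = norm.cdf(np.log1p(-x) / sigma) if x < 1.0 else 0.0
            return upper - lower - 0.5

        return brentq(cdf_half, 1e-12, 1e6)

    return brentq(lambda s: mad_ratio(s) - ratio, 1e-6, 10.0)


def gen_heights(
    median: float, spread: float, n: int, seed: int = 0, condition: str = ""
) -> "HeightSample":
    """Draw AFM-like fibril heights from a log-normal distribution.

    Parameterized so that, as n → ∞, the sample median converges to
    ``median`` (nm) and the median absolute deviation to ``spread``
    (nm).  All draws are positive by construction.
    """
    from .afm_stats import HeightSample

    if median <= 0 or spread <= 0:
        raise ValueError("median and spread must be positive")
    sigma = _lognormal_sigma_for_mad_ratio(spread / median)
    rng = np.random.default_rng(seed)
    heights = median * np.exp(sigma * rng.standard_normal(n))
    return HeightSample(heights=heights, condition=condition)
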