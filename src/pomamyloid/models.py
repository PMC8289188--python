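"""Closed-form models for POM inhibition of S100A9 amyloid formation.

All downstream fitting, simulation and pipeline code evaluates the
closed forms defined here:

* isodesmic (step-growth) polymerization extent of reaction, in its
  irreversible and reversible variants — the lag-free hyperbolic
  kinetics that ThT traces of S100A9 follow;
* exponential decay of the apparent polymerization rate with inhibitor
  concentration;
* one-site ligand binding (Langmuir isotherm, with an optional
  depletion-corrected variant) mapped onto a fluorescence titration
  signal;
* sphere-of-action (static + dynamic) fluorescence quenching and the
  conversion between the action volume and an equivalent radius.

Units are fixed package-wide: time in hours, protein and POM
concentrations in μM, quencher concentration in M, wavelengths and
heights in nm, sphere radii in Å. Conversions happen only at I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import constants

__all__ = [
    "IsodesmicParams",
    "RateConcParams",
    "BindingParams",
    "QuenchParams",
    "isodesmic_extent",
    "isodesmic_extent_reversible",
    "rate_vs_conc",
    "binding_fraction",
    "binding_fraction_depletion",
    "titration_signal",
    "sphere_of_action_ratio",
    "action_volume_to_radius",
    "radius_to_action_volume",
]

# litres per cubic nanometre: 1 nm^3 = 1e-27 m^3 = 1e-24 L
_L_PER_NM3 = 1e-24
# ångström to nanometre
_NM_PER_A = 0.1


class DomainError(ValueError):
    """An argument lies outside the physical domain of a model."""


def _asarray_nonneg(x: ArrayLike, name: str) -> NDArray[np.float64]:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise DomainError(f"{name} must be nonnegative")
    return arr


@dataclass(frozen=True)
class IsodesmicParams:
    """Reversible isodesmic polymerization parameters.

    k_f : forward step rate (μM⁻¹·h⁻¹); k_b : backward step rate (h⁻¹);
    c0 : total monomer concentration (μM).
    """

    k_f: float
    k_b: float
    c0: float

    def __post_init__(self) -> None:
        if self.k_f < 0 or self.k_b < 0:
            raise DomainError("rate constants must be nonnegative")
        if self.c0 <= 0:
            raise DomainError("monomer concentration must be positive")


@dataclass(frozen=True)
class RateConcParams:
    """Exponential dose-response of the apparent rate: k(c) = α·e^(−βc) + γ.

    alpha : rate amplitude (h⁻¹); beta : susceptibility to inhibitor
    concentration (μM⁻¹); gamma : residual rate at saturating inhibitor
    (h⁻¹).  For an inhibitor beta ≥ 0 and alpha + gamma ≥ 0 (the rate at
    zero inhibitor).
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.alpha + self.gamma < 0:
            raise DomainError("rate at zero inhibitor (alpha + gamma) must be nonnegative")


@dataclass(frozen=True)
class BindingParams:
    """One-site binding isotherm parameters.

    Kd : dissociation constant (μM); S0 : signal at zero ligand (a.u.);
    Sinf : signal at saturation (a.u.).  Decreasing titrations
    (Sinf < S0), as observed for Trp and ANS fluorescence on POM
    binding, and increasing ones are both valid.
    """

    Kd: float
    S0: float
    Sinf: float

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise DomainError("Kd must be positive")


@dataclass(frozen=True)
class QuenchParams:
    """Sphere-of-action quenching parameters.

    Ksv : Stern–Volmer constant (M⁻¹); V : sphere-of-action volume
    (M⁻¹).  The equivalent radius r (Å) is a deterministic function of V
    (see :func:`action_volume_to_radius`).
    """

    Ksv: float
    V: float

    def __post_init__(self) -> None:
        if self.Ksv < 0 or self.V < 0:
            raise DomainError("Ksv and V must be nonnegative")

    @property
    def r(self) -> float:
        """Sphere-of-action radius in Å derived from the volume."""
        return action_volume_to_radius(self.V)


def isodesmic_extent(t: ArrayLike, k: float) -> NDArray[np.float64]:
    """Extent of reaction for irreversible isodesmic polymerization.

    p(t) = k·t / (1 + k·t), the solution of dp/dt = k·(1 − p)² with
    p(0) = 0.  This is the hyperbolic, lag-free growth law used to fit
    ThT kinetic traces; ``k`` is the apparent polymerization rate
    constant in h⁻¹ (the forward step rate with the monomer
    concentration absorbed).
    """
    t = _asarray_nonneg(t, "t")
    if k < 0:
        raise DomainError("k must be nonnegative")
    kt = k * t
    return kt / (1.0 + kt)


def isodesmic_extent_reversible(t: ArrayLike, params: IsodesmicParams) -> NDArray[np.float64]:
    """Extent of reaction for reversible isodesmic polymerization.

    Solves dp/dt = k_f·c0·(1 − p)² − k_b·p with p(0) = 0.  Writing
    a = k_f·c0 and b = k_b, the right-hand side factors as
    a·(p − p₁)(p − p₂) with roots

        p₁,₂ = (2a + b ∓ sqrt(b² + 4ab)) / (2a),   p₁ < 1 < p₂,

    giving the closed form

        p(t) = p₁·(1 − e^(−λt)) / (1 − (p₁/p₂)·e^(−λt)),
        λ = sqrt(b·(b + 4a)).

    p rises monotonically from 0 to the equilibrium extent p₁ < 1.
    When the backward rate is negligible (b → 0) this reduces to
    :func:`isodesmic_extent` with k = k_f·c0.
    """
    t = _asarray_nonneg(t, "t")
    a = params.k_f * params.c0
    b = params.k_b
    if b == 0.0:
        return isodesmic_extent(t, a)
    if a == 0.0:
        return np.zeros_like(t)
    disc = np.sqrt(b * b + 4.0 * a * b)
    p1 = (2.0 * a + b - disc) / (2.0 * a)
    p2 = (2.0 * a + b + disc) / (2.0 * a)
    lam = a * (p2 - p1)  # == sqrt(b(b+4a))
    e = np.exp(-lam * t)
    return p1 * (1.0 - e) / (1.0 - (p1 / p2) * e)


def rate_vs_conc(
    c: ArrayLike,
    params: RateConcParams,
    parameterization: str = "rate",
) -> NDArray[np.float64]:
    """Apparent polymerization rate as a function of inhibitor concentration.

    Default ("rate") parameterization: k(c) = α·e^(−β·c) + γ with β in
    μM⁻¹.  The alternative "scale" parameterization reads β as a decay
    scale in μM, k(c) = α·e^(−c/β) + γ.  Decreasing in c whenever
    α > 0 and β > 0.
    """
    c = _asarray_nonneg(c, "c")
    if parameterization == "rate":
        decay = params.beta * c
    elif parameterization == "scale":
        if params.beta <= 0:
            raise DomainError("scale parameterization requires beta > 0")
        decay = c / params.beta
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    return params.alpha * np.exp(-decay) + params.gamma


def binding_fraction(c: ArrayLike, Kd: float) -> NDArray[np.float64]:
    """Fraction of the ligand–protein complex, θ(c) = c / (Kd + c).

    One-site Langmuir isotherm in the free-ligand approximation
    (titrated ligand in excess of binding sites).  θ(0) = 0,
    θ(Kd) = 1/2, θ → 1 at saturation.
    """
    c = _asarray_nonneg(c, "c")
    if Kd <= 0:
        raise DomainError("Kd must be positive")
    return c / (Kd + c)


def binding_fraction_depletion(
    c_total: ArrayLike, Kd: float, protein_conc: float
) -> NDArray[np.float64]:
    """Bound-site fraction treating ``c_total`` as TOTAL ligand.

    Exact one-site solution accounting for ligand depletion by the
    protein (total concentration ``protein_conc`` μM of binding sites):

        θ = (P + c + Kd − sqrt((P + c + Kd)² − 4·P·c)) / (2·P).

    Relevant when Kd is comparable to the protein concentration, as for
    POM titrations of 4 μM S100A9 with Kd of a few μM.
    """
    c = _asarray_nonneg(c_total, "c_total")
    if Kd <= 0:
        raise DomainError("Kd must be positive")
    if protein_conc <= 0:
        raise DomainError("protein_conc must be positive")
    s = protein_conc + c + Kd
    disc = np.sqrt(s * s - 4.0 * protein_conc * c)
    # bound = (s - disc)/2 suffers cancellation at small protein_conc;
    # the equivalent 2Pc/(s + disc) is stable, and theta = bound/P
    return 2.0 * c / (s + disc)


def titration_signal(
    c: ArrayLike,
    params: BindingParams,
    depletion: bool = False,
    protein_conc: float | None = None,
) -> NDArray[np.float64]:
    """Fluorescence signal along a titration: S(c) = S0 + (Sinf − S0)·θ(c).

    With ``depletion=True`` the bound fraction is computed by
    :func:`binding_fraction_depletion` using ``protein_conc`` (μM).
    """
    if depletion:
        if protein_conc is None:
            raise ValueError("protein_conc is required when depletion=True")
        theta = binding_fraction_depletion(c, params.Kd, protein_conc)
    else:
        theta = binding_fraction(c, params.Kd)
    return params.S0 + (params.Sinf - params.S0) * theta


def sphere_of_action_ratio(Q: ArrayLike, params: QuenchParams) -> NDArray[np.float64]:
    """Stern–Volmer ratio F0/F under the sphere-of-action model.

    F0/F = (1 + Ksv·Q)·exp(V·Q): collisional (dynamic) quenching with
    constant Ksv, multiplied by the static term exp(V·Q) for quenchers
    already inside the action volume V at the moment of excitation.
    Reduces to the linear Stern–Volmer law when V = 0; upward-curving
    (convex) in Q when V > 0.
    """
    Q = _asarray_nonneg(Q, "Q")
    return (1.0 + params.Ksv * Q) * np.exp(params.V * Q)


def radius_to_action_volume(r: float | ArrayLike) -> float | NDArray[np.float64]:
    """Convert a sphere-of-action radius (Å) to an action volume (M⁻¹).

    Litre-based convention: V [M⁻¹] = N_A · (4/3)π·r³ [L] with r
    converted Å → nm and 1 nm³ = 1e−24 L.  A 7.7 Å radius gives
    V ≈ 1.15 M⁻¹, the magnitude matching Trp-acrylamide quenching.
    """
    r = _asarray_nonneg(r, "r")
    r_nm = r * _NM_PER_A
    v_litre = (4.0 / 3.0) * np.pi * r_nm**3 * _L_PER_NM3
    out = constants.Avogadro * v_litre
    return float(out) if np.ndim(out) == 0 else out


def action_volume_to_radius(V: float | ArrayLike) -> float | NDArray[np.float64]:
    """Convert an action volume (M⁻¹) to the equivalent sphere radius (Å).

    Exact inverse of :func:`radius_to_action_volume`.
    """
    V = _asarray_nonneg(V, "V")
    v_nm3 = V / (constants.Avogadro * _L_PER_NM3)
    r_nm = (3.0 * v_nm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    out = r_nm / _NM_PER_A
    return float(out) if np.ndim(out) == 0 else out
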