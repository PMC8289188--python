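# Methods

## Kinetic model

ThT-monitored S100A9 aggregation is treated as isodesmic (equal-rate
step-growth) polymerization: every association step shares one forward
rate and one backward rate, which produces hyperbolic, lag-free growth
— no nucleation term, no secondary processes. The package implements
both the reversible closed form and the irreversible limit.

For dp/dt = a(1−p)² − b·p with a = k_f·c₀ and b = k_b, the right-hand
side factors through the roots p₁ < 1 < p₂ of a·p² − (2a+b)·p + a, and
integrating from p(0) = 0 gives

    p(t) = p₁ (1 − e^(−λt)) / (1 − (p₁/p₂) e^(−λt)),  λ = a(p₂−p₁) = √(b(b+4a)).

p rises monotonically to the equilibrium extent p₁ < 1. The b = 0
limit is p(t) = at/(1+at); the implementation switches to it exactly
at b = 0 (λ → 0 makes the general expression 0/0 there). Both forms
are validated against direct numerical integration of the ODE
(`solve_ivp`, LSODA, rtol 1e−10) to 1e−5 over 0–150 h for randomized
parameter draws.

Traces are fitted as baseline + amplitude·p(t; k) with k absorbing the
monomer concentration; depolymerization is assumed negligible over the
assay, so the single apparent rate k is the quantity compared across
inhibitor doses.

### Dose-response parameterization

Rates versus POM concentration follow k(c) = α·e^(−βc) + γ. Two
readings of the decay parameter are supported — β as a rate (μM⁻¹,
default) or as a scale (μM, `parameterization="scale"`); they are
reciprocal reparameterizations with identical fits, and the default is
the one in which "susceptibility" grows with inhibitory potency. α and
γ are bounded at 0 (γ is the residual rate at saturating inhibitor);
data whose rates do not decrease drive β (or α) to the zero bound, and
the fit flags this as `beta_pinned` rather than failing, since a
constant model is the correct limiting description.

## Binding isotherm

The default θ(c) = c/(K_d + c) treats the titrated POM concentration
as free ligand. Because the titrations use 4 μM protein while K_d is
0.45–2.9 μM, ligand depletion is not strictly negligible; the exact
one-site solution treating c as total ligand,
θ = 2c/(P + c + K_d + √((P+c+K_d)² − 4Pc)) (written in its
cancellation-free form), is available via `depletion=True`. The
default remains the Langmuir form, which is the convention under which
the reported constants were obtained; switching to the depletion
variant systematically raises fitted K_d by roughly the protein
concentration scale and should be reported as such.

Unidentifiability: a fitted signal change |S₀ − S∞| below three
residual standard deviations flags the curve as uninformative about
K_d instead of reporting a meaningless constant.

## Sphere-of-action quenching

F₀/F = (1 + K_SV·Q)·e^(V·Q). F₀ is the measured Q = 0 fluorescence,
not a fitted parameter, matching how Stern–Volmer plots are drawn. The
volume-to-radius convention is litre-based:
V [M⁻¹] = N_A · (4/3)πr³ · 1e−24 with r in nm (so 7.7 Å ↔ 1.15 M⁻¹).
This convention reproduces radii of the observed 7–9 Å magnitude from
K_SV-scale action volumes; it is isolated in one function pair
(`radius_to_action_volume` / `action_volume_to_radius`) so an
alternative convention can be swapped in one place. During fitting V
is capped at 100 M⁻¹ (a ~34 Å radius, far beyond any indole
environment) purely to keep e^(V·Q) finite while the optimizer
explores.

## Weighted spectral difference

WSD(ref, test) = √(n⁻¹ Σ wᵢ (refᵢ − testᵢ)²) with
wᵢ = |refᵢ| / mean|ref|. The weights average to 1, WSD is zero iff
the spectra coincide, scales linearly in the difference at fixed
reference, and is deliberately asymmetric (weights from the reference
only). The weighting is isolated in one private function so a
different weight definition can be substituted without touching
callers. Uncertainty: the point estimate uses repeat-mean spectra; the
SD is taken over all reference-repeat × test-repeat pairings (25 for
five repeats each side), which treats scan-to-scan noise as the only
error source.

Peak positions use the first-derivative method: Savitzky–Golay
smoothing (default window 9 points, order 2, both configurable), then
the positive-to-negative zero crossing of the derivative, refined by
linear interpolation between the bracketing grid points. Monotone
spectra raise a no-peak error.

## AFM height statistics

Median, median deviation (unscaled median absolute deviation from the
median — a descriptive spread, deliberately without the 1.4826
Gaussian consistency factor) and n. Condition comparisons use a
two-sided permutation test on the median difference,
p = (1 + #{|perm| ≥ |obs|})/(n_perm + 1), with a seeded percentile
bootstrap CI. The permutation p-value is exactly valid but becomes
conservative for very small samples (≲15 per group), where the median
of a pooled shuffle takes few distinct values; null-uniformity holds
well from ~30 measurements per condition upward.

## Synthetic data: what it emulates and what it does not

Generators are deterministic functions of (parameters, seed) and
reproduce the phenomenology the analysis relies on: lag-free concave
ThT growth whose rate and plateau both decay with dose, decreasing
low-μM titrations, convex Stern–Volmer curves, Gaussian-band spectra
with repeat scans, and positive unimodal height distributions
(log-normal, parameterized so sample median → median and MAD → spread;
the shape parameter is solved by bisection from the MAD/median ratio).

Defaults are the study conditions: 75 μM protein; POM:protein molar
ratios 0, 0.5, 1, 2, 4, 8, 10; 150 h sampled every 10 min; three
replicates; 2% multiplicative Gaussian noise (plate-reader-like; 1%
for fluorometer quenching curves). Values the design leaves open were
fixed once at realistic magnitudes: rate model α = 0.2 h⁻¹,
β = 0.005 μM⁻¹, γ = 0.01 h⁻¹ (reference half-time ~5 h; ~7% of the
reference rate left at the 1:10 dose) and plateau model α = 0.9,
β = 0.003 μM⁻¹, γ = 0.1 on the normalized scale, with baseline 0.02.
The plateau suppression reuses the same exponential family as the rate
— a modelling convenience, not an observed functional form.

Not emulated: baseline drift and well-to-well gain variation,
heteroscedastic detector noise, ThT binding nonlinearity, aggregation
intermediates, optical artifacts in CD, or tip-convolution bias in AFM
heights. Passing recovery tests therefore demonstrates estimator
correctness and precision under the assumed noise model, not
robustness to instrument systematics.

## Fitting conventions

Data-driven starts (k from the half-plateau time, K_d from the
half-signal concentration, K_SV from the initial Stern–Volmer slope,
V from ~0); five log-spaced multi-start perturbations; cost tolerance
1e−10, ≤2000 evaluations per start; physical nonnegativity bounds
throughout; standard errors from the converged fit covariance, with an
optional seeded residual bootstrap for K_d. Replicates are fitted
separately and summarized as mean ± SD per condition (a pooled fit is
possible by concatenation but separate fits expose replicate scatter,
which is the error the study design actually measures).

## Problem sizes

Recovery studies use 100 seeded replicates of ≤25-point curves;
kinetic end-to-end checks use 21-trace panels of ≤900 points;
permutation tests in the test-suite use 199–999 shuffles. These sizes
give medians stable to ~1–2%, comfortably inside the 10% acceptance
bands used for stochastic recoveries.

## Known limitations

* The isodesmic description ignores the nucleation dependence of the
  underlying self-assembly; it is adequate precisely because these
  kinetics show no significant lag phase.
* The exponential dose-response is an empirical summary, not a binding
  mechanism; α, β, γ should not be over-interpreted.
* WSD weighting follows the reference-magnitude convention described
  above; other weightings exist and would change absolute WSD values
  (not the zero/homogeneity properties).
* The Langmuir default slightly underestimates K_d when protein
  concentration ≳ K_d; use the depletion flag for such designs.
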