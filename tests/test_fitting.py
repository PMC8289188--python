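"""Fitters: noiseless round trips, noisy recovery, degenerate inputs."""

import numpy as np
import pytest
from dataclasses import replace

from pomamyloid.fitting import (
    ConfigurationError,
    FitFailureError,
    InputError,
    KineticTrace,
    QuenchCurve,
    TitrationCurve,
    fit_kinetic_trace,
    fit_quenching,
    fit_rate_concentration,
    fit_titration,
    normalize_panel,
)
from pomamyloid.models import (
    BindingParams,
    QuenchParams,
    RateConcParams,
    isodesmic_extent,
    radius_to_action_volume,
    rate_vs_conc,
    sphere_of_action_ratio,
    titration_signal,
)
from pomamyloid.synthetic_data import gen_titration_curve

PAPER_CONCS = np.array([0.0, 37.5, 75.0, 150.0, 300.0, 600.0, 750.0])  # 1:0 .. 1:10 of 75 uM


def make_trace(k=0.05, amplitude=1.0, baseline=0.02, n=90, t_max=150.0, **meta):
    t = np.linspace(0, t_max, n)
    return KineticTrace(times=t, signal=baseline + amplitude * isodesmic_extent(t, k), **meta)


class TestKineticFit:
    def test_noiseless_round_trip(self):
        fit = fit_kinetic_trace(make_trace(k=0.05, amplitude=1.0, baseline=0.02))
        assert fit.k == pytest.approx(0.05, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)
        assert fit.baseline == pytest.approx(0.02, abs=1e-6)
        assert fit.rss < 1e-12

    def test_noisy_median_recovery(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 150, 90)
        clean = 0.02 + 1.0 * isodesmic_extent(t, 0.1)
        ks = []
        for _ in range(100):
            noisy = clean * (1 + 0.02 * rng.standard_normal(t.size))
            ks.append(fit_kinetic_trace(KineticTrace(times=t, signal=noisy)).k)
        assert np.median(ks) == pytest.approx(0.1, rel=0.05)

    def test_constant_signal_fails(self):
        t = np.linspace(0, 150, 50)
        with pytest.raises(FitFailureError):
            fit_kinetic_trace(KineticTrace(times=t, signal=np.full(50, 3.0)))

    def test_decreasing_signal_fails(self):
        t = np.linspace(0, 150, 50)
        with pytest.raises(FitFailureError):
            fit_kinetic_trace(KineticTrace(times=t, signal=np.exp(-t / 30.0)))

    def test_too_few_points(self):
        with pytest.raises(InputError):
            fit_kinetic_trace(make_trace(n=5))

    def test_fitted_rate_invariant_under_signal_rescaling(self):
        trace = make_trace(k=0.08, amplitude=0.7, baseline=0.01)
        k_ref = fit_kinetic_trace(trace).k
        for scale in (1e-3, 0.4, 250.0):
            scaled = replace(trace, signal=trace.signal * scale)
            assert fit_kinetic_trace(scaled).k == pytest.approx(k_ref, abs=1e-8)


class TestNormalizePanel:
    def make_panel(self):
        ref = [make_trace(amplitude=900.0, baseline=0.0, pom_id="none", pom_conc=0.0, replicate=r)
               for r in range(2)]
        treated = make_trace(amplitude=400.0, baseline=0.0, pom_id="TiNb9", pom_conc=75.0)
        return ref + [treated]

    def test_reference_maximum_maps_to_one(self):
        out = normalize_panel(self.make_panel())
        ref_max = np.mean([np.max(tr.signal) for tr in out[:2]])
        assert ref_max == pytest.approx(1.0)

    def test_treated_plateau_scales_linearly(self):
        panel = self.make_panel()
        raw_ratio = np.max(panel[2].signal) / np.mean([np.max(t.signal) for t in panel[:2]])
        out = normalize_panel(panel)
        assert np.max(out[2].signal) == pytest.approx(raw_ratio)

    def test_idempotent(self):
        once = normalize_panel(self.make_panel())
        twice = normalize_panel(once)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.signal, b.signal, rtol=1e-12)

    def test_missing_reference_raises(self):
        treated = [make_trace(pom_id="TiNb9", pom_conc=75.0)]
        with pytest.raises(ConfigurationError):
            normalize_panel(treated, "none")


class TestRateConcentrationFit:
    def test_noiseless_round_trip_at_assay_concentrations(self):
        truth = RateConcParams(alpha=0.2, beta=0.05, gamma=0.01)
        pts = [(c, float(rate_vs_conc(c, truth))) for c in PAPER_CONCS]
        fit = fit_rate_concentration(pts)
        assert fit.params.alpha == pytest.approx(0.2, rel=1e-6)
        assert fit.params.beta == pytest.approx(0.05, rel=1e-6)
        assert fit.params.gamma == pytest.approx(0.01, rel=1e-6)
        assert not fit.beta_pinned

    def test_scale_parameterization_round_trip(self):
        truth = RateConcParams(alpha=0.2, beta=20.0, gamma=0.01)
        pts = [(c, float(rate_vs_conc(c, truth, "scale"))) for c in PAPER_CONCS]
        fit = fit_rate_concentration(pts, parameterization="scale")
        assert fit.params.beta == pytest.approx(20.0, rel=1e-5)

    def test_concentration_independent_rates(self):
        pts = [(c, 0.15) for c in PAPER_CONCS]
        fit = fit_rate_concentration(pts)
        assert fit.params.alpha + fit.params.gamma == pytest.approx(0.15, rel=1e-4)

    def test_increasing_rates_pin_beta_at_zero(self):
        pts = [(c, 0.05 + 1e-4 * c) for c in PAPER_CONCS]
        fit = fit_rate_concentration(pts)
        assert fit.beta_pinned

    def test_too_few_points(self):
        with pytest.raises(InputError):
            fit_rate_concentration([(0.0, 0.2), (75.0, 0.1), (150.0, 0.05)])

    def test_missing_zero_point(self):
        with pytest.raises(InputError):
            fit_rate_concentration([(10.0, 0.2), (75.0, 0.1), (150.0, 0.05), (300.0, 0.02)])


class TestTitrationFit:
    def test_noiseless_round_trip(self):
        c = np.linspace(0, 25, 25)
        truth = BindingParams(Kd=2.5, S0=100.0, Sinf=40.0)
        curve = TitrationCurve(conc=c, signal=titration_signal(c, truth))
        fit = fit_titration(curve)
        assert fit.params.Kd == pytest.approx(2.5, rel=1e-6)
        assert fit.params.S0 == pytest.approx(100.0, rel=1e-6)
        assert fit.params.Sinf == pytest.approx(40.0, rel=1e-6)
        assert not fit.unidentifiable

    def test_depletion_round_trip(self):
        c = np.linspace(0, 25, 25)
        truth = BindingParams(Kd=2.5, S0=100.0, Sinf=40.0)
        clean = titration_signal(c, truth, depletion=True, protein_conc=4.0)
        fit = fit_titration(
            TitrationCurve(conc=c, signal=clean), depletion=True, protein_conc=4.0
        )
        assert fit.params.Kd == pytest.approx(2.5, rel=1e-6)

    def test_noisy_median_recovery_of_low_micromolar_kd(self):
        kds = [
            fit_titration(
                gen_titration_curve(2.48, 100.0, 40.0, np.linspace(0, 25, 25), 0.02, seed=s)
            ).params.Kd
            for s in range(100)
        ]
        assert np.median(kds) == pytest.approx(2.48, rel=0.10)

    def test_recovery_sharpens_as_noise_and_grid_improve(self):
        # dispersion of fitted Kd shrinks with noise at both grid densities
        for n_points in (12, 25):
            grid = np.linspace(0, 25, n_points)
            spread = []
            for noise in (0.08, 0.02, 0.005):
                kds = [
                    fit_titration(
                        gen_titration_curve(2.5, 100.0, 40.0, grid, noise, seed=s)
                    ).params.Kd
                    for s in range(30)
                ]
                spread.append(np.median(np.abs(np.array(kds) - 2.5)))
            assert spread[0] > spread[1] > spread[2]

    def test_flat_curve_flagged_unidentifiable(self):
        c = np.linspace(0, 25, 25)
        fit = fit_titration(TitrationCurve(conc=c, signal=np.full(25, 80.0)))
        assert fit.unidentifiable

    def test_bootstrap_uncertainty_is_seeded(self):
        curve = gen_titration_curve(2.5, 100.0, 40.0, np.linspace(0, 25, 25), 0.02, seed=1)
        a = fit_titration(curve, n_bootstrap=50, seed=9).bootstrap_se_Kd
        b = fit_titration(curve, n_bootstrap=50, seed=9).bootstrap_se_Kd
        assert a == b and a > 0

    def test_too_few_concentrations(self):
        with pytest.raises(InputError):
            fit_titration(TitrationCurve(conc=np.arange(4.0), signal=np.ones(4)))


class TestQuenchingFit:
    def test_noiseless_round_trip(self):
        Q = np.linspace(0, 0.5, 11)
        truth = QuenchParams(Ksv=5.24, V=float(radius_to_action_volume(7.7)))
        F = 100.0 / sphere_of_action_ratio(Q, truth)
        fit = fit_quenching(QuenchCurve(Q=Q, F=F))
        assert fit.params.Ksv == pytest.approx(5.24, rel=1e-6)
        assert fit.r == pytest.approx(7.7, rel=1e-6)

    def test_linear_stern_volmer_gives_zero_volume(self):
        Q = np.linspace(0, 0.5, 11)
        F = 100.0 / (1.0 + 5.0 * Q)
        fit = fit_quenching(QuenchCurve(Q=Q, F=F))
        assert fit.params.V == pytest.approx(0.0, abs=1e-6)
        assert fit.params.Ksv == pytest.approx(5.0, rel=1e-6)

    def test_too_few_points(self):
        Q = np.array([0.0, 0.1, 0.2])
        with pytest.raises(InputError):
            fit_quenching(QuenchCurve(Q=Q, F=100.0 / (1 + 5 * Q)))

    def test_missing_zero_quencher_point(self):
        Q = np.linspace(0.05, 0.5, 10)
        with pytest.raises(InputError):
            fit_quenching(QuenchCurve(Q=Q, F=100.0 / (1 + 5 * Q)))

    def test_increasing_fluorescence_fails(self):
        Q = np.linspace(0, 0.5, 11)
        with pytest.raises(FitFailureError):
            fit_quenching(QuenchCurve(Q=Q, F=100.0 * (1 + Q)))
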