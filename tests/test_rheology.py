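"""Sizing, stress reconstruction and viscoelastic least-squares fitting."""

import numpy as np
import pytest

from npsrheo import StrainWave, ZoneSpec
from npsrheo.errors import ConfigError, FitError
from npsrheo.rheology import (
    GPP_DETECTION_LIMIT,
    RheologyParams,
    StressSeries,
    ZoneFit,
    analyze_events,
    assemble_result,
    compute_stress_series,
    fit_rheology,
    results_to_frame,
    size_cell,
)
from npsrheo.signal_pipeline import CellEvent, Pulse
from npsrheo.simulate import SimConfig, generate_trace, stress_to_blockage

from conftest import make_four_zone_geometry, truth_indexed, zone_relative_errors


def _series(sigma_p=10.0, Gp=500.0, Gpp=50.0, eps0=0.15, f=30.0, n=200, phase0=0.0):
    wave = StrainWave(eps_mean=0.4, eps0=eps0, f=f, omega=2 * np.pi * f, phase0=phase0)
    t = np.linspace(0, 3.0 / f, n)
    phi = wave.phase(t)
    sigma = sigma_p + eps0 * (Gp * np.cos(phi) + Gpp * np.sin(phi))
    return StressSeries(
        t=t, sigma=sigma, eps_cos=eps0 * np.cos(phi), eps_sin=eps0 * np.sin(phi), wave=wave
    )


class TestFitRheology:
    def test_exact_recovery_of_synthetic_series(self):
        sigma_p, Gp, Gpp, rms = fit_rheology(_series())
        assert sigma_p == pytest.approx(10.0, abs=1e-9)
        assert Gp == pytest.approx(500.0, rel=1e-9)
        assert Gpp == pytest.approx(50.0, rel=1e-9)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_constant_stress_gives_zero_moduli(self):
        s = _series(sigma_p=42.0, Gp=0.0, Gpp=0.0)
        sigma_p, Gp, Gpp, _ = fit_rheology(s)
        assert sigma_p == pytest.approx(42.0, abs=1e-9)
        assert abs(Gp) < 1e-9 and abs(Gpp) < 1e-9

    def test_pure_quadrature_maps_to_loss_modulus(self):
        s = _series(sigma_p=0.0, Gp=0.0, Gpp=77.0)
        _, Gp, Gpp, _ = fit_rheology(s)
        assert abs(Gp) < 1e-9
        assert Gpp == pytest.approx(77.0, rel=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(10, 50))
            s = _series(
                sigma_p=rng.uniform(0, 50),
                Gp=rng.uniform(10, 1000),
                Gpp=rng.uniform(0, 200),
                f=rng.uniform(10, 120),
                n=n,
            )
            noisy = StressSeries(
                t=s.t, sigma=s.sigma + rng.normal(0, 5.0, n),
                eps_cos=s.eps_cos, eps_sin=s.eps_sin, wave=s.wave,
            )
            X = np.column_stack([np.ones(n), noisy.eps_cos, noisy.eps_sin])
            beta = np.linalg.solve(X.T @ X, X.T @ noisy.sigma)
            sigma_p, Gp, Gpp, _ = fit_rheology(noisy)
            np.testing.assert_allclose([sigma_p, Gp, Gpp], beta, rtol=1e-9)

    def test_rank_deficient_basis_rejected(self):
        wave = StrainWave(eps_mean=0.4, eps0=0.0, f=30.0, omega=2 * np.pi * 30.0)
        t = np.linspace(0, 0.1, 50)
        s = StressSeries(t=t, sigma=np.full(50, 10.0), eps_cos=np.zeros(50),
                         eps_sin=np.zeros(50), wave=wave)
        with pytest.raises(FitError):
            fit_rheology(s)

    def test_subperiod_span_rejected(self):
        s = _series(n=50)
        short = StressSeries(t=s.t[:5] * 0.01, sigma=s.sigma[:5], eps_cos=s.eps_cos[:5],
                             eps_sin=s.eps_sin[:5], wave=s.wave)
        with pytest.raises(FitError):
            fit_rheology(short)


class TestComputeStressSeries:
    ZONE = ZoneSpec(index=0, L_zone=6000.0, L_p=500.0, w0=11.25, a=2.75, w_node=21.0)

    def test_roundtrip_with_forward_model(self):
        # stress -> blockage (forward) -> stress (inverse) is the identity
        D, v, mu_f, P, R0 = 18.4, 15000.0, 0.1, 13800.0, 5e5
        from npsrheo import contraction_width, deformed_diameter, strain_wave
        from npsrheo.simulate import synth_stress

        wave = strain_wave(self.ZONE, D, v)
        t = np.arange(0, self.ZONE.L_zone / v, 1e-4)
        w = contraction_width(self.ZONE, v * t)
        D_d = deformed_diameter(D, w)
        sigma_true = synth_stress(wave, 150.0, 500.0, 50.0, t)
        dR = stress_to_blockage(sigma_true, w, D_d, mu_f, P, R0)
        series = compute_stress_series(t, dR / R0, 0.0, v, self.ZONE, D, mu_f, P)
        np.testing.assert_allclose(series.sigma, sigma_true, rtol=1e-12)
        sigma_p, Gp, Gpp, rms = fit_rheology(series)
        assert (sigma_p, Gp, Gpp) == pytest.approx((150.0, 500.0, 50.0), rel=1e-9)

    def test_friction_coefficient_scaling(self):
        # doubling mu_f halves the reconstructed stress
        t = np.arange(0, 0.1, 1e-4)
        h = np.full_like(t, 0.003)
        s1 = compute_stress_series(t, h, 0.0, 15000.0, self.ZONE, 18.4, 0.1, 13800.0)
        s2 = compute_stress_series(t, h, 0.0, 15000.0, self.ZONE, 18.4, 0.2, 13800.0)
        np.testing.assert_allclose(s2.sigma, s1.sigma / 2.0, rtol=1e-12)

    def test_zero_blockage_gives_zero_stress(self):
        t = np.arange(0, 0.1, 1e-4)
        s = compute_stress_series(t, np.zeros_like(t), 0.0, 15000.0, self.ZONE, 18.4, 0.1, 13800.0)
        np.testing.assert_allclose(s.sigma, 0.0)

    def test_constant_pressure_mode_uses_mean(self):
        t = np.arange(0, 0.1, 1e-4)
        h = 0.003 + 0.001 * np.sin(2 * np.pi * 30 * t)
        s_t = compute_stress_series(t, h, 0.0, 15000.0, self.ZONE, 18.4, 0.1, 13800.0,
                                    pressure_mode="time_resolved")
        s_c = compute_stress_series(t, h, 0.0, 15000.0, self.ZONE, 18.4, 0.1, 13800.0,
                                    pressure_mode="constant")
        assert np.std(s_c.sigma) < np.std(s_t.sigma)


class TestSizing:
    def _event(self, pore_dr):
        pulse = Pulse(start=0, stop=10, t_start=0.0, t_end=1e-3)
        return CellEvent(cell_id=0, pore_pulse=pulse, zone_pulses=[None],
                         pore_dr=pore_dr, zone_samples=[None])

    def test_zero_blockage_sizes_to_zero(self, four_zone_geometry):
        assert size_cell(self._event(0.0), four_zone_geometry.pore) == 0.0

    def test_noiseless_population_sized_exactly(self, noiseless_run):
        truth = truth_indexed(noiseless_run)
        df = noiseless_run["results"]
        true_d = truth["D_cell_um"].to_numpy()[df["cell_id"]]
        np.testing.assert_allclose(df["D_cell_um"], true_d, rtol=1e-3)

    def test_noisy_population_mean_within_one_percent(self, noisy_run):
        truth = truth_indexed(noisy_run)
        df = noisy_run["results"]
        true_mean = truth["D_cell_um"].to_numpy()[df["cell_id"]].mean()
        assert df["D_cell_um"].mean() == pytest.approx(true_mean, rel=0.01)


class TestAssembleResult:
    def _fit(self, Gp=500.0, Gpp=50.0, zone=1):
        eta = Gpp / Gp if Gp > 0 else float("nan")
        return ZoneFit(zone=zone, f_applied=30.0, sigma_p=150.0, Gp=Gp, Gpp=Gpp,
                       eta=eta, residual_rms=0.1, n_samples=1000,
                       negative_modulus=Gp < 0 or Gpp < 0)

    def test_loss_tangent_definition(self):
        res = assemble_result(0, 18.4, [self._fit(500.0, 50.0)])
        assert res.zones[0].eta == pytest.approx(0.1)

    def test_below_detection_threshold_flag(self):
        res = assemble_result(0, 18.4, [self._fit(Gpp=0.05), self._fit(Gpp=5.0, zone=2)])
        assert res.below_detection
        res2 = assemble_result(0, 18.4, [self._fit(Gpp=GPP_DETECTION_LIMIT + 1e-6)])
        assert not res2.below_detection

    def test_negative_modulus_flagged_not_clipped(self):
        res = assemble_result(0, 18.4, [self._fit(Gp=500.0, Gpp=-2.0)])
        assert res.zones[0].Gpp == -2.0
        assert res.zones[0].negative_modulus

    def test_no_valid_zones_rejected(self):
        with pytest.raises(FitError):
            assemble_result(0, 18.4, [None, None])

    def test_failed_zones_stay_missing_in_table(self):
        geo = make_four_zone_geometry()
        res = assemble_result(0, 18.4, [self._fit(), None, None, None])
        frame = results_to_frame([res], geo)
        assert np.isnan(frame.loc[0, "zone2_Gp_Pa"])
        assert frame.loc[0, "zone1_Gp_Pa"] == pytest.approx(500.0)


class TestPopulationRecovery:
    def test_doubling_elastic_modulus_doubles_recovered_median(self):
        """Parameter-recovery sanity: a population generated with twice the
        elastic modulus yields twice the recovered median G'."""
        geo = make_four_zone_geometry(L_zone=2000.0)
        from npsrheo import detect_events

        medians = []
        for gp in (400.0, 800.0):
            cfg = SimConfig(geometry=geo, seed=21, n_cells=8, noise_sd=0.0,
                            gp_median=gp, event_rate_per_hour=3000.0)
            trace, _ = generate_trace(cfg)
            events = detect_events(trace, geo)
            results, _ = analyze_events(events, geo)
            frame = results_to_frame(results, geo)
            medians.append(np.nanmedian(frame["zone1_Gp_Pa"]))
        assert medians[1] / medians[0] == pytest.approx(2.0, rel=0.05)

    def test_unstrained_cell_excluded_from_rheology(self, four_zone_geometry):
        # a cell smaller than w0 + a never contacts both walls: sized but
        # not fitted
        from npsrheo import forward_blockage

        h = forward_blockage(13.0, four_zone_geometry.pore.D_eff,
                             four_zone_geometry.pore.L_pore)
        pulse = Pulse(start=0, stop=10, t_start=0.0, t_end=1e-3)
        ev = CellEvent(cell_id=0, pore_pulse=pulse, zone_pulses=[None] * 4,
                       pore_dr=h, zone_samples=[None] * 4)
        results, excluded = analyze_events([ev], four_zone_geometry)
        assert results == []
        assert excluded == [(0, "unstrained")]

    def test_excluded_plus_fitted_conserves_events(self, four_zone_geometry):
        # a deliberately overlapping pair is excluded as coincident, and
        # every event is accounted for
        cfg = SimConfig(geometry=four_zone_geometry, seed=5, n_cells=3, noise_sd=0.0,
                        event_rate_per_hour=3000.0, arrival_jitter=0.0)
        trace, _ = generate_trace(cfg)
        from npsrheo import detect_events

        events = detect_events(trace, four_zone_geometry)
        results, excluded = analyze_events(events, four_zone_geometry)
        assert len(results) + len(excluded) == len(events)
        assert all(reason == "coincident" for _, reason in excluded)
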