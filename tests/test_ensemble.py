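import numpy as np
import pandas as pd
import pytest

from apeeg.ensemble import (MCConfig, N_CORTICAL_NEURONS, asynchronous_spectrum,
                            chebyshev_required_n, ensemble_bruteforce,
                            ensemble_spectrum, mean_unitary_spectrum,
                            pair_term_monte_carlo, synaptic_ensemble_spectrum,
                            unitary_scalp_energy)
from apeeg.geometry import (CortexGeometry, LeadField, pair_distance_density,
                            place_population)
from apeeg.spectra import Spectrum, TimeSeries, WindowConfig, estimate_psd
from apeeg.synchrony import SynchronyParams
from apeeg.synthetic import (calibrate_kernel_bank, make_kernel_bank,
                             make_population, population_to_specs)
from apeeg.trend import PARALYZED_EEG_TREND, detectability


@pytest.fixture(scope="module")
def calibrated(population):
    """Kernel bank calibrated to the printed class energies (0.09 / 0.02
    pV^2*ms for excitatory / inhibitory) on the surrogate head."""
    specs = population_to_specs(population)
    bank = make_kernel_bank(specs)
    geom = CortexGeometry.sphere(70.0)
    lf = LeadField.infinite_medium([0.0, 0.0, 85.0])
    bank = calibrate_kernel_bank(bank, specs, geom, lf, n_locations=100, seed=0)
    return bank, geom, lf


class TestMeanUnitary:
    def test_abundance_weighted_energy(self, population, calibrated):
        bank, geom, lf = calibrated
        mu = mean_unitary_spectrum(bank, population, geom, lf,
                                   n_locations=100, seed=0)
        assert mu.weighted_energy == pytest.approx(0.85 * 0.09 + 0.15 * 0.02,
                                                   rel=1e-6)
        assert mu.weighted_energy == pytest.approx(0.08, abs=0.005)

    def test_single_class_mean_is_class_spectrum(self, calibrated):
        bank, geom, lf = calibrated
        name = next(iter(bank))
        pop1 = pd.DataFrame([{"name": name, "abundance": 1.0}])
        mu = mean_unitary_spectrum({name: bank[name]}, pop1, geom, lf,
                                   n_locations=50, seed=2)
        assert np.allclose(mu.spectrum.values, mu.per_class[name].values)

    def test_amplitude_doubling_quadruples_spectrum(self, population, calibrated):
        bank, geom, lf = calibrated
        doubled = {k: v.scaled(2.0) for k, v in bank.items()}
        mu1 = mean_unitary_spectrum(bank, population, geom, lf,
                                    n_locations=30, seed=3)
        mu2 = mean_unitary_spectrum(doubled, population, geom, lf,
                                    n_locations=30, seed=3)
        assert np.allclose(mu2.spectrum.values, 4.0 * mu1.spectrum.values)

    def test_spectrum_integral_matches_energy(self, population, calibrated):
        bank, geom, lf = calibrated
        f = np.geomspace(0.5, 4000.0, 600)
        mu = mean_unitary_spectrum(bank, population, geom, lf,
                                   n_locations=50, seed=1, freqs=f)
        assert mu.spectrum.total() == pytest.approx(mu.weighted_energy, rel=0.02)


class TestAsynchronous:
    def test_zero_rate_is_silent(self, population, calibrated, freq_grid):
        bank, geom, lf = calibrated
        mu = mean_unitary_spectrum(bank, population, geom, lf,
                                   n_locations=20, seed=0, freqs=freq_grid)
        s = asynchronous_spectrum(0.0, N_CORTICAL_NEURONS, mu)
        assert np.all(s.values == 0.0)

    def test_linear_in_rate_and_count(self, population, calibrated, freq_grid):
        bank, geom, lf = calibrated
        mu = mean_unitary_spectrum(bank, population, geom, lf,
                                   n_locations=20, seed=0, freqs=freq_grid)
        s1 = asynchronous_spectrum(2.0, 5.0, mu)
        s2 = asynchronous_spectrum(1.0, 1.0, mu)
        assert np.allclose(s1.values, 10.0 * s2.values)

    def test_whole_brain_asynchronous_below_noise_floor(self, population, calibrated):
        """Even the whole cortex firing asynchronously at 1 Hz stays far
        below the EEG amplifier noise floor."""
        bank, geom, lf = calibrated
        mu = mean_unitary_spectrum(bank, population, geom, lf,
                                   n_locations=100, seed=0)
        s = asynchronous_spectrum(1.0, N_CORTICAL_NEURONS, mu)
        peak, flag = detectability(s)
        assert not flag
        assert peak < 1e-6

    def test_matches_simulated_scalp_signal(self, population, kernel_bank,
                                            sphere_fixture):
        """Direct simulation oracle: Poisson trains convolved with scalp
        kernels and summed match lambda * sum 2|g_i|^2 within 5% band-mean."""
        from apeeg.ensemble import scalp_kernel_spectra

        geom, lf = sphere_fixture
        placed = place_population(geom, population, n_neurons=50, seed=9)
        lam, dur_ms, dt = 40.0, 60_000.0, 0.5
        rng = np.random.default_rng(10)
        n = int(dur_ms / dt)
        scalp = np.zeros(n)
        for row in placed.itertuples(index=False):
            k = kernel_bank[row.name]
            nu = lf(np.asarray(row.position))
            gk = nu @ (np.asarray(row.frame) @ k.waveform)  # uV, dt of kernel
            # kernel dt 0.1 ms -> resample to simulation dt
            step = int(round(dt / k.dt))
            gk = gk[::step]
            n_spk = rng.poisson(lam * dur_ms / 1000.0)
            idx = rng.integers(0, n - gk.size, size=n_spk)
            delta = np.zeros(n)
            np.add.at(delta, idx, 1.0)
            scalp += np.convolve(delta, gk)[:n]
        psd = estimate_psd(TimeSeries(dt, scalp), WindowConfig(segment_ms=1000.0))
        g = scalp_kernel_spectra(placed, kernel_bank, lf, psd.freqs[1:])
        theory = lam * 2.0 * np.sum(np.abs(g) ** 2, axis=0)
        band = (psd.freqs[1:] > 30.0) & (psd.freqs[1:] < 300.0)
        ratio = np.mean(psd.values[1:][band]) / np.mean(theory[band])
        assert ratio == pytest.approx(1.0, abs=0.05)


class TestBruteForce:
    def test_uncorrelated_pair_term_vanishes(self, placed_50, kernel_bank,
                                             sphere_fixture, freq_grid):
        _, lf = sphere_fixture
        sp = SynchronyParams(lam=1.0, rmax=0.0)
        auto, pair = ensemble_bruteforce(placed_50, kernel_bank, sp, lf, freq_grid)
        assert np.all(pair.values == 0.0)
        assert np.all(auto.values >= 0.0)

    def test_single_neuron_is_auto_only(self, placed_50, kernel_bank,
                                        sphere_fixture, freq_grid):
        _, lf = sphere_fixture
        sp = SynchronyParams(lam=1.0, rmax=0.2, sigma_t=0.0)
        auto, pair = ensemble_bruteforce(placed_50.iloc[:1], kernel_bank, sp,
                                         lf, freq_grid)
        assert np.all(pair.values == 0.0)
        assert np.any(auto.values > 0.0)

    def test_large_population_redirects_to_mc(self, population, kernel_bank,
                                              sphere_fixture, freq_grid):
        geom, lf = sphere_fixture
        placed = place_population(geom, population, n_neurons=201, seed=0)
        with pytest.raises(ValueError, match="[Mm]onte"):
            ensemble_bruteforce(placed, kernel_bank,
                                SynchronyParams(), lf, freq_grid)

    def test_pair_term_nonnegative_at_dc(self, placed_50, kernel_bank,
                                         sphere_fixture):
        _, lf = sphere_fixture
        f = np.concatenate([[1e-3], np.geomspace(1, 500, 50)])
        sp = SynchronyParams(lam=1.0, rmax=0.2, sigma_t=11.3)
        _, pair = ensemble_bruteforce(placed_50, kernel_bank, sp, lf, f)
        assert pair.values.real[0] >= 0.0


class TestMonteCarlo:
    def test_chebyshev_stopping_arithmetic(self):
        assert chebyshev_required_n(1.0, 0.1, 0.01) == 10_000

    def test_matches_bruteforce_within_bound(self, placed_50, kernel_bank,
                                             sphere_fixture, freq_grid):
        _, lf = sphere_fixture
        sp = SynchronyParams(lam=1.0, rmax=0.2, sigma_t=11.3)
        _, pair = ensemble_bruteforce(placed_50, kernel_bank, sp, lf, freq_grid)
        delta = 0.1 * float(np.max(np.abs(pair.values.real)))
        res = pair_term_monte_carlo(sp, MCConfig(delta_abs=delta, seed=5),
                                    freq_grid, placed=placed_50,
                                    bank=kernel_bank, leadfield=lf)
        assert res.converged
        err = np.max(np.abs(res.spectrum.values.real - pair.values.real))
        assert err <= delta

    def test_estimator_unbiased(self, placed_50, kernel_bank, sphere_fixture,
                                freq_grid):
        """Mean of many short (fixed-draw) runs agrees with the exact sum
        within 2 standard errors at the peak frequency."""
        _, lf = sphere_fixture
        sp = SynchronyParams(lam=1.0, rmax=0.2, sigma_t=11.3)
        _, pair = ensemble_bruteforce(placed_50, kernel_bank, sp, lf, freq_grid)
        i_peak = int(np.argmax(np.abs(pair.values.real)))
        runs = []
        for seed in range(100):
            res = pair_term_monte_carlo(
                sp, MCConfig(delta_abs=1.0, batch_size=500, max_draws=500,
                             seed=seed),
                freq_grid, placed=placed_50, bank=kernel_bank, leadfield=lf)
            runs.append(res.spectrum.values.real[i_peak])
        runs = np.array(runs)
        se = runs.std(ddof=1) / np.sqrt(len(runs))
        assert abs(runs.mean() - pair.values.real[i_peak]) < 2.0 * se

    def test_vanishing_spatial_scale_kills_pair_term(self, placed_50,
                                                     kernel_bank,
                                                     sphere_fixture, freq_grid):
        _, lf = sphere_fixture
        sp = SynchronyParams(lam=1.0, rmax=0.2, sigma_t=11.3, sigma_x=1e-6)
        res = pair_term_monte_carlo(sp, MCConfig(delta_abs=1e-30, max_draws=1000,
                                                 batch_size=500, seed=0),
                                    freq_grid, placed=placed_50,
                                    bank=kernel_bank, leadfield=lf)
        assert np.allclose(res.spectrum.values.real, 0.0)

    def test_nonconverged_run_is_flagged(self, placed_50, kernel_bank,
                                         sphere_fixture, freq_grid):
        _, lf = sphere_fixture
        sp = SynchronyParams(lam=1.0, rmax=0.2, sigma_t=11.3)
        res = pair_term_monte_carlo(sp, MCConfig(delta_abs=1e-30, max_draws=2000,
                                                 batch_size=1000, seed=0),
                                    freq_grid, placed=placed_50,
                                    bank=kernel_bank, leadfield=lf)
        assert not res.converged

    def test_continuum_mode_runs_and_scales(self, population, kernel_bank,
                                            freq_grid):
        """Continuum sampling (location + dN displacement) produces a pair
        spectrum of the same sign and order as the placed-population sum."""
        geom = CortexGeometry.sphere(10.0, subdivisions=3)
        lf = LeadField.infinite_medium([0.0, 0.0, 20.0])
        radii = np.arange(0.0, 21.0, 1.0)
        dn = pair_distance_density(geom, radii, n_centers=20, seed=0)
        sp = SynchronyParams(lam=1.0, rmax=0.2, sigma_t=11.3)
        res = pair_term_monte_carlo(sp, MCConfig(delta_abs=1.0, batch_size=400,
                                                 max_draws=400, seed=1),
                                    freq_grid, population=population,
                                    geometry=geom, pair_density=dn,
                                    bank=kernel_bank, leadfield=lf)
        assert res.n_draws == 400
        assert np.any(res.spectrum.values.real != 0.0)


class TestEnsembleSpectrum:
    def test_zero_pair_term_reduces_to_auto(self, freq_grid):
        auto = Spectrum(freq_grid, np.ones_like(freq_grid))
        pair = Spectrum(freq_grid, np.zeros_like(freq_grid), kind="cross")
        total = ensemble_spectrum(auto, pair)
        assert np.allclose(total.values, auto.values)

    def test_grid_mismatch_error(self, freq_grid):
        auto = Spectrum(freq_grid, np.ones_like(freq_grid))
        pair = Spectrum(freq_grid * 2.0, np.zeros_like(freq_grid), kind="cross")
        with pytest.raises(ValueError, match="grid"):
            ensemble_spectrum(auto, pair)

    def test_infinite_jitter_equals_asynchronous(self, placed_50, kernel_bank,
                                                 sphere_fixture, freq_grid):
        _, lf = sphere_fixture
        base = dict(lam=1.0, rmax=0.2)
        a_inf, p_inf = ensemble_bruteforce(
            placed_50, kernel_bank, SynchronyParams(sigma_t=1e9, **base),
            lf, freq_grid)
        a_async, p_async = ensemble_bruteforce(
            placed_50, kernel_bank, SynchronyParams(rmax=0.0, lam=1.0),
            lf, freq_grid)
        assert np.allclose(p_inf.values, 0.0)
        assert np.allclose(a_inf.values, a_async.values)

    def test_jitter_cutoff_frequency(self, placed_50, kernel_bank,
                                     sphere_fixture, freq_grid):
        """Finite jitter tracks the zero-jitter pair spectrum at low f and
        falls away above a cutoff that shrinks as sigma_t grows."""
        _, lf = sphere_fixture
        base = dict(lam=1.0, rmax=0.2)
        _, p0 = ensemble_bruteforce(placed_50, kernel_bank,
                                    SynchronyParams(sigma_t=0.0, **base),
                                    lf, freq_grid)
        cutoffs = []
        for st in (5.0, 20.0):
            _, p = ensemble_bruteforce(placed_50, kernel_bank,
                                       SynchronyParams(sigma_t=st, **base),
                                       lf, freq_grid)
            ratio = p.values.real / np.where(p0.values.real != 0,
                                             p0.values.real, 1.0)
            f_half_pred = np.sqrt(np.log(2.0) / 2.0) / (np.pi * st / 1000.0)
            i = int(np.argmin(np.abs(freq_grid - f_half_pred)))
            assert ratio[i] == pytest.approx(0.5, abs=0.1)
            below = freq_grid < 0.2 * f_half_pred
            assert np.allclose(ratio[below], 1.0, atol=0.05)
            cutoffs.append(f_half_pred)
        assert cutoffs[1] < cutoffs[0]

    def test_rhythmic_peaks_trace_zero_jitter_curve(self, population,
                                                    kernel_bank, dense_fixture,
                                                    freq_grid):
        """On a pair-dominated fixture, sharp rhythms (sigma_t * f0 << 1)
        reach the zero-jitter aperiodic level at f0 within 5%."""
        geom, lf = dense_fixture
        placed = place_population(geom, population, n_neurons=60, seed=1)
        base = dict(lam=1.0, rmax=0.2)
        a0, p0 = ensemble_bruteforce(placed, kernel_bank,
                                     SynchronyParams(sigma_t=0.0, **base),
                                     lf, freq_grid)
        total0 = a0.values + p0.values.real
        for f0 in (40.0, 80.0):
            sigma_t = 12.0 / f0  # sharp relative to the rhythm period
            ar, pr = ensemble_bruteforce(
                placed, kernel_bank,
                SynchronyParams(sigma_t=sigma_t, f0=f0, **base), lf, freq_grid)
            i = int(np.argmin(np.abs(freq_grid - f0)))
            ratio = (ar.values[i] + pr.values.real[i]) / total0[i]
            assert ratio == pytest.approx(1.0, abs=0.05)

    def test_monotone_in_rate_correlation_and_count(self, population,
                                                    kernel_bank, dense_fixture,
                                                    freq_grid):
        geom, lf = dense_fixture
        placed = place_population(geom, population, n_neurons=40, seed=2)

        def total(lam, rmax, n):
            sp = SynchronyParams(lam=lam, rmax=rmax, sigma_t=11.3)
            a, p = ensemble_bruteforce(placed.iloc[:n], kernel_bank, sp, lf,
                                       freq_grid)
            return a.values + p.values.real

        base = total(1.0, 0.1, 40)
        assert np.all(total(2.0, 0.1, 40) >= base - 1e-30)
        assert np.all(total(1.0, 0.2, 40) >= base - 1e-30)
        assert np.all(total(1.0, 0.1, 40) >= total(1.0, 0.1, 20) - 1e-30)


class TestSynapticEnsemble:
    def make_dn(self):
        geom = CortexGeometry.sphere(30.0, subdivisions=3)
        radii = np.arange(0.0, 61.0, 2.0)
        return pair_distance_density(geom, radii, n_centers=20, seed=0)

    def test_zero_scales_give_n_times_single_neuron(self, freq_grid):
        s = synaptic_ensemble_spectrum(PARALYZED_EEG_TREND, 0.0, 0.0, None, 100.0,
                                       freq_grid)
        from apeeg.trend import eval_trend

        assert np.allclose(s.values, 100.0 * eval_trend(PARALYZED_EEG_TREND, freq_grid))

    def test_ampa_cross_term_vanishes_without_spatial_scale(self, freq_grid):
        dn = self.make_dn()
        s0 = synaptic_ensemble_spectrum(PARALYZED_EEG_TREND, 0.5, 0.0, dn, 100.0,
                                        freq_grid)
        s1 = synaptic_ensemble_spectrum(PARALYZED_EEG_TREND, 0.5, 0.3, dn, 100.0,
                                        freq_grid)
        # enabling AMPA coherence only adds high-frequency (AMPA) power
        assert np.all(s1.values >= s0.values - 1e-30)

    def test_gaba_coherence_boosts_gaba_share(self, freq_grid):
        """With wider GABA than AMPA coherence, the slow-timescale share of
        ensemble power exceeds its single-neuron share."""
        from apeeg.trend import _lorentz_pair

        dn = self.make_dn()
        t = PARALYZED_EEG_TREND
        s = synaptic_ensemble_spectrum(t, 0.8, 0.1, dn, 100.0, freq_grid)
        p_gaba = _lorentz_pair(freq_grid, t.tau_i1, t.tau_i2, t.amp_inhibitory)
        p_ampa = _lorentz_pair(freq_grid, t.tau_e1, t.tau_e2, t.amp_excitatory)
        single_share = np.trapezoid(p_gaba, freq_grid) / np.trapezoid(
            p_gaba + p_ampa, freq_grid)
        gaba_part = s.values - 100.0 * (1.0 + dn.gaussian_weighted_integral(0.1)) * p_ampa
        ens_share = np.trapezoid(gaba_part, freq_grid) / np.trapezoid(
            s.values, freq_grid)
        assert ens_share > single_share
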