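import numpy as np
import pytest

from thetasync import synth
from thetasync.cfc import (
    CouplingGrid,
    apply_mi_mask,
    cfd,
    cfd_significance,
    comodulogram,
    equalized_bin_assignment,
    mean_vector_length,
    mi_surrogates,
    modulation_index,
)
from thetasync.cycles import detect_theta_cycles, waveform_phase
from thetasync.spectral import SLOW_GAMMA, band_envelope

FS = 625.0


def _sine_table(duration=60.0, freq=8.0):
    t = np.arange(int(duration * FS)) / FS
    x = np.sin(2 * np.pi * freq * t)
    phase, table = waveform_phase(x, FS)
    return x, phase, table


class TestModulationIndex:
    def test_constant_amplitude_zero_mi(self):
        x, _, table = _sine_table()
        mi, profile, _ = modulation_index(np.ones(x.size), table)
        assert mi == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(profile, profile[0])

    def test_single_bin_concentration_mi_one(self):
        x, _, table = _sine_table()
        assign = equalized_bin_assignment(table, x.size, 20)
        amp = np.where(assign == 7, 1.0, 1e-300)
        mi, _, pref = modulation_index(amp, table)
        assert mi == pytest.approx(1.0, abs=1e-6)
        assert pref == pytest.approx((7 + 0.5) * 2 * np.pi / 20)

    def test_two_bin_closed_form(self):
        # amplitude equally split over exactly 2 of 20 bins:
        # MI = 1 - log2/log20
        x, _, table = _sine_table()
        assign = equalized_bin_assignment(table, x.size, 20)
        amp = np.where((assign == 3) | (assign == 12), 1.0, 1e-300)
        mi, _, _ = modulation_index(amp, table)
        assert mi == pytest.approx(1 - np.log(2) / np.log(20), abs=1e-6)

    def test_amplitude_scale_invariance(self, rng):
        x, _, table = _sine_table()
        amp = rng.uniform(0.1, 1.0, x.size)
        mi1, _, _ = modulation_index(amp, table)
        mi2, _, _ = modulation_index(123.4 * amp, table)
        assert mi1 == pytest.approx(mi2, abs=1e-12)

    def test_circular_bin_relabeling_invariance(self, rng):
        x, _, table = _sine_table()
        assign = equalized_bin_assignment(table, x.size, 20)
        amp = rng.uniform(0.1, 1.0, x.size)
        mi1, _, _ = modulation_index(amp, n_bins=20, bin_assignment=assign)
        rolled = np.where(assign >= 0, (assign + 5) % 20, -1)
        mi2, _, _ = modulation_index(amp, n_bins=20, bin_assignment=rolled)
        assert mi1 == pytest.approx(mi2, abs=1e-12)

    def test_bins_must_divide_by_four(self, rng):
        x, _, table = _sine_table(duration=10.0)
        with pytest.raises(ValueError):
            equalized_bin_assignment(table, x.size, 18)

    def test_equalized_quadrants_equal_time(self):
        x, _, table = _sine_table()
        assign = equalized_bin_assignment(table, x.size, 20)
        counts = np.bincount(assign[assign >= 0], minlength=20)
        # symmetric sinusoid: even occupancy up to integer-rounding of the
        # ~5-sample bins at this sampling rate
        assert counts.min() > 0.6 * counts.mean()
        assert counts.max() < 1.4 * counts.mean()


class TestMVL:
    def test_uniform_amplitude_small(self, rng):
        ph = rng.uniform(0, 2 * np.pi, 200000)
        amp = np.ones(ph.size)
        assert mean_vector_length(ph, amp) < 0.01

    def test_cosine_modulation_half(self):
        ph = np.linspace(0, 2 * np.pi, 100001)[:-1]
        amp = 1 + np.cos(ph)
        assert mean_vector_length(ph, amp) == pytest.approx(0.5, abs=1e-3)

    def test_ranking_matches_mi(self):
        # MI and MVL rank increasing coupling strengths identically
        mis, mvls = [], []
        for c in (0.05, 0.5, 0.95):
            spec = synth.GeneratorSpec(loading=np.ones(1), coupling=c,
                                       preferred_phase=np.pi,
                                       gamma_amplitude=0.5)
            _, truth = synth.simulate_laminar_lfp([spec], duration=40.0,
                                                  noise_level=0.0, seed=1,
                                                  n_channels=1)
            x = truth.sources[0]
            phase, table = waveform_phase(x, FS)
            env, _, _ = band_envelope(x, FS, SLOW_GAMMA)
            mi, _, _ = modulation_index(env, table)
            ok = np.isfinite(phase)
            mvl = mean_vector_length(phase[ok], env[ok])
            mis.append(mi)
            mvls.append(mvl)
        assert np.argsort(mis).tolist() == np.argsort(mvls).tolist() == [0, 1, 2]

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            mean_vector_length(np.zeros(10), np.zeros(10))


class TestSurrogates:
    def test_coupled_exceeds_threshold(self, laminar):
        _, _, truth = laminar
        x = truth.sources[0]
        _, table = waveform_phase(x, FS)
        env, _, _ = band_envelope(x, FS, SLOW_GAMMA)
        mi, _, _ = modulation_index(env, table)
        dist = mi_surrogates(env, table, n_surrogates=100, fs=FS, seed=0)
        assert mi > dist.threshold(95.0)
        assert dist.mu > 0  # finite-sample MI bias: threshold, not zero

    def test_uncoupled_below_threshold(self):
        x, _ = synth.simulate_directional_cfc("gamma_leads", duration=60.0,
                                              seed=5, coupled=False)
        _, table = waveform_phase(x, FS)
        env, _, _ = band_envelope(x, FS, SLOW_GAMMA)
        mi, _, _ = modulation_index(env, table)
        dist = mi_surrogates(env, table, n_surrogates=100, fs=FS, seed=0)
        assert mi < dist.threshold(95.0)


class TestComodulogram:
    def test_grid_maximum_at_coupled_cell(self):
        spec = synth.GeneratorSpec(loading=np.ones(1), coupling=1.0,
                                   gamma_band=(35.0, 45.0),
                                   preferred_phase=np.pi, gamma_amplitude=0.5)
        rec, _ = synth.simulate_laminar_lfp([spec], duration=60.0,
                                            noise_level=0.05, seed=2,
                                            n_channels=1)
        grid = comodulogram(rec.data[:, 0], FS,
                            theta_freqs=np.arange(5.0, 12.0),
                            gamma_freqs=np.arange(30.0, 105.0, 5.0))
        tf, gf = grid.argmax_cell()
        assert abs(tf - 8.0) <= 1.0
        assert abs(gf - 40.0) <= 10.0

    def test_within_vs_between_generator(self, laminar):
        _, _, truth = laminar
        gamma_centres = [45.0, 80.0, 125.0]
        mi = np.zeros((3, 3))  # phase source x gamma source
        for i in range(3):
            for j in range(3):
                grid = comodulogram(
                    truth.sources[j], FS, phase_signal=truth.sources[i],
                    theta_freqs=np.array([7.0, 8.0, 9.0]),
                    gamma_freqs=np.array([gamma_centres[j]]),
                )
                mi[i, j] = np.nanmax(grid.values)
        # for each pathway's gamma, the same pathway's theta wins
        for j in range(3):
            assert np.argmax(mi[:, j]) == j

    def test_gamma_grid_must_clear_theta(self):
        with pytest.raises(ValueError):
            comodulogram(np.zeros(10000), FS, theta_freqs=np.array([10.0]),
                         gamma_freqs=np.array([15.0]))


class TestEqualizedOnAsymmetric:
    def test_no_false_positive_with_independent_gamma(self):
        # strongly asymmetric theta, gamma amplitude fully independent of it:
        # the equalized-bin MI must stay at its surrogate level
        from thetasync._dsp import bandpass

        hits = 0
        for seed in range(5):
            spec = synth.GeneratorSpec(loading=np.ones(1), asymmetry=0.2,
                                       coupling=0.0, gamma_amplitude=0.0)
            _, truth = synth.simulate_laminar_lfp([spec], duration=60.0,
                                                  noise_level=0.0, seed=seed,
                                                  n_channels=1)
            x = truth.sources[0]
            rng = np.random.default_rng(seed + 100)
            g = bandpass(rng.standard_normal(x.size), FS, 30.0, 60.0)
            env, _, _ = band_envelope(g, FS, SLOW_GAMMA)
            _, table = waveform_phase(x, FS)
            mi, _, _ = modulation_index(env, table)
            dist = mi_surrogates(env, table, n_surrogates=50, fs=FS, seed=0)
            hits += mi > dist.threshold(95.0)
        assert hits <= 1

    def test_harmonic_leakage_is_detected(self):
        # the signal's own harmonics in the gamma band are genuinely
        # phase-locked amplitude: the MI must flag them (known limitation of
        # any binning; documented rather than suppressed)
        rng = np.random.default_rng(0)
        spec = synth.GeneratorSpec(loading=np.ones(1), asymmetry=0.25,
                                   coupling=0.0, gamma_amplitude=0.0)
        _, truth = synth.simulate_laminar_lfp([spec], duration=60.0,
                                              noise_level=0.0, seed=4,
                                              n_channels=1)
        x = truth.sources[0]
        env, _, _ = band_envelope(x + 0.05 * rng.standard_normal(x.size),
                                  FS, SLOW_GAMMA)
        _, table = waveform_phase(x, FS)
        mi, _, _ = modulation_index(env, table)
        dist = mi_surrogates(env, table, n_surrogates=50, fs=FS, seed=0)
        assert mi > dist.threshold(95.0)


class TestCFD:
    def test_gamma_leads_negative(self):
        x, _ = synth.simulate_directional_cfc("gamma_leads", lag=0.03,
                                              duration=120.0, seed=1)
        grid = cfd(x, FS, theta_freqs=np.arange(6.0, 10.5, 0.5),
                   gamma_freqs=np.array([45.0]))
        i = np.nanargmax(np.abs(grid.values[:, 0]))
        assert grid.values[i, 0] < 0

    def test_theta_leads_positive(self):
        x, _ = synth.simulate_directional_cfc("theta_leads", lag=0.03,
                                              duration=120.0, seed=1)
        grid = cfd(x, FS, theta_freqs=np.arange(6.0, 10.5, 0.5),
                   gamma_freqs=np.array([45.0]))
        i = np.nanargmax(np.abs(grid.values[:, 0]))
        assert grid.values[i, 0] > 0

    def test_antisymmetry_under_role_swap(self):
        # feeding the envelope as the slow input flips the sign
        from thetasync.cfc import _complex_coherency, _psi, _segment_spectra
        from thetasync._dsp import bandpass, envelope

        x, _ = synth.simulate_directional_cfc("gamma_leads", lag=0.03,
                                              duration=60.0, seed=2)
        env = envelope(bandpass(x, FS, 35.0, 55.0))
        f, X = _segment_spectra(x, FS, 2.0)
        _, Y = _segment_spectra(env, FS, 2.0)
        psi_xy = _psi(_complex_coherency(X, Y), f, 8.0, 2.0, 0.5)
        psi_yx = _psi(_complex_coherency(Y, X), f, 8.0, 2.0, 0.5)
        assert psi_xy == pytest.approx(-psi_yx, rel=1e-9)

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="segments"):
            cfd(rng.standard_normal(int(10 * FS)), FS)

    def test_null_within_bounds(self):
        x, _ = synth.simulate_directional_cfc("gamma_leads", duration=60.0,
                                              seed=3, coupled=False)
        grid, flags = cfd_significance(
            x, FS, theta_freqs=np.arange(6.0, 10.5, 1.0),
            gamma_freqs=np.array([45.0]), n_surrogates=50, seed=0,
        )
        assert np.mean(flags != 0) <= 0.25

    def test_significance_flags_direction(self):
        x, _ = synth.simulate_directional_cfc("gamma_leads", lag=0.03,
                                              duration=120.0, seed=1)
        grid, flags = cfd_significance(
            x, FS, theta_freqs=np.arange(6.0, 10.5, 0.5),
            gamma_freqs=np.array([45.0]), n_surrogates=50, seed=0,
        )
        i = np.nanargmax(np.abs(grid.values[:, 0]))
        assert flags[i, 0] == -1
        # thresholds roughly symmetric about the surrogate mean
        mu = (grid.upper_threshold + grid.lower_threshold) / 2
        half = (grid.upper_threshold - grid.lower_threshold) / 2
        assert np.all(np.abs(mu) <= 0.2 * np.abs(half) + 1e-12)


class TestMask:
    def _grids(self, mi_vals, cfd_vals):
        tf = np.array([7.0, 8.0])
        gf = np.array([40.0, 80.0])
        return (CouplingGrid(tf, gf, np.asarray(mi_vals, float), kind="mi"),
                CouplingGrid(tf, gf, np.asarray(cfd_vals, float), kind="cfd"))

    def test_uniform_mi_maps_to_ones(self):
        mi, psi = self._grids([[0.3, 0.3], [0.3, 0.3]], [[1.0, -2.0], [3.0, -4.0]])
        out = apply_mi_mask(mi, psi)
        assert np.allclose(out.values, psi.values)

    def test_zero_mi_cell_zeroes_psi(self):
        mi, psi = self._grids([[0.0, 0.5], [1.0, 0.2]], [[5.0, 5.0], [5.0, 5.0]])
        out = apply_mi_mask(mi, psi)
        assert out.values[0, 0] == 0.0
        assert out.values[1, 0] == 5.0

    def test_masked_extreme_at_mi_maximum(self):
        x, _ = synth.simulate_directional_cfc("gamma_leads", lag=0.03,
                                              duration=120.0, seed=7)
        tf = np.arange(6.0, 10.5, 1.0)
        gf = np.arange(35.0, 60.0, 5.0)
        mi = comodulogram(x, FS, theta_freqs=tf, gamma_freqs=gf)
        dgrid = cfd(x, FS, theta_freqs=tf, gamma_freqs=gf)
        masked = apply_mi_mask(mi, dgrid)
        i, j = np.unravel_index(np.nanargmax(np.abs(masked.values)),
                                masked.values.shape)
        # the masked extreme sits on the MI plateau (within 90% of the max)
        assert mi.values[i, j] >= 0.9 * np.nanmax(mi.values)

    def test_grid_mismatch_rejected(self):
        mi, _ = self._grids([[0.1, 0.2], [0.3, 0.4]], [[0, 0], [0, 0]])
        other = CouplingGrid(np.array([1.0, 2.0]), np.array([40.0, 80.0]),
                             np.zeros((2, 2)))
        with pytest.raises(ValueError):
            apply_mi_mask(mi, other)


class TestGridIO:
    def test_write_roundtrip_values(self, tmp_path):
        grid = CouplingGrid(np.array([7.0, 8.0]), np.array([40.0, 80.0]),
                            np.array([[0.1, 0.2], [0.3, 0.4]]))
        grid.write(tmp_path / "g.tsv")
        lines = (tmp_path / "g.tsv").read_text().strip().splitlines()
        assert lines[0].startswith("# kind")
        body = np.array([[float(v) for v in ln.split("\t")[1:]]
                         for ln in lines[2:]])
        assert np.allclose(body, grid.values)

    def test_rejects_unsorted_axes(self):
        with pytest.raises(ValueError):
            CouplingGrid(np.array([8.0, 7.0]), np.array([40.0]), np.zeros((2, 1)))
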