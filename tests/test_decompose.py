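import copy

import numpy as np
import pytest

from thetasync import synth
from thetasync.decompose import (
    fit_decomposition,
    match_components,
    reconstruct_lfp,
    reconstruct_partial_lfp,
    select_components,
    validate_band_split,
    write_decomposition,
)
from thetasync.recording import MultichannelRecording

FS = 625.0


def _matched_correlations(truth, dec):
    """Best |corr| between each true source and any component."""
    out = []
    for g in range(truth.sources.shape[0]):
        cs = [abs(np.corrcoef(truth.sources[g], dec.series[n])[0, 1])
              for n in range(dec.n_components)]
        out.append(max(cs))
    return np.array(out)


class TestFit:
    def test_single_source_one_dominant_component(self):
        loading = np.linspace(1.0, 0.1, 8)
        spec = synth.GeneratorSpec(loading=loading, coupling=0.0,
                                   gamma_amplitude=0.0)
        rec, _ = synth.simulate_laminar_lfp([spec], duration=20.0,
                                            noise_level=1e-4, seed=0)
        dec = fit_decomposition(rec, seed=0)
        assert dec.variance_share[0] > 0.99

    def test_three_generator_recovery(self, laminar, laminar_dec):
        _, _, truth = laminar
        corr = _matched_correlations(truth, laminar_dec)
        assert np.all(corr > 0.95)

    def test_variance_share_structure(self, laminar_dec):
        s = laminar_dec.variance_share
        assert np.all((s >= 0) & (s <= 1))
        assert s.sum() <= 1.0 + 1e-9
        assert s.sum() >= 0.99 - 0.02  # retained subspace variance
        assert (s > 0.01).sum() == 3
        assert np.all(s[3:] < 0.01)

    def test_deterministic_given_seed(self, laminar):
        _, rec, _ = laminar
        d1 = fit_decomposition(rec, seed=42)
        d2 = fit_decomposition(rec, seed=42)
        assert np.array_equal(d1.mixing, d2.mixing)
        assert np.array_equal(d1.series, d2.series)

    def test_channel_permutation_equivariance(self, laminar):
        _, rec, _ = laminar
        perm = np.arange(rec.n_channels)[::-1]
        rec_p = MultichannelRecording(
            data=rec.data[:, perm], fs=rec.fs,
            depths_um=np.arange(rec.n_channels) * 100.0,
        )
        d1 = fit_decomposition(rec, seed=0)
        d2 = fit_decomposition(rec_p, seed=0)
        # series unchanged up to sign/order; loading rows permuted identically
        for j in range(d2.n_components):
            corr = np.array([np.corrcoef(d1.series[i], d2.series[j])[0, 1]
                             for i in range(d1.n_components)])
            i = int(np.argmax(np.abs(corr)))
            sign = np.sign(corr[i])
            assert abs(corr[i]) > 1 - 1e-6
            a = d1.mixing[perm, i]
            b = sign * d2.mixing[:, j]
            assert np.allclose(a, b, atol=1e-6 * max(np.abs(a).max(), 1.0))

    def test_rank_deficient_rejected(self, rng):
        base = rng.standard_normal((5000, 1))
        data = np.repeat(base, 4, axis=1)  # rank 1
        rec = MultichannelRecording(data=data, fs=FS,
                                    depths_um=np.arange(4) * 100.0)
        with pytest.raises(ValueError, match="rank"):
            fit_decomposition(rec)


class TestMatch:
    def test_permutation_and_sign_recovery(self, laminar_dec):
        dec = laminar_dec
        k = dec.n_components
        rng = np.random.default_rng(0)
        perm = rng.permutation(k)
        signs = rng.choice([-1.0, 1.0], k)
        other = copy.deepcopy(dec)
        other.mixing = dec.mixing[:, perm] * signs[None, :]
        other.series = dec.series[perm] * signs[:, None]
        p, s, sims = match_components(dec, other)
        assert np.array_equal(p, perm)
        assert np.allclose(s, signs)
        assert np.allclose(sims, 1.0)

    def test_stable_under_loading_noise(self, laminar_dec, rng):
        dec = laminar_dec
        other = copy.deepcopy(dec)
        scale = 0.02 * np.linalg.norm(dec.mixing, axis=0, keepdims=True)
        other.mixing = dec.mixing + scale * rng.standard_normal(dec.mixing.shape)
        p, _, sims = match_components(dec, other)
        assert np.array_equal(p, np.arange(dec.n_components))
        assert np.all(sims > 0.95)

    def test_random_orthogonal_loadings_low_similarity(self, rng):
        # Monte-Carlo oracle: |cos| of two random unit vectors in R^d has
        # mean ~ sqrt(2/(pi*d))
        d = 32
        sims = []
        for _ in range(200):
            a = rng.standard_normal(d)
            b = rng.standard_normal(d)
            sims.append(abs(a @ b) / np.linalg.norm(a) / np.linalg.norm(b))
        expected = np.sqrt(2 / (np.pi * d))
        assert np.mean(sims) == pytest.approx(expected, rel=0.2)


class TestSelect:
    def test_stationary_fixture_all_selected(self, laminar, laminar_dec):
        _, rec, _ = laminar
        n4 = rec.n_samples // 4
        epochs = [(i * n4, (i + 1) * n4) for i in range(4)]
        selected, stability = select_components(laminar_dec, rec, epochs, seed=0)
        big = np.nonzero(laminar_dec.variance_share > 0.01)[0]
        assert set(big) <= set(selected.tolist())
        assert np.all(stability[big] > 0.95)

    def test_min_variance_one_empty(self, laminar, laminar_dec):
        _, rec, _ = laminar
        n2 = rec.n_samples // 2
        selected, _ = select_components(laminar_dec, rec,
                                        [(0, n2), (n2, 2 * n2)],
                                        min_variance=1.0, seed=0)
        assert selected.size == 0

    def test_transient_generator_excluded(self):
        # generator 2 switched off in the second half
        rng = np.random.default_rng(0)
        n = int(40 * FS)
        t = np.arange(n) / FS
        s1 = np.sin(2 * np.pi * 8 * t) + 0.05 * rng.standard_normal(n)
        s2 = np.sin(2 * np.pi * 7 * t + 1.0) + 0.05 * rng.standard_normal(n)
        s2[n // 2:] = 0.0  # generator fully off: its spatial pattern vanishes
        load1 = np.exp(-0.5 * ((np.arange(8) - 2) / 1.0) ** 2)
        load2 = np.exp(-0.5 * ((np.arange(8) - 5) / 1.0) ** 2)
        data = np.outer(s1, load1) + np.outer(s2, load2)
        data += 0.02 * rng.standard_normal(data.shape)
        rec = MultichannelRecording(data=data, fs=FS,
                                    depths_um=np.arange(8) * 100.0)
        dec = fit_decomposition(rec, seed=0)
        half = n // 2
        selected, stability = select_components(
            dec, rec, [(0, half), (half, n)], seed=0
        )
        # the transient generator's component must not survive selection
        corr2 = [abs(np.corrcoef(s2[:half], dec.series[k][:half])[0, 1])
                 for k in range(dec.n_components)]
        transient = int(np.argmax(corr2))
        assert transient not in selected

    def test_overlapping_epochs_rejected(self, laminar, laminar_dec):
        _, rec, _ = laminar
        with pytest.raises(ValueError, match="overlap"):
            select_components(laminar_dec, rec, [(0, 10000), (5000, 20000)])


class TestReconstruct:
    def test_partials_plus_mean_reconstruct(self, laminar, laminar_dec):
        _, rec, _ = laminar
        dec = laminar_dec
        total = dec.mean + sum(
            reconstruct_partial_lfp(dec, n).data for n in range(dec.n_components)
        )
        # equals the PCA-retained reconstruction of the input
        resid = np.linalg.norm(rec.data - total) / np.linalg.norm(rec.data)
        assert resid**2 < 1e-2  # discarded-variance budget (1% kept out)
        assert np.allclose(total, reconstruct_lfp(dec).data, rtol=1e-10, atol=1e-10)

    def test_gauge_flip_invariance(self, laminar_dec):
        dec = laminar_dec
        flipped = copy.deepcopy(dec)
        flipped.mixing = -flipped.mixing
        flipped.series = -flipped.series
        a = reconstruct_partial_lfp(dec, 0).data
        b = reconstruct_partial_lfp(flipped, 0).data
        assert np.array_equal(a, b)

    def test_partial_lfp_correlates_with_source(self, laminar, laminar_dec):
        _, _, truth = laminar
        dec = laminar_dec
        for g in range(3):
            cs = [abs(np.corrcoef(truth.sources[g], dec.series[n])[0, 1])
                  for n in range(dec.n_components)]
            n = int(np.argmax(cs))
            partial = reconstruct_partial_lfp(dec, n)
            ch = int(np.argmax(np.abs(truth.mixing[:, g])))
            r = abs(np.corrcoef(truth.sources[g], partial.data[:, ch])[0, 1])
            assert r > 0.95

    def test_invalid_index(self, laminar_dec):
        with pytest.raises(ValueError):
            reconstruct_partial_lfp(laminar_dec, -1)


class TestBandSplit:
    def test_synthetic_fixture_similarities(self, laminar):
        _, rec, _ = laminar
        full, report = validate_band_split(rec, seed=0)
        big = np.nonzero(full.variance_share > 0.01)[0]
        # theta dominates: low-band decomposition must recover the loadings
        assert np.all(report["low"]["similarity"][np.isin(
            report["low"]["permutation"], big)] > 0.9)

    def test_identical_input_similarity_one(self, laminar):
        _, rec, _ = laminar
        full = fit_decomposition(rec, seed=0)
        p, _, sims = match_components(full, full)
        assert np.array_equal(p, np.arange(full.n_components))
        assert np.allclose(sims, 1.0)


class TestIO:
    def test_write_decomposition(self, laminar_dec, tmp_path):
        write_decomposition(laminar_dec, tmp_path / "dec")
        loadings = np.loadtxt(tmp_path / "dec" / "loadings.tsv")
        assert loadings.shape == laminar_dec.mixing.shape
        import json

        meta = json.loads((tmp_path / "dec" / "meta.json").read_text())
        assert meta["n_components"] == laminar_dec.n_components
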