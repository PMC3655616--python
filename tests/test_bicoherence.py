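import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegbico as eb
from eegbico.bicoherence import BifrequencyGrid, band_pair_table
from eegbico.preprocess import ParameterError

from oracles import fft_bicoherence

FS = 256.0
SMALL_GRID = BifrequencyGrid(1, 20, 1, 2)


class TestHarmonicWaveletCoeffs:
    def test_energy_concentrated_in_containing_band(self):
        t = np.arange(512) / FS
        x = np.cos(2 * np.pi * 10 * t)
        grid = BifrequencyGrid(1, 45, 1, 2)
        w = eb.harmonic_wavelet_coeffs(x, FS, grid)
        mags = np.mean(np.abs(w) ** 2, axis=-1)
        freqs = grid.frequencies
        assert freqs[np.argmax(mags)] == 10.0
        i20 = np.argmin(abs(freqs - 20))
        assert np.sqrt(mags[i20] / mags.max()) < 0.05

    def test_zero_epoch_gives_zero_coefficients(self):
        w = eb.harmonic_wavelet_coeffs(np.zeros(512), FS, SMALL_GRID)
        assert np.all(w == 0)

    def test_linearity_in_amplitude(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=512)
        w1 = eb.harmonic_wavelet_coeffs(x, FS, SMALL_GRID)
        w3 = eb.harmonic_wavelet_coeffs(3.0 * x, FS, SMALL_GRID)
        np.testing.assert_allclose(w3, 3.0 * w1, atol=1e-9)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            eb.harmonic_wavelet_coeffs(np.zeros(512), FS, BifrequencyGrid(1, 130, 1, 2))


class TestWaveletBicoherence:
    def test_coupled_triplet_detected(self, coupled_triplet_epochs):
        epochs, _ = coupled_triplet_epochs
        bic = eb.wavelet_bicoherence(epochs, epochs.labels[0], SMALL_GRID)
        assert bic.at(9, 6) >= 0.8

    def test_uncoupled_triplet_near_zero(self, uncoupled_triplet_epochs):
        epochs, _ = uncoupled_triplet_epochs
        bic = eb.wavelet_bicoherence(epochs, epochs.labels[0], SMALL_GRID)
        assert bic.at(9, 6) <= 0.15

    def test_agrees_with_direct_fft_bispectrum_oracle(self, coupled_triplet_epochs):
        epochs, rec = coupled_triplet_epochs
        bic = eb.wavelet_bicoherence(epochs, epochs.labels[0], SMALL_GRID)
        oracle = fft_bicoherence(rec.data[0], FS, 6.0, 9.0)
        assert abs(bic.at(9, 6) - oracle) < 0.1

    def test_white_noise_stays_low_everywhere(self):
        n = 512 + 199 * 128
        rec = eb.generate_background(
            eb.SynthSpec(n_channels=1, fs=FS, duration=n / FS,
                         background_slope=0.0, seed=4)
        )
        bic = eb.wavelet_bicoherence(eb.make_epochs(rec), rec.labels[0], SMALL_GRID)
        assert np.nanmax(bic.values) <= 0.2

    def test_amplitude_invariance(self, coupled_triplet_epochs):
        epochs, _ = coupled_triplet_epochs
        b1 = eb.wavelet_bicoherence(epochs, epochs.labels[0], SMALL_GRID)
        scaled = eb.EpochSet(epochs.epochs * 5.0, epochs.fs, epochs.labels,
                             epochs.epoch_length, epochs.overlap)
        b5 = eb.wavelet_bicoherence(scaled, epochs.labels[0], SMALL_GRID)
        np.testing.assert_allclose(b1.values, b5.values, atol=1e-9, equal_nan=True)

    def test_single_epoch_rejected(self):
        rec = eb.generate_background(eb.SynthSpec(n_channels=1, fs=FS, duration=2, seed=0))
        ep = eb.make_epochs(rec, 2.0, 0.0)
        with pytest.raises(ParameterError):
            eb.wavelet_bicoherence(ep, rec.labels[0], SMALL_GRID)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounded_in_unit_interval_on_random_input(self, seed):
        """Cauchy-Schwarz bound: any input yields values in [0, 1]."""
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(1, 512 * 4)) * rng.uniform(0.1, 100)
        rec = eb.Recording(data=data, fs=FS, labels=["A"])
        bic = eb.wavelet_bicoherence(eb.make_epochs(rec), "A", SMALL_GRID)
        vals = bic.values[bic.domain]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_coupling_strength_monotonic(self):
        """Peak bicoherence is monotone increasing in coupling strength
        (rank correlation 1 over {0,.25,.5,.75,1}, 200 epochs, 3 seeds)."""
        n = 512 + 199 * 128
        strengths = [0.0, 0.25, 0.5, 0.75, 1.0]
        for seed in (1, 2, 3):
            est = []
            for s in strengths:
                spec = eb.SynthSpec(
                    n_channels=1, fs=FS, duration=n / FS, background_slope=0.0,
                    background_rms=0.5, qpc_triplets=[(6.0, 9.0, s, 1.0)],
                    seed=seed,
                )
                ep = eb.make_epochs(eb.build_recording(spec))
                est.append(eb.wavelet_bicoherence(ep, ep.labels[0], SMALL_GRID).at(9, 6))
            assert all(b > a for a, b in zip(est, est[1:])), (seed, est)


class TestFilterBicoherence:
    def test_zero_threshold_is_identity(self, coupled_triplet_epochs):
        epochs, _ = coupled_triplet_epochs
        bic = eb.wavelet_bicoherence(epochs, epochs.labels[0], SMALL_GRID)
        out = eb.filter_bicoherence(bic, 0.0)
        np.testing.assert_allclose(out.values, bic.values, equal_nan=True)

    def test_unit_threshold_zeroes_everything(self, coupled_triplet_epochs):
        epochs, _ = coupled_triplet_epochs
        bic = eb.wavelet_bicoherence(epochs, epochs.labels[0], SMALL_GRID)
        out = eb.filter_bicoherence(bic, 1.0)
        assert np.nansum(out.values) == 0

    def test_surrogate_filter_isolates_coupled_neighborhood(self, coupled_triplet_epochs):
        """After surrogate filtering, the coupled cell survives and
        essentially all surviving coupling mass sits in its 2 Hz-bandwidth
        neighborhood; any stragglers elsewhere are near-threshold noise."""
        epochs, _ = coupled_triplet_epochs
        bic = eb.wavelet_bicoherence(epochs, epochs.labels[0], SMALL_GRID)
        thr = eb.surrogate_threshold(epochs, epochs.labels[0], SMALL_GRID,
                                     n_surrogates=40, seed=5)
        out = eb.filter_bicoherence(bic, thr)
        jj, kk = np.nonzero(np.nan_to_num(out.values) > 0)
        freqs = SMALL_GRID.frequencies
        surviving = {(freqs[j], freqs[k]): out.values[j, k] for j, k in zip(jj, kk)}
        assert (9.0, 6.0) in surviving
        near = {pair: v for pair, v in surviving.items()
                if abs(pair[0] - 9) <= 2 and abs(pair[1] - 6) <= 2}
        far = {pair: v for pair, v in surviving.items() if pair not in near}
        assert sum(near.values()) >= 0.9 * sum(surviving.values())
        assert all(v < 0.1 for v in far.values())

    def test_threshold_source_recorded(self, coupled_triplet_epochs):
        epochs, _ = coupled_triplet_epochs
        bic = eb.wavelet_bicoherence(epochs, epochs.labels[0], SMALL_GRID)
        assert "0.3" in eb.filter_bicoherence(bic, 0.3).filter_source


class TestTotalBandCoupling:
    def _matrix_with(self, cells):
        grid = BifrequencyGrid(1, 45, 1, 2)
        from eegbico.bicoherence import _sum_indices

        domain, _ = _sum_indices(grid)
        values = np.where(domain, 0.0, np.nan)
        freqs = list(grid.frequencies)
        for (fj, fk), v in cells.items():
            values[freqs.index(fj), freqs.index(fk)] = v
        return eb.BicoherenceMatrix(values=values, grid=grid, n_epochs=10)

    def test_all_zero_matrix_gives_zero(self):
        bic = self._matrix_with({})
        assert eb.total_band_coupling(bic, "theta", "alpha") == 0.0

    def test_single_cell_squared_sum_convention(self):
        # one magnitude-valued cell v in (alpha_j, theta_k): squared sum -> v^2
        bic = self._matrix_with({(9.0, 6.0): 0.6})
        assert eb.total_band_coupling(bic, "theta", "alpha", square=True) == \
            pytest.approx(0.36)
        # default: stored values are already squared, summed as-is
        assert eb.total_band_coupling(bic, "theta", "alpha") == pytest.approx(0.6)

    def test_symmetrized_band_pair(self):
        bic = self._matrix_with({(9.0, 6.0): 0.5})
        assert eb.total_band_coupling(bic, "alpha", "theta") == \
            eb.total_band_coupling(bic, "theta", "alpha")

    def test_empty_pair_returns_nan_sentinel(self):
        # gamma-gamma has no cells with f_j + f_k <= 45
        bic = self._matrix_with({})
        assert np.isnan(eb.total_band_coupling(bic, "gamma", "gamma"))

    def test_coupled_fixture_ranks_band_pairs(self, coupled_triplet_epochs):
        epochs, _ = coupled_triplet_epochs
        grid = BifrequencyGrid(1, 45, 1, 2)
        bic = eb.wavelet_bicoherence(epochs, epochs.labels[0], grid)
        # triplet 6+9->15: (alpha_j=9, theta_k=6) cell carries the coupling
        assert eb.total_band_coupling(bic, "theta", "alpha") > \
            eb.total_band_coupling(bic, "theta", "beta")

    def test_band_pair_table_covers_all_pairs(self, coupled_triplet_epochs):
        epochs, _ = coupled_triplet_epochs
        bic = eb.wavelet_bicoherence(epochs, epochs.labels[0],
                                     BifrequencyGrid(1, 45, 1, 2))
        tbl = band_pair_table(bic)
        assert len(tbl) == 15  # 5 bands -> 15 unordered pairs incl self
        assert np.isnan(
            tbl.set_index(["band_j", "band_k"]).loc[("gamma", "gamma"), "coupling"]
        )
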