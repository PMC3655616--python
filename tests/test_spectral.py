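import numpy as np
import pandas as pd
import pytest

import eegbico as eb
from eegbico.preprocess import ParameterError
from eegbico.spectral import CANONICAL_BANDS, FrequencyGrid, PowerSpectrum

FS = 256.0


def _epochs_of(x):
    rec = eb.Recording(data=np.atleast_2d(x), fs=FS,
                       labels=[f"C{i}" for i in range(np.atleast_2d(x).shape[0])])
    return eb.make_epochs(rec)


class TestMorletPower:
    @pytest.mark.parametrize("freq", [3.0, 10.0, 20.0, 40.0])
    def test_peak_recovery_within_grid_step(self, freq):
        t = np.arange(int(30 * FS)) / FS
        ps = eb.morlet_power(_epochs_of(np.cos(2 * np.pi * freq * t)))
        peak = ps.grid.frequencies[np.argmax(ps.power[0])]
        assert abs(peak - freq) <= 0.5

    def test_amplitude_squared_scaling_across_frequencies(self):
        """6 Hz amp 1 vs 20 Hz amp 2 -> peak power ratio 1:4."""
        t = np.arange(int(60 * FS)) / FS
        x = np.cos(2 * np.pi * 6 * t) + 2 * np.cos(2 * np.pi * 20 * t)
        ps = eb.morlet_power(_epochs_of(x))
        f = ps.grid.frequencies
        p6 = ps.power[0, np.argmin(abs(f - 6))]
        p20 = ps.power[0, np.argmin(abs(f - 20))]
        assert p20 / p6 == pytest.approx(4.0, rel=0.10)

    def test_doubling_amplitude_quadruples_power(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.cos(2 * np.pi * 10 * t)
        p1 = eb.morlet_power(_epochs_of(x)).power
        p2 = eb.morlet_power(_epochs_of(2 * x)).power
        i = np.argmax(p1[0])
        assert p2[0, i] / p1[0, i] == pytest.approx(4.0, rel=0.02)

    def test_zero_input_gives_zero_spectrum(self):
        ps = eb.morlet_power(_epochs_of(np.zeros(int(10 * FS))))
        assert np.all(ps.power == 0)

    def test_grid_beyond_nyquist_rejected(self):
        t = np.arange(int(10 * FS)) / FS
        with pytest.raises(ParameterError):
            eb.morlet_power(_epochs_of(np.cos(2 * np.pi * 10 * t)),
                            FrequencyGrid(1, 130, 0.5))

    def test_agrees_with_pywavelets_cwt(self):
        """Independent route: pywt's complex Morlet (B=2, C=omega/2pi) gives
        the same peak location and the same cross-frequency power ratio."""
        pywt = pytest.importorskip("pywt")
        t = np.arange(int(30 * FS)) / FS
        x = np.cos(2 * np.pi * 6 * t) + 2 * np.cos(2 * np.pi * 20 * t)
        ps = eb.morlet_power(_epochs_of(x))
        f = ps.grid.frequencies
        omega = 6.0
        wav = f"cmor2.0-{omega / (2 * np.pi):.6f}"
        scales = pywt.frequency2scale(wav, f / FS)
        coef, _ = pywt.cwt(x, scales, wav, sampling_period=1.0 / FS)
        p = np.mean(np.abs(coef) ** 2, axis=1)
        i6, i20 = np.argmin(abs(f - 6)), np.argmin(abs(f - 20))
        # same peak, up to one grid step of each other
        assert abs(f[np.argmax(p)] - f[np.argmax(ps.power[0])]) <= 0.5
        # pywt's convention scales per frequency; compare gain-corrected ratio
        ratio_ours = ps.power[0, i20] / ps.power[0, i6]
        ratio_pywt = (p[i20] / scales[i20]) / (p[i6] / scales[i6])
        assert ratio_ours == pytest.approx(ratio_pywt, rel=0.10)


class TestBandPower:
    def _uniform_spectrum(self):
        grid = FrequencyGrid(1, 45, 0.5)
        power = np.ones((2, len(grid.frequencies)))
        return PowerSpectrum(power=power, grid=grid, labels=["A", "B"])

    def test_uniform_spectrum_relative_proportional_to_band_width(self):
        bp = eb.band_power(self._uniform_spectrum())
        # uniform spectrum: absolute band power = 1 for every band (mean),
        # so relative = 1/5 per band
        np.testing.assert_allclose(bp.relative.values, 0.2)

    def test_pure_alpha_sinusoid_dominates_alpha_band(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.cos(2 * np.pi * 10 * t) + 0.01 * np.sin(2 * np.pi * 3 * t)
        bp = eb.band_power(eb.morlet_power(_epochs_of(x)))
        assert bp.relative.loc["C0", "alpha"] > 0.9

    def test_relative_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        grid = FrequencyGrid(1, 45, 0.5)
        ps = PowerSpectrum(power=rng.random((5, len(grid.frequencies))),
                           grid=grid, labels=list("ABCDE"))
        bp = eb.band_power(ps)
        np.testing.assert_allclose(bp.relative.sum(axis=1), 1.0, atol=1e-6)

    def test_relative_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(1)
        grid = FrequencyGrid(1, 45, 0.5)
        p = rng.random((2, len(grid.frequencies)))
        r1 = eb.band_power(PowerSpectrum(p, grid, ["A", "B"])).relative
        r2 = eb.band_power(PowerSpectrum(7.3 * p, grid, ["A", "B"])).relative
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-12)

    def test_shared_endpoint_belongs_to_upper_band(self):
        f = FrequencyGrid(1, 45, 0.5).frequencies
        assert not CANONICAL_BANDS.mask(f, "delta")[f == 4.0].any()
        assert CANONICAL_BANDS.mask(f, "theta")[f == 4.0].all()
        # gamma is closed at 45
        assert CANONICAL_BANDS.mask(f, "gamma")[f == 45.0].all()


class TestChangeRate:
    def _table(self, values):
        df = pd.DataFrame(values, index=["A"], columns=["delta", "theta"])
        return eb.BandPowerTable(absolute=df, relative=df / df.values.sum())

    def test_identity_gives_zero(self):
        t = self._table([[4.0, 2.0]])
        assert (eb.change_rate(t, t, "absolute").values == 0).all()

    def test_doubling_gives_plus_100(self):
        before = self._table([[4.0, 2.0]])
        after = self._table([[8.0, 4.0]])
        np.testing.assert_allclose(
            eb.change_rate(after, before, "absolute").values, 100.0
        )

    def test_decrease_arithmetic(self):
        before = self._table([[4.0, 4.0]])
        after = self._table([[3.0, 4.0]])
        assert eb.change_rate(after, before, "absolute").loc["A", "delta"] == -25.0

    def test_zero_baseline_flagged_as_nan(self):
        before = self._table([[0.0, 4.0]])
        after = self._table([[3.0, 4.0]])
        out = eb.change_rate(after, before, "absolute")
        assert np.isnan(out.loc["A", "delta"]) and out.loc["A", "theta"] == 0.0
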