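"""Morlet wavelet power spectra and canonical band powers.

Power is estimated per channel on a dense frequency grid (default 1-45 Hz
in 0.5 Hz steps) with a complex Morlet wavelet of central angle frequency
omega = 6 cycles. The wavelet kernel has unit gain at its center frequency,
so the time-averaged quantity reported for a sinusoid of amplitude A is its
mean-square power A^2/2 at every analysis frequency; this makes peak power
directly comparable across frequencies and proportional to amplitude
squared. Band powers average the spectrum over in-band grid points;
relative powers are fractions of the summed five-band absolute power.

Caveat at the low end: a 2-s epoch holds only ~2 cycles at 1 Hz and the
cone-of-influence exclusion there is capped (see ``morlet_power``), so
delta-band estimates from short epochs carry a wide variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochSet, ParameterError

__all__ = [
    "FrequencyGrid",
    "BandScheme",
    "PowerSpectrum",
    "BandPowerTable",
    "CANONICAL_BANDS",
    "morlet_power",
    "band_power",
    "change_rate",
]


@dataclass(frozen=True)
class FrequencyGrid:
    lo: float = 1.0
    hi: float = 45.0
    step: float = 0.5

    def __post_init__(self) -> None:
        if not (self.lo < self.hi and self.step > 0):
            raise ParameterError("need lo < hi and step > 0")

    @property
    def frequencies(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step))
        return self.lo + self.step * np.arange(n + 1)


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands; intervals are [lo, hi) except the last, which
    is closed at the top so a shared endpoint belongs to the upper band."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for (_, _, h1), (_, l2, _) in zip(self.bands, self.bands[1:]):
            if l2 < h1:
                raise ParameterError("bands must not overlap (shared endpoints ok)")

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.bands]

    def mask(self, freqs: np.ndarray, name: str) -> np.ndarray:
        idx = self.names.index(name)
        _, lo, hi = self.bands[idx]
        last = idx == len(self.bands) - 1
        m = (freqs >= lo) & ((freqs <= hi) if last else (freqs < hi))
        if not m.any():
            raise ParameterError(f"band {name} contains no grid point")
        return m


#: delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz
CANONICAL_BANDS = BandScheme(
    (
        ("delta", 1.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("beta", 13.0, 30.0),
        ("gamma", 30.0, 45.0),
    )
)


@dataclass
class PowerSpectrum:
    power: np.ndarray  # (n_channels, n_freqs), uV^2
    grid: FrequencyGrid
    labels: list[str]
    session_tag: str = ""

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ParameterError("power must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.power, index=self.labels, columns=self.grid.frequencies
        )


@dataclass
class BandPowerTable:
    """Absolute (uV^2) and relative band power, channels x bands."""

    absolute: pd.DataFrame
    relative: pd.DataFrame
    session_tag: str = ""

    def to_frame(self) -> pd.DataFrame:
        a = self.absolute.stack().rename("absolute")
        r = self.relative.stack().rename("relative")
        out = pd.concat([a, r], axis=1).reset_index()
        out.columns = ["channel", "band", "absolute", "relative"]
        out.insert(0, "session", self.session_tag)
        return out


def _morlet_kernels(
    freqs: np.ndarray, n_fft: int, fs: float, omega: float
) -> np.ndarray:
    """Frequency-domain Morlet kernels with unit gain at center frequency.

    Kernel k_f(w) = 2 * exp(-(w - 2 pi f)^2 * s^2 / 2) on positive
    frequencies (0 elsewhere), with s = omega / (2 pi f) seconds; the
    factor 2 makes the inverse transform the analytic signal.
    """
    w = 2 * np.pi * np.fft.fftfreq(n_fft, d=1.0 / fs)  # angular, signed
    s = omega / (2 * np.pi * freqs)  # (n_freqs,)
    kern = 2.0 * np.exp(-0.5 * (s[:, None] * (w[None, :] - 2 * np.pi * freqs[:, None])) ** 2)
    kern[:, w < 0] = 0.0
    kern[:, 0] *= 0.5  # DC is its own conjugate bin
    return kern


def morlet_coefficients(
    x: np.ndarray, fs: float, freqs: np.ndarray, omega: float = 6.0
) -> np.ndarray:
    """Complex Morlet coefficients, shape (..., n_freqs, n_samples).

    Computed by FFT convolution with zero-padding to twice the signal
    length so wavelet tails do not wrap around.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    n_fft = 2 * n
    kern = _morlet_kernels(freqs, n_fft, fs, omega)
    xf = np.fft.fft(x, n=n_fft, axis=-1)
    prod = xf[..., None, :] * kern
    return np.fft.ifft(prod, axis=-1)[..., :n]


def _coi_margin(freq: float, fs: float, n: int, omega: float) -> int:
    """Samples to drop at each epoch edge: 2 wavelet time-stds, capped so
    at least two central samples survive (matters at 1 Hz in 2-s epochs)."""
    sigma_t = omega / (2 * np.pi * freq)
    margin = int(round(2 * sigma_t * fs))
    return min(margin, (n - 2) // 2)


def morlet_power(
    epochs: EpochSet, grid: FrequencyGrid | None = None, omega: float = 6.0
) -> PowerSpectrum:
    """Morlet wavelet power spectrum averaged over time and epochs.

    For each channel and grid frequency: squared coefficient magnitude / 2
    (so a sinusoid of amplitude A reports its mean-square power A^2/2),
    time-averaged within each epoch excluding the cone of influence at the
    edges, then averaged across epochs.
    """
    grid = grid if grid is not None else FrequencyGrid()
    nyq = epochs.fs / 2
    if grid.hi >= nyq:
        raise ParameterError(f"grid.hi {grid.hi} Hz must be below Nyquist {nyq} Hz")
    if omega < 5:
        raise ParameterError("omega must be >= 5 for admissibility")
    freqs = grid.frequencies
    n = epochs.samples_per_epoch
    n_fft = 2 * n  # pad so wavelet tails do not wrap around
    n_ch = epochs.epochs.shape[1]
    margins = [_coi_margin(f, epochs.fs, n, omega) for f in freqs]
    power = np.zeros((n_ch, len(freqs)))
    block = 16  # frequencies per block keeps temporaries modest
    for ch in range(n_ch):
        xf = np.fft.fft(epochs.epochs[:, ch, :], n=n_fft, axis=-1)
        for start in range(0, len(freqs), block):
            sel = slice(start, min(start + block, len(freqs)))
            kern = _morlet_kernels(freqs[sel], n_fft, epochs.fs, omega)
            w = np.fft.ifft(xf[:, None, :] * kern, axis=-1)
            for ci, fi in enumerate(range(sel.start, sel.stop)):
                m = margins[fi]
                power[ch, fi] = np.mean(np.abs(w[:, ci, m : n - m]) ** 2) / 2.0
    return PowerSpectrum(
        power=power,
        grid=grid,
        labels=list(epochs.labels),
        session_tag=epochs.session_tag,
    )


def band_power(
    spec: PowerSpectrum, bands: BandScheme | None = None
) -> BandPowerTable:
    """Average the spectrum within each canonical band; normalize.

    ``absolute`` is the mean power over in-band grid points; ``relative``
    divides by the sum of the five absolute band powers, so each channel's
    relative values sum to 1.
    """
    bands = bands if bands is not None else CANONICAL_BANDS
    freqs = spec.grid.frequencies
    cols = {}
    for name in bands.names:
        m = bands.mask(freqs, name)
        cols[name] = spec.power[:, m].mean(axis=1)
    absolute = pd.DataFrame(cols, index=spec.labels)
    total = absolute.sum(axis=1)
    if (total <= 0).any():
        # all-zero channel: relative power undefined, report NaN
        relative = absolute.div(total.replace(0, np.nan), axis=0)
    else:
        relative = absolute.div(total, axis=0)
    return BandPowerTable(absolute=absolute, relative=relative,
                          session_tag=spec.session_tag)


def change_rate(after: BandPowerTable, before: BandPowerTable,
                which: str = "relative") -> pd.DataFrame:
    """Percentage change (After - Before) / Before * 100 per channel/band.

    Cells with a zero baseline are NaN (undefined), never silently dropped.
    """
    a = getattr(after, which)
    b = getattr(before, which)
    if not (a.index.equals(b.index) and a.columns.equals(b.columns)):
        raise ParameterError("after/before tables must share channels and bands")
    denom = b.where(b != 0, np.nan)
    return (a - b) / denom * 100.0
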