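"""Wavelet bicoherence: quadratic phase coupling on a bifrequency grid.

Quadratic phase coupling (QPC) between components at f_j and f_k exists
when the component at f_j + f_k keeps the phase relation
phi(f_j + f_k) = phi(f_j) + phi(f_k). It is measured here with harmonic
(box-spectrum) wavelets: each analysis band is a rectangular frequency-
domain mask of fixed bandwidth (default 2 Hz) centered on a grid frequency
(default 1..45 Hz in 1 Hz steps), inverted to a complex analytic time
series W(f, t) per 2-s epoch. The squared-normalized bicoherence

    b2(f_j, f_k) = |<W_j W_k W*_{j+k}>|^2 / (<|W_j W_k|^2> <|W_{j+k}|^2>)

with <.> pooling time samples and epochs is bounded in [0, 1] by
Cauchy-Schwarz, independent of signal amplitude, and estimated only on the
principal domain f_k <= f_j, f_j + f_k <= hi. A "filtered" variant zeroes
values below a significance threshold derived from phase-randomized
surrogates (or a fixed level). Band-pair totals sum the (optionally
re-squared) values over all grid cells whose frequencies fall in an
ordered pair of canonical bands, symmetrized over the pair order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import EpochSet, ParameterError
from .spectral import BandScheme, CANONICAL_BANDS

__all__ = [
    "BifrequencyGrid",
    "BicoherenceMatrix",
    "harmonic_wavelet_coeffs",
    "wavelet_bicoherence",
    "surrogate_threshold",
    "filter_bicoherence",
    "total_band_coupling",
    "band_pair_table",
]


@dataclass(frozen=True)
class BifrequencyGrid:
    """Center frequencies lo..hi in steps of ``step``, each analyzed with a
    rectangular band of width ``bandwidth``."""

    lo: float = 1.0
    hi: float = 45.0
    step: float = 1.0
    bandwidth: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi and self.step > 0 and self.bandwidth > 0):
            raise ParameterError("invalid bifrequency grid")

    @property
    def frequencies(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step))
        return self.lo + self.step * np.arange(n + 1)


@dataclass
class BicoherenceMatrix:
    """Squared-normalized bicoherence values on the principal domain.

    ``values[j, k]`` corresponds to (f_j, f_k) = (freqs[j], freqs[k]) and
    is NaN outside the principal domain (f_k > f_j or f_j + f_k > hi).
    """

    values: np.ndarray
    grid: BifrequencyGrid
    n_epochs: int
    channel: str = ""
    session_tag: str = ""
    filter_source: str | None = None

    @property
    def domain(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def at(self, f_j: float, f_k: float) -> float:
        freqs = list(self.grid.frequencies)
        return float(self.values[freqs.index(f_j), freqs.index(f_k)])

    def to_frame(self) -> pd.DataFrame:
        freqs = self.grid.frequencies
        jj, kk = np.nonzero(self.domain)
        return pd.DataFrame(
            {
                "f_j": freqs[jj],
                "f_k": freqs[kk],
                "value": self.values[jj, kk],
                "channel": self.channel,
                "session": self.session_tag,
            }
        )


def harmonic_wavelet_coeffs(
    x: np.ndarray, fs: float, grid: BifrequencyGrid | None = None
) -> np.ndarray:
    """Analytic band time series via box-spectrum (harmonic) wavelets.

    For each grid center f, FFT bins in [f - bw/2, f + bw/2) are retained
    (doubled, negative frequencies zeroed) and inverse-transformed, giving
    a complex series whose magnitude tracks the band envelope and whose
    phase tracks the band phase. Shape: (..., n_centers, n_samples).
    """
    grid = grid if grid is not None else BifrequencyGrid()
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    freqs = grid.frequencies
    if freqs[-1] + grid.bandwidth / 2 > fs / 2:
        raise ParameterError("highest band exceeds Nyquist")
    if n / fs < 1.0 / grid.lo:
        raise ParameterError("epoch shorter than one cycle of the lowest band")
    fft_f = np.fft.fftfreq(n, d=1.0 / fs)
    xf = np.fft.fft(x, axis=-1)
    masks = np.zeros((len(freqs), n))
    for i, f in enumerate(freqs):
        m = (fft_f >= f - grid.bandwidth / 2) & (fft_f < f + grid.bandwidth / 2)
        masks[i, m] = 2.0
    return np.fft.ifft(xf[..., None, :] * masks, axis=-1)


def _sum_indices(grid: BifrequencyGrid) -> tuple[np.ndarray, np.ndarray]:
    """Principal-domain mask and the grid index of f_j + f_k per cell."""
    freqs = grid.frequencies
    n = len(freqs)
    jj, kk = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    fsum = freqs[jj] + freqs[kk]
    sidx = np.round((fsum - grid.lo) / grid.step).astype(int)
    on_grid = np.abs(grid.lo + sidx * grid.step - fsum) < 1e-9
    domain = (kk <= jj) & (fsum <= grid.hi + 1e-9) & on_grid & (sidx < n)
    return domain, sidx


def wavelet_bicoherence(
    epochs: EpochSet,
    channel: str,
    grid: BifrequencyGrid | None = None,
    _block: int = 64,
) -> BicoherenceMatrix:
    """Squared-normalized wavelet bicoherence for one channel.

    Time samples within epochs and all epochs are pooled into a single
    average for both the numerator and the normalization, which maximizes
    estimator stability for long sessions. Requires >= 2 epochs (with one
    epoch the normalization is degenerate).
    """
    grid = grid if grid is not None else BifrequencyGrid()
    if epochs.n_epochs < 2:
        raise ParameterError("bicoherence needs at least 2 epochs")
    sig = epochs.channel(channel)  # (n_epochs, n_samples)
    domain, sidx = _sum_indices(grid)
    n_f = len(grid.frequencies)
    num = np.zeros((n_f, n_f), dtype=complex)
    d1 = np.zeros((n_f, n_f))
    d2 = np.zeros(n_f)
    for start in range(0, epochs.n_epochs, _block):
        w = harmonic_wavelet_coeffs(sig[start : start + _block], epochs.fs, grid)
        d2 += np.sum(np.abs(w) ** 2, axis=(0, 2))
        for j in range(n_f):
            ks = np.nonzero(domain[j])[0]
            if ks.size == 0:
                continue
            prod = w[:, ks, :] * w[:, j, None, :]
            conj_sum = np.conj(w[:, sidx[j, ks], :])
            num[j, ks] += np.sum(prod * conj_sum, axis=(0, 2))
            d1[j, ks] += np.sum(np.abs(prod) ** 2, axis=(0, 2))
    values = np.full((n_f, n_f), np.nan)
    jj, kk = np.nonzero(domain)
    denom = d1[jj, kk] * d2[sidx[jj, kk]]
    with np.errstate(invalid="ignore", divide="ignore"):
        b2 = np.abs(num[jj, kk]) ** 2 / denom
    b2 = np.where(denom > 0, b2, 0.0)
    values[jj, kk] = np.clip(b2, 0.0, 1.0)
    return BicoherenceMatrix(
        values=values,
        grid=grid,
        n_epochs=epochs.n_epochs,
        channel=channel,
        session_tag=epochs.session_tag,
    )


def surrogate_threshold(
    epochs: EpochSet,
    channel: str,
    grid: BifrequencyGrid | None = None,
    n_surrogates: int = 40,
    alpha: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell significance threshold from phase-randomized surrogates.

    The channel's continuous signal is reconstructed from the (contiguous,
    overlapping) epochs, its Fourier phases are randomized independently
    within each non-overlapping epoch-length block (preserving block
    amplitude spectra, destroying phase coupling — including that of
    stationary sinusoid triplets, whose bicoherence would survive a single
    whole-signal randomization), and the surrogate is re-epoched with the
    original overlap so the surrogate null carries the same
    overlap-induced estimator variance as the data. Returns the
    (1 - alpha) quantile per grid cell (NaN outside the principal domain).

    Falls back to per-epoch randomization when the epochs are not
    contiguous slices of one signal (e.g. after epoch rejection); that
    null is anti-conservative under heavy overlap.
    """
    from .preprocess import make_epochs, Recording

    grid = grid if grid is not None else BifrequencyGrid()
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie in (0, 1)")
    if n_surrogates < 1:
        raise ParameterError("need at least one surrogate")
    rng = np.random.default_rng(seed)
    sig = epochs.channel(channel)
    n = sig.shape[1]
    step = int(round(n * (1 - epochs.overlap)))

    # try to reconstruct the continuous signal from contiguous epochs
    contiguous = step >= 1
    if contiguous and epochs.n_epochs > 1:
        contiguous = all(
            np.array_equal(sig[i, step:], sig[i + 1, : n - step])
            for i in range(epochs.n_epochs - 1)
        )
    full = None
    if contiguous:
        full = np.concatenate([sig[0]] + [sig[i][n - step :] for i in range(1, epochs.n_epochs)])

    def _randomize_blocks(x: np.ndarray) -> np.ndarray:
        blocks = x.reshape(-1, n) if x.size % n == 0 else None
        if blocks is None:
            pad = (-x.size) % n
            blocks = np.concatenate([x, np.zeros(pad)]).reshape(-1, n)
        xf = np.fft.rfft(blocks, axis=1)
        ph = np.exp(2j * np.pi * rng.random(xf.shape))
        ph[:, 0] = 1.0
        if n % 2 == 0:
            ph[:, -1] = 1.0
        out = np.fft.irfft(xf * ph, n=n, axis=1).ravel()
        return out[: x.size]

    stack = []
    for _ in range(n_surrogates):
        if full is not None:
            surr_sig = _randomize_blocks(full)
            rec = Recording(data=surr_sig[None, :], fs=epochs.fs, labels=[channel])
            sur_ep = make_epochs(rec, epochs.epoch_length, epochs.overlap)
        else:
            surr = np.stack([_randomize_blocks(sig[i]) for i in range(epochs.n_epochs)])
            sur_ep = replace(epochs, epochs=surr[:, None, :], labels=[channel])
        stack.append(wavelet_bicoherence(sur_ep, channel, grid).values)
    arr = np.stack(stack)
    domain, _ = _sum_indices(grid)
    thr = np.full(arr.shape[1:], np.nan)
    thr[domain] = np.quantile(arr[:, domain], 1 - alpha, axis=0)
    return thr


def filter_bicoherence(
    bic: BicoherenceMatrix,
    threshold: float | np.ndarray,
    source: str | None = None,
) -> BicoherenceMatrix:
    """Zero out bicoherence values below a significance threshold (FIWBIC).

    ``threshold`` is a fixed level in [0, 1] or a per-cell array (e.g. from
    ``surrogate_threshold``); the threshold source is recorded on the
    output.
    """
    if np.isscalar(threshold):
        if not (0 <= threshold <= 1):
            raise ParameterError("scalar threshold must lie in [0, 1]")
        thr = float(threshold)
        src = source or f"fixed threshold {thr}"
    else:
        thr = np.asarray(threshold, dtype=float)
        if thr.shape != bic.values.shape:
            raise ParameterError("threshold array shape mismatch")
        src = source or "per-cell surrogate threshold"
    with np.errstate(invalid="ignore"):
        filtered = np.where(bic.values >= thr, bic.values, 0.0)
    filtered[~bic.domain] = np.nan
    return replace(bic, values=filtered, filter_source=src)


def total_band_coupling(
    bic: BicoherenceMatrix,
    band_j: str,
    band_k: str,
    bands: BandScheme | None = None,
    square: bool = False,
) -> float:
    """Total coupling between two canonical bands: sum over grid cells.

    Sums bicoherence over principal-domain cells whose frequencies fall in
    the (symmetrized) band pair; cells with f_j + f_k above the grid cap
    are simply not part of the domain (their exclusion is inherent to the
    truncated grid). With ``square=False`` (default) the stored
    squared-normalized values are summed as-is; ``square=True`` squares
    them first, for the reading in which stored values are magnitudes.
    Returns NaN when the pair has no valid grid cell (e.g. gamma-gamma
    under a 45 Hz cap) — a sentinel distinct from a true zero coupling.
    """
    bands = bands if bands is not None else CANONICAL_BANDS
    freqs = bic.grid.frequencies
    mj = bands.mask(freqs, band_j)
    mk = bands.mask(freqs, band_k)
    pair = (mj[:, None] & mk[None, :]) | (mk[:, None] & mj[None, :])
    cells = pair & bic.domain
    if not cells.any():
        return float("nan")
    vals = bic.values[cells]
    return float(np.sum(vals**2 if square else vals))


def band_pair_table(
    bic: BicoherenceMatrix,
    bands: BandScheme | None = None,
    square: bool = False,
) -> pd.DataFrame:
    """Total coupling for every unordered band pair (including self-pairs)."""
    bands = bands if bands is not None else CANONICAL_BANDS
    rows = []
    names = bands.names
    for i, bj in enumerate(names):
        for bk in names[: i + 1]:
            rows.append(
                {
                    "band_j": bj,
                    "band_k": bk,
                    "coupling": total_band_coupling(bic, bj, bk, bands, square),
                    "channel": bic.channel,
                    "session": bic.session_tag,
                }
            )
    return pd.DataFrame(rows)
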