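"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: direct-FFT
bicoherence with plain segmentation, a periodogram slope fit, and
brute-force enumeration for rank tests.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def fft_bicoherence(x: np.ndarray, fs: float, f1: float, f2: float,
                    seg_seconds: float = 2.0) -> float:
    """Squared bicoherence at (f1, f2) from non-overlapping FFT segments.

    b2 = |sum_m X(f1) X(f2) X*(f1+f2)|^2
         / (sum_m |X(f1) X(f2)|^2 * sum_m |X(f1+f2)|^2)
    """
    seg = int(round(seg_seconds * fs))
    n_seg = len(x) // seg
    segs = x[: n_seg * seg].reshape(n_seg, seg)
    segs = segs - segs.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(segs, axis=1)
    freqs = np.fft.rfftfreq(seg, d=1.0 / fs)

    def bin_of(f: float) -> int:
        return int(np.argmin(np.abs(freqs - f)))

    x1 = spec[:, bin_of(f1)]
    x2 = spec[:, bin_of(f2)]
    x3 = spec[:, bin_of(f1 + f2)]
    num = np.abs(np.sum(x1 * x2 * np.conj(x3))) ** 2
    den = np.sum(np.abs(x1 * x2) ** 2) * np.sum(np.abs(x3) ** 2)
    return float(num / den)


def loglog_psd_slope(x: np.ndarray, fs: float, f_lo: float = 2.0,
                     f_hi: float = 40.0) -> float:
    """Least-squares slope of log10(PSD) vs log10(f) from a periodogram."""
    from scipy.signal import welch

    f, p = welch(x, fs=fs, nperseg=min(len(x), 8192))
    m = (f >= f_lo) & (f <= f_hi)
    return float(np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0])


def exact_ranksum_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating all assignments of ranks.

    Assumes no ties. p = P(|W - E[W]| >= |w_obs - E[W]|) over all
    C(n1+n2, n1) equally likely rank assignments to the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == pooled.size, "oracle assumes no ties"
    ranks = np.argsort(np.argsort(pooled)) + 1
    w_obs = ranks[: x.size].sum()
    n = pooled.size
    e_w = x.size * (n + 1) / 2.0
    count = total = 0
    for comb in combinations(range(1, n + 1), x.size):
        total += 1
        if abs(sum(comb) - e_w) >= abs(w_obs - e_w) - 1e-12:
            count += 1
    return count / total
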