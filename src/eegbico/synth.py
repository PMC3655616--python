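"""Synthetic EEG and behavioral data with known ground truth.

Every downstream stage of the package is exercised on recordings built
here: 1/f background (spectrally shaped white noise), band-limited
oscillatory components (narrow-band filtered noise) whose per-channel RMS
is set exactly, and quadratically phase-coupled sinusoid triplets whose
coupling strength is the fraction of 2-s segments on which the sum
component's phase is locked to phi1 + phi2. Behavioral up-down staircase
sequences come from a logistic responder with a known true threshold.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .preprocess import ParameterError, Recording
from .behavior import FilamentLadder, UpDownSequence, CHAPLAN_LADDER

__all__ = [
    "SynthSpec",
    "Responder",
    "generate_background",
    "inject_oscillation",
    "inject_qpc_triplet",
    "build_recording",
    "simulate_updown",
    "DEFAULT_LABELS",
]

# 12 scalp electrodes of the rat epidural montage plus reference/ground rows
DEFAULT_LABELS = [
    "FL1", "FR1", "FL2", "FR2", "PL1", "PR1",
    "PL2", "PR2", "LFL", "RFR", "LPL", "RPR", "REF", "GND",
]


@dataclass
class SynthSpec:
    """Parameters of a synthetic EEG session.

    Defaults emulate the recording conditions the pipeline targets:
    14 channels digitized at 256 Hz over a 25-minute session, with a 1/f
    background. ``band_components`` entries are
    (center_hz, bandwidth_hz, rms_uv, channel_indices_or_None);
    ``qpc_triplets`` entries are (f1_hz, f2_hz, coupling_strength, amp_uv).
    """

    n_channels: int = 14
    fs: float = 256.0
    duration: float = 1500.0
    background_slope: float = 1.0
    background_rms: float = 10.0
    band_components: list[tuple] = field(default_factory=list)
    qpc_triplets: list[tuple] = field(default_factory=list)
    seed: int = 0
    labels: list[str] | None = None
    session_tag: str = ""

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ParameterError("need at least one channel")
        if self.fs <= 0 or self.duration <= 0:
            raise ParameterError("fs and duration must be positive")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-6:
            raise ParameterError("duration * fs must be an integer sample count")
        for f1, f2, strength, _amp in self.qpc_triplets:
            if not (0 <= strength <= 1):
                raise ParameterError("coupling strength must lie in [0, 1]")
            if f1 + f2 >= self.fs / 2:
                raise ParameterError("triplet sum frequency at or above Nyquist")
        for center, bw, _rms, _ch in self.band_components:
            if not (0 < center - bw / 2 and center + bw / 2 < self.fs / 2):
                raise ParameterError("band component outside (0, Nyquist)")
        if self.labels is None:
            if self.n_channels <= len(DEFAULT_LABELS):
                self.labels = DEFAULT_LABELS[: self.n_channels]
            else:
                self.labels = [f"CH{i}" for i in range(self.n_channels)]

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class Responder:
    """Stochastic withdrawal responder with a logistic psychometric curve.

    P(withdraw | force F) = expit(slope * (log10 F - log10 true_threshold)).
    ``slope`` is per log10-gram; ``slope=inf`` gives the deterministic step
    responder (withdraw iff F >= true_threshold).
    """

    true_threshold: float
    slope: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_threshold <= 0:
            raise ParameterError("true threshold must be positive (grams)")
        if not (self.slope > 0):
            raise ParameterError("slope must be positive (inf = deterministic)")

    @property
    def deterministic(self) -> bool:
        return np.isinf(self.slope)

    def p_withdraw(self, force_g: float) -> float:
        if self.deterministic:
            return 1.0 if force_g >= self.true_threshold else 0.0
        from scipy.special import expit

        return float(
            expit(self.slope * (np.log10(force_g) - np.log10(self.true_threshold)))
        )


def generate_background(spec: SynthSpec) -> Recording:
    """1/f^slope background noise via FFT-domain spectral shaping.

    White Gaussian noise per channel is scaled in the frequency domain by
    f^(-slope/2) (so power falls as f^-slope) and renormalized to
    ``background_rms`` per channel. slope=0 reduces to white noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    white = rng.standard_normal((spec.n_channels, n))
    if spec.background_slope == 0:
        data = white
    else:
        spec_f = np.fft.rfft(white, axis=1)
        freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
        scale = np.ones_like(freqs)
        nz = freqs > 0
        scale[nz] = freqs[nz] ** (-spec.background_slope / 2.0)
        scale[0] = 0.0  # no DC
        data = np.fft.irfft(spec_f * scale, n=n, axis=1)
    rms = np.sqrt(np.mean(data**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    data = data / rms * spec.background_rms
    return Recording(
        data=data, fs=spec.fs, labels=list(spec.labels), session_tag=spec.session_tag
    )


def inject_oscillation(
    rec: Recording,
    center: float,
    bandwidth: float,
    rms: float,
    channels: list[int] | None = None,
    seed: int = 0,
) -> Recording:
    """Add a band-limited oscillatory component of exact RMS.

    The component is white noise band-passed to center +/- bandwidth/2
    (4th-order zero-phase Butterworth) and rescaled to the requested RMS,
    added only on the listed channel indices (all channels if None).
    Untouched channels are bit-identical to the input.
    """
    if not (0 < center - bandwidth / 2 and center + bandwidth / 2 < rec.fs / 2):
        raise ParameterError(
            f"band {center}+/-{bandwidth / 2} Hz outside (0, {rec.fs / 2}) Hz"
        )
    if rms < 0:
        raise ParameterError("rms must be nonnegative")
    out = rec.copy()
    if rms == 0:
        return out
    if channels is None:
        channels = list(range(rec.n_channels))
    rng = np.random.default_rng(seed)
    sos = signal.butter(
        4,
        [center - bandwidth / 2, center + bandwidth / 2],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    for ch in channels:
        comp = signal.sosfiltfilt(sos, rng.standard_normal(rec.n_samples))
        comp *= rms / np.sqrt(np.mean(comp**2))
        out.data[ch] += comp
    return out


def inject_qpc_triplet(
    rec: Recording,
    f1: float,
    f2: float,
    strength: float,
    amp: float,
    channels: list[int] | None = None,
    seed: int = 0,
    segment_length: float = 2.0,
) -> Recording:
    """Add a quadratically phase-coupled sinusoid triplet at f1, f2, f1+f2.

    The f1 and f2 components have fixed random phases phi1, phi2. The sum
    component's phase is phi1 + phi2 on a fraction ``strength`` of the
    ``segment_length``-second segments and independently random per segment
    on the rest. The locked segments form one contiguous coupled episode at
    a random position: round(strength * n_segments) segments long, so the
    time-pooled bicoherence magnitude approaches ``strength`` (squared
    value ~ strength^2) without the phase discontinuities that scattered
    locking would introduce at nearly every segment boundary.
    """
    if not (0 <= strength <= 1):
        raise ParameterError("strength must lie in [0, 1]")
    if f1 + f2 >= rec.fs / 2:
        raise ParameterError(
            f"sum frequency {f1 + f2} Hz at or above Nyquist {rec.fs / 2} Hz"
        )
    if amp < 0:
        raise ParameterError("amp must be nonnegative")
    out = rec.copy()
    if amp == 0:
        return out
    if channels is None:
        channels = list(range(rec.n_channels))
    rng = np.random.default_rng(seed)
    t = np.arange(rec.n_samples) / rec.fs
    f3 = f1 + f2
    seg = int(round(segment_length * rec.fs))
    n_seg = int(np.ceil(rec.n_samples / seg))
    for ch in channels:
        phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
        x = amp * (np.cos(2 * np.pi * f1 * t + phi1) + np.cos(2 * np.pi * f2 * t + phi2))
        n_locked = int(round(strength * n_seg))
        locked = np.zeros(n_seg, dtype=bool)
        if n_locked > 0:
            start = int(rng.integers(0, n_seg - n_locked + 1))
            locked[start : start + n_locked] = True
        phases = np.where(locked, phi1 + phi2, rng.uniform(0, 2 * np.pi, size=n_seg))
        phi3 = np.repeat(phases, seg)[: rec.n_samples]
        x += amp * np.cos(2 * np.pi * f3 * t + phi3)
        out.data[ch] += x
    return out


def build_recording(spec: SynthSpec) -> Recording:
    """Background plus all band components and QPC triplets of the spec.

    Component seeds are derived from ``spec.seed`` via ``SeedSequence`` so
    the whole recording is reproducible from the spec alone.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_comp = len(spec.band_components) + len(spec.qpc_triplets)
    children = ss.spawn(n_comp + 1)
    rec = generate_background(replace(spec, seed=children[0].generate_state(1)[0] % 2**31))
    k = 1
    for center, bw, rms, channels in spec.band_components:
        rec = inject_oscillation(
            rec, center, bw, rms, channels,
            seed=children[k].generate_state(1)[0] % 2**31,
        )
        k += 1
    for f1, f2, strength, amp in spec.qpc_triplets:
        rec = inject_qpc_triplet(
            rec, f1, f2, strength, amp,
            seed=children[k].generate_state(1)[0] % 2**31,
        )
        k += 1
    return rec


def simulate_updown(
    responder: Responder,
    filaments: FilamentLadder | None = None,
    start_force: float = 2.00,
    max_post_change_trials: int = 6,
    max_trials: int = 30,
) -> UpDownSequence:
    """Simulate one up-down staircase against a responder.

    A positive response (withdrawal) moves to the next weaker filament, a
    negative one to the next stronger; at a ladder boundary the boundary
    filament is repeated. The staircase terminates
    ``max_post_change_trials`` stimuli after the first change in response;
    if no change occurs within ``max_trials`` the sequence ends saturated
    (all-positive or all-negative) and is flagged unterminated.
    """
    ladder = filaments if filaments is not None else CHAPLAN_LADDER
    forces = list(ladder.forces)
    if not forces:
        raise ParameterError("filament ladder is empty")
    try:
        idx = forces.index(start_force)
    except ValueError:
        raise ParameterError(f"start force {start_force} g not in ladder") from None
    rng = np.random.default_rng(responder.seed)
    trials: list[tuple[float, int]] = []
    first_change: int | None = None
    while len(trials) < max_trials:
        force = forces[idx]
        resp = int(rng.random() < responder.p_withdraw(force))
        trials.append((force, resp))
        i = len(trials) - 1
        if first_change is None and i >= 1 and trials[i][1] != trials[i - 1][1]:
            first_change = i
        if first_change is not None and i >= first_change + max_post_change_trials:
            break
        idx = max(idx - 1, 0) if resp else min(idx + 1, len(forces) - 1)
    return UpDownSequence(
        trials=trials,
        first_change_index=first_change,
        terminated=first_change is not None
        and len(trials) == first_change + max_post_change_trials + 1,
    )
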