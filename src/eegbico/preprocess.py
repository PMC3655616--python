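"""Signal conditioning for multichannel EEG recordings.

The pipeline order is fixed: band-pass filter -> average rereference ->
channel rejection -> (optional epoch-level artifact rejection) -> epoching.
Filtering is zero-phase so that phase relationships, on which bicoherence
depends, are not distorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "EpochSet",
    "RejectionReport",
    "bandpass",
    "rereference_average",
    "reject_channels",
    "reject_epochs",
    "make_epochs",
    "resample",
]


class ParameterError(ValueError):
    """Raised when an operation is called with invalid parameters."""


@dataclass
class Recording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes in microvolts.
    fs : float
        Sampling rate in samples per second.
    labels : list of str
        Unique channel names, one per row of ``data``.
    montage : dict, optional
        Mapping label -> (anterior_mm, lateral_mm) planar coordinates.
    session_tag : str
        Free-text session label, e.g. ``before_incision``.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    montage: dict[str, tuple[float, float]] | None = None
    session_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be a (channels, samples) matrix")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ParameterError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())


@dataclass
class EpochSet:
    """Fixed-length, possibly overlapping epochs cut from a recording.

    ``epochs`` has shape (n_epochs, n_channels, samples_per_epoch); epoch
    boundaries are half-open sample intervals [start, start + L) with
    integer step L * (1 - overlap).
    """

    epochs: np.ndarray
    fs: float
    labels: list[str]
    epoch_length: float
    overlap: float
    session_tag: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ParameterError("epochs must be (epoch, channel, sample)")
        if not (0 <= self.overlap < 1):
            raise ParameterError("overlap must lie in [0, 1)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]

    def channel(self, label: str) -> np.ndarray:
        """Epoch matrix (n_epochs, samples) for one channel label."""
        return self.epochs[:, self.labels.index(label), :]


@dataclass
class RejectionReport:
    """Which channels were removed and why."""

    removed: dict[str, str] = field(default_factory=dict)
    amp_limit: float = np.inf
    flat_limit: float = 0.0

    def __bool__(self) -> bool:
        return bool(self.removed)


def _design_bandpass(lo: float, hi: float, fs: float) -> np.ndarray:
    """Zero-phase-ready elliptic band-pass in second-order sections.

    Sized so that after forward-backward filtering the passband deviation
    inside [lo+1, hi-1] stays under 1 dB while 50 Hz (for hi = 45) sits in
    the stopband with at least 20 dB attenuation, and DC is suppressed far
    enough that a 100 uV offset leaves a sub-microvolt mean.
    """
    nyq = fs / 2.0
    wp = [lo / nyq, hi / nyq]
    # stopband corners: well below lo, and ~11% above hi (50 Hz when hi=45)
    ws = [max(lo * 0.3, 0.01) / nyq, min(hi * 50.0 / 45.0, nyq * 0.999) / nyq]
    order, wn = signal.ellipord(wp, ws, gpass=0.2, gstop=25.0)
    return signal.ellip(order, 0.2, 25.0, wn, btype="bandpass", output="sos")


def bandpass(rec: Recording, lo: float = 1.0, hi: float = 45.0) -> Recording:
    """Zero-phase band-pass filter, default 1-45 Hz.

    The upper edge excludes mains interference at 50 Hz. Filtering is
    forward-backward (``sosfiltfilt``), so the net phase response is zero.
    """
    if not (0 < lo < hi < rec.fs / 2):
        raise ParameterError(
            f"band ({lo}, {hi}) Hz invalid for fs={rec.fs} (Nyquist {rec.fs / 2})"
        )
    sos = _design_bandpass(lo, hi, rec.fs)
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def rereference_average(
    rec: Recording, excluded: set[str] | None = None
) -> Recording:
    """Rereference to the average of retained channels.

    Excluded channels contribute nothing to the mean and are dropped from
    the output. After rereferencing, the retained channels sum to zero at
    every sample, and the operation is idempotent.
    """
    excluded = set(excluded or ())
    unknown = excluded - set(rec.labels)
    if unknown:
        raise ParameterError(f"excluded labels not in recording: {sorted(unknown)}")
    keep = [i for i, lab in enumerate(rec.labels) if lab not in excluded]
    if len(keep) < 2:
        raise ParameterError("average reference needs at least 2 retained channels")
    data = rec.data[keep]
    data = data - data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, labels=[rec.labels[i] for i in keep])


def reject_channels(
    rec: Recording, amp_limit: float = 1000.0, flat_limit: float = 0.01
) -> tuple[Recording, RejectionReport]:
    """Drop channels with excessive or vanishing peak-to-peak amplitude.

    This is an offline stand-in for acquisition-time quality checks
    (electrode impedance): a channel whose peak-to-peak amplitude exceeds
    ``amp_limit`` uV is treated as artifactual, one below ``flat_limit`` uV
    as disconnected/flat.
    """
    if amp_limit <= 0 or flat_limit <= 0:
        raise ParameterError("amplitude limits must be positive")
    ptp = rec.data.max(axis=1) - rec.data.min(axis=1)
    report = RejectionReport(amp_limit=amp_limit, flat_limit=flat_limit)
    keep = []
    for i, lab in enumerate(rec.labels):
        if ptp[i] > amp_limit:
            report.removed[lab] = f"peak-to-peak {ptp[i]:.1f} uV > {amp_limit} uV"
        elif ptp[i] < flat_limit:
            report.removed[lab] = f"peak-to-peak {ptp[i]:.3g} uV < {flat_limit} uV (flat)"
        else:
            keep.append(i)
    if not keep:
        raise ParameterError(
            f"all channels rejected (amp_limit={amp_limit} uV, flat_limit={flat_limit} uV)"
        )
    out = replace(rec, data=rec.data[keep], labels=[rec.labels[i] for i in keep])
    return out, report


def make_epochs(
    rec: Recording, length: float = 2.0, overlap: float = 0.75
) -> EpochSet:
    """Cut the recording into fixed-length epochs with fractional overlap.

    With N samples, epoch length L = length * fs samples and step
    L * (1 - overlap), the epoch count is floor((N - L) / step) + 1.
    Samples are copied, never aliased.
    """
    if not (0 <= overlap < 1):
        raise ParameterError("overlap must lie in [0, 1)")
    L = length * rec.fs
    if abs(L - round(L)) > 1e-9:
        raise ParameterError(f"epoch length {length}s is not an integer sample count at fs={rec.fs}")
    L = int(round(L))
    if rec.n_samples < L:
        raise ParameterError("recording shorter than one epoch")
    step = int(round(L * (1 - overlap)))
    if step < 1:
        raise ParameterError("overlap too high: epoch step below one sample")
    n_ep = (rec.n_samples - L) // step + 1
    starts = np.arange(n_ep) * step
    epochs = np.stack([rec.data[:, s : s + L] for s in starts]).copy()
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        labels=list(rec.labels),
        epoch_length=length,
        overlap=overlap,
        session_tag=rec.session_tag,
    )


def reject_epochs(epochs: EpochSet, ptp_factor: float = 6.0) -> tuple[EpochSet, np.ndarray]:
    """Drop epochs contaminated by movement artifact or baseline drift.

    An epoch is rejected when its maximum peak-to-peak amplitude across
    channels exceeds ``ptp_factor`` times the median of that quantity over
    all epochs. Returns the cleaned set and a boolean keep-mask.
    """
    if ptp_factor <= 0:
        raise ParameterError("ptp_factor must be positive")
    ptp = (epochs.epochs.max(axis=2) - epochs.epochs.min(axis=2)).max(axis=1)
    med = np.median(ptp)
    keep = ptp <= ptp_factor * med
    if not keep.any():
        raise ParameterError("all epochs rejected; check ptp_factor")
    out = replace(epochs, epochs=epochs.epochs[keep])
    return out, keep


def resample(rec: Recording, fs_target: float) -> Recording:
    """Polyphase-resample a recording to the analysis rate (default 256 Hz)."""
    if fs_target <= 0:
        raise ParameterError("target rate must be positive")
    if abs(fs_target - rec.fs) < 1e-9:
        return rec.copy()
    from fractions import Fraction

    frac = Fraction(fs_target / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=data, fs=fs_target)
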