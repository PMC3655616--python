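"""File formats: EDF, delimited matrices, montages, behavioral tables,
and the flat key-value configuration format.

EDF is the interchange recording format. Reading goes through MNE's EDF
reader; writing uses a minimal 16-bit EDF writer implemented here (header
per the EDF specification, one 1-second data record per block), sufficient
for round-tripping analysis recordings. Delimited matrices (one row per
channel) are accepted everywhere a recording is, for small fixtures.
"""

from __future__ import annotations

import datetime as _dt
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import UpDownSequence
from .preprocess import ParameterError, Recording
from .topo import Montage

__all__ = [
    "write_edf",
    "read_edf",
    "write_matrix",
    "read_matrix",
    "read_montage",
    "write_updown",
    "read_updown",
    "read_config",
    "write_config",
]


def write_edf(path: str | Path, rec: Recording) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    The recording is zero-padded to a whole number of seconds. Each channel
    is scaled to its own physical min/max, so quantization error is at most
    peak amplitude / 2^15.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((rec.n_channels, n_rec * fs))
    data[:, : rec.n_samples] = rec.data
    ns = rec.n_channels

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad(rec.session_tag or "eegbico recording", 80),
            pad(now.strftime("%d.%m.%y"), 8),
            pad(now.strftime("%H.%M.%S"), 8),
            pad(str(256 + ns * 256), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),  # record duration, seconds
            pad(str(ns), 4),
        ]
    )
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    fields = []
    for getter, width in [
        (lambda i: rec.labels[i], 16),
        (lambda i: "EEG", 80),
        (lambda i: "uV", 8),
        (lambda i: f"{phys_min[i]:.6g}", 8),
        (lambda i: f"{phys_max[i]:.6g}", 8),
        (lambda i: "-32768", 8),
        (lambda i: "32767", 8),
        (lambda i: "", 80),
        (lambda i: str(fs), 8),
        (lambda i: "", 32),
    ]:
        fields.append(b"".join(pad(getter(i), width) for i in range(ns)))
    header += b"".join(fields)
    # parse back the printed physical limits so scaling matches the header
    pmin = np.array([float(f"{v:.6g}") for v in phys_min])
    pmax = np.array([float(f"{v:.6g}") for v in phys_max])
    scale = (pmax - pmin) / (32767.0 - (-32768.0))
    digital = np.clip(
        np.round((data - pmin[:, None]) / scale[:, None] + (-32768.0)),
        -32768, 32767,
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(struct.pack(f"<{ns * fs}h", *block.ravel()))


def read_edf(path: str | Path, session_tag: str = "") -> Recording:
    """Read an EDF recording via MNE (amplitudes returned in microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    return Recording(
        data=data, fs=float(raw.info["sfreq"]), labels=list(raw.ch_names),
        session_tag=session_tag,
    )


def write_matrix(path: str | Path, rec: Recording, sep: str = "\t") -> None:
    """Write a recording as a delimited matrix, one row per channel.

    The first column holds the channel label; a ``# fs=<rate>`` comment
    line carries the sampling rate.
    """
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        for lab, row in zip(rec.labels, rec.data):
            fh.write(sep.join([lab] + [f"{v:.9g}" for v in row]) + "\n")


def read_matrix(path: str | Path, fs: float | None = None, sep: str = "\t",
                session_tag: str = "") -> Recording:
    """Read a delimited channels-x-samples matrix written by ``write_matrix``."""
    labels, rows = [], []
    header_fs = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "fs=" in line:
                    header_fs = float(line.split("fs=")[1].split()[0])
                continue
            parts = line.split(sep)
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    fs = fs if fs is not None else header_fs
    if fs is None:
        raise ParameterError("sampling rate not in file header; pass fs=")
    return Recording(data=np.array(rows), fs=fs, labels=labels,
                     session_tag=session_tag)


def read_montage(path: str | Path, sep: str = "\t") -> Montage:
    """Read a 3-column montage table (label, anterior_mm, lateral_mm)."""
    df = pd.read_csv(path, sep=sep, comment="#")
    required = {"label", "anterior_mm", "lateral_mm"}
    if not required <= set(df.columns):
        raise ParameterError(f"montage file needs columns {sorted(required)}")
    return Montage.from_table(df)


def write_updown(path: str | Path, seq: UpDownSequence, sep: str = "\t") -> None:
    """Write an up-down sequence as a two-column (force_g, response) table."""
    seq.to_frame().to_csv(path, sep=sep, index=False)


def read_updown(path: str | Path, sep: str = "\t") -> UpDownSequence:
    df = pd.read_csv(path, sep=sep)
    if not {"force_g", "response"} <= set(df.columns):
        raise ParameterError("sequence file needs columns force_g, response")
    trials = [(float(f), int(r)) for f, r in zip(df["force_g"], df["response"])]
    return UpDownSequence(trials=trials)


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` configuration file.

    Lines starting with ``#`` and blank lines are ignored; values are
    returned as strings (typed by the consumer).
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParameterError(f"{path}:{ln}: expected 'key = value'")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def write_config(path: str | Path, values: dict) -> None:
    with open(path, "w") as fh:
        for k, v in values.items():
            fh.write(f"{k} = {v}\n")
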