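"""Reading, validation and segmentation of multichannel EEG recordings.

The reference acquisition setup is a 14-channel consumer headset sampled at
128 Hz with a hardware bandwidth of 0.2-43 Hz; recordings are labeled with
one of three mental states (focused, unfocused, drowsy) and analysed in
30 s non-overlapping windows of 3840 samples.  Nothing in this module is
tied to those numbers: any channel count, sampling rate and window length
is accepted.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, filtfilt

STATES = ("focused", "unfocused", "drowsy")


class ValidationError(ValueError):
    """Raised when a recording violates a structural invariant."""


@dataclass
class Recording:
    """A labeled multichannel EEG block.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts, one row per channel.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Ordered channel labels (file order; no re-referencing is applied).
    subject_id, session_id : str
        Provenance identifiers.
    state : str or None
        One of ``focused``, ``unfocused``, ``drowsy``, or None if unlabeled.
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    subject_id: str = ""
    session_id: str = ""
    state: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim == 1:
            self.signal = self.signal[None, :]
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a channels x samples matrix")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        bad = ~np.isfinite(self.signal)
        if bad.any():
            ch, idx = np.argwhere(bad)[0]
            name = self.channel_names[ch] if self.channel_names else f"channel {ch}"
            raise ValidationError(
                f"non-finite value in {name} (row {ch}, sample {idx})"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )
        if self.state is not None and self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}; expected {STATES}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs


@dataclass
class Segment:
    """One fixed-length window cut from a Recording."""

    signal: np.ndarray
    fs: float
    subject_id: str = ""
    session_id: str = ""
    state: str | None = None
    window_index: int = 0

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class SegmentSet:
    """Segments with aligned class labels and provenance."""

    segments: list[Segment]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.labels):
            raise ValidationError("labels must align 1:1 with segments")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def fs(self) -> float:
        return self.segments[0].fs

    @property
    def n_channels(self) -> int:
        return self.segments[0].n_channels

    def provenance(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [s.subject_id for s in self.segments],
                "session": [s.session_id for s in self.segments],
                "state": self.labels,
                "window": [s.window_index for s in self.segments],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Export the provenance table as CSV."""
        self.provenance().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# loading


def load_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    **meta,
) -> Recording:
    """Load a recording from EDF, CSV matrix (rows = channels) or .npy.

    Headerless matrix formats (csv, npy) carry no sampling rate, so ``fs``
    must be given explicitly unless a YAML sidecar ``<stem>.yaml`` with an
    ``fs`` key sits next to the file.  EDF supplies fs and channel labels
    from its header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".edf": "edf", ".csv": "matrix_csv", ".npy": "matrix_npy"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")

    if format == "edf":
        return _load_edf(path, **meta)

    if format == "matrix_csv":
        data = pd.read_csv(path, header=None).to_numpy(dtype=float)
    elif format in ("matrix_npy", "matrix_npy-like binary"):
        data = np.load(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        side = yaml.safe_load(sidecar.read_text()) or {}
        fs = fs if fs is not None else side.get("fs")
        for key in ("channel_names", "subject_id", "session_id", "state"):
            meta.setdefault(key, side.get(key))
        meta = {k: v for k, v in meta.items() if v is not None}
    if fs is None:
        raise ValidationError(
            f"{path.name}: headerless matrix needs an explicit sampling rate"
        )
    return Recording(signal=data, fs=float(fs), **meta)


def _load_edf(path: Path, **meta) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads EDF in volts; store microvolts
    return Recording(
        signal=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        **meta,
    )


def save_matrix_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording as a plain CSV matrix plus a YAML sidecar."""
    path = Path(path)
    pd.DataFrame(rec.signal).to_csv(path, header=False, index=False)
    side = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "subject_id": rec.subject_id,
        "session_id": rec.session_id,
        "state": rec.state,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(side))


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as EDF (16-bit), one data record per second.

    Minimal writer covering the plain EDF profile: enough for synthetic
    recordings to exercise the EDF loading path.  The recording is
    truncated to whole seconds.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one 1 s EDF record")
    nch = rec.n_channels
    data = rec.signal[:, : n_rec * spr]

    pmin = np.floor(data.min(axis=1))
    pmax = np.ceil(data.max(axis=1))
    pmax = np.where(pmax <= pmin, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * gain[:, None] + dmin).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad(f"{rec.subject_id or 'X'}", 80),
            pad(f"{rec.session_id or 'X'}", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + nch)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(nch), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(pad(name, 16) for name in rec.channel_names),
            b"".join(pad("AgAgCl electrode", 80) for _ in range(nch)),
            b"".join(pad("uV", 8) for _ in range(nch)),
            b"".join(pad(f"{pmin[c]:g}", 8) for c in range(nch)),
            b"".join(pad(f"{pmax[c]:g}", 8) for c in range(nch)),
            b"".join(pad(str(dmin), 8) for _ in range(nch)),
            b"".join(pad(str(dmax), 8) for _ in range(nch)),
            b"".join(pad("", 80) for _ in range(nch)),
            b"".join(pad(str(spr), 8) for _ in range(nch)),
            b"".join(pad("", 32) for _ in range(nch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# segmentation and filtering


def segment_recording(
    rec: Recording,
    window_seconds: float = 30.0,
    overlap_fraction: float = 0.0,
) -> list[Segment]:
    """Cut a recording into fixed-length windows.

    Windows are contiguous from the start of the recording; a trailing
    remainder shorter than one window is dropped, so every segment has
    exactly ``round(window_seconds * fs)`` samples (3840 for 30 s at
    128 Hz).  With ``overlap_fraction`` 0 the windows are non-overlapping
    and the count is ``floor(duration / window_seconds)``.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    win = int(round(window_seconds * rec.fs))
    if win <= 0:
        raise ValueError("window_seconds too small for this sampling rate")
    if rec.n_samples < win:
        raise ValidationError(
            f"recording of {rec.duration:.1f} s is shorter than one "
            f"{window_seconds:.1f} s window"
        )
    hop = max(1, int(round(win * (1 - overlap_fraction))))
    out = []
    idx = 0
    for start in range(0, rec.n_samples - win + 1, hop):
        out.append(
            Segment(
                signal=rec.signal[:, start : start + win].copy(),
                fs=rec.fs,
                subject_id=rec.subject_id,
                session_id=rec.session_id,
                state=rec.state,
                window_index=idx,
            )
        )
        idx += 1
    return out


def bandpass(rec: Recording, low_hz: float, high_hz: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass copy of a recording.

    The reference device band-limits to 0.2-43 Hz in hardware, so this is
    optional pre-processing for data from other sources.  Forward-backward
    filtering preserves length and introduces no phase shift; Gustafsson
    initial conditions keep edge transients out of short windows.
    """
    nyq = rec.fs / 2
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 <= low < high < fs/2; "
            f"got ({low_hz}, {high_hz}) at fs={rec.fs}"
        )
    if low_hz == 0:
        b, a = butter(order, high_hz / nyq, btype="low")
    else:
        b, a = butter(order, [low_hz / nyq, high_hz / nyq], btype="band")
    return replace(rec, signal=filtfilt(b, a, rec.signal, axis=1, method="gust"))
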