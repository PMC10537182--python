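"""Synthetic multichannel EEG with state-dependent rhythm-band power.

Emulates the structure of the reference recordings (14 channels, 128 Hz,
10-minute blocks per mental state, segmentable into 30 s windows) so the
whole pipeline is exercisable without external data.  Each channel is a sum
of band-limited Gaussian noise components -- one per canonical EEG rhythm
(delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-43 Hz) -- over a
1/f pink-noise floor.  The default profiles encode the physiological
expectations the three states rest on: drowsiness is slow-wave (theta/
alpha) dominant, focus is beta dominant, and the unfocused state is flat.

Band-limited components are synthesised in the frequency domain (random
phase, shaped magnitude), which gives exact band control.  What this
generator does NOT model: eye-blink/EMG artifacts, volume conduction and
inter-channel covariance, non-stationarity within a block.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .signal_core import Recording, SegmentSet, segment_recording

BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 43.0),
}


@dataclass(frozen=True)
class StateProfile:
    """Relative per-band power plus pink-noise floor for one mental state."""

    band_power: dict = field(
        default_factory=lambda: {b: 1.0 for b in BANDS}
    )
    pink_level: float = 1.0
    gain_jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        unknown = set(self.band_power) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands {sorted(unknown)}")
        if any(v < 0 for v in self.band_power.values()):
            raise ValueError("band powers must be >= 0")
        if not any(v > 0 for v in self.band_power.values()):
            raise ValueError("at least one band power must be positive")


#: Well-separated defaults: beta-dominant focus, flat unfocused,
#: theta/alpha-dominant drowsiness (alpha:beta ratio 5).
DEFAULT_PROFILES: dict[str, StateProfile] = {
    "focused": StateProfile(
        {"delta": 1.0, "theta": 0.7, "alpha": 0.8, "beta": 2.5, "gamma": 0.8}
    ),
    "unfocused": StateProfile(
        {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0}
    ),
    "drowsy": StateProfile(
        {"delta": 1.5, "theta": 2.5, "alpha": 2.5, "beta": 0.5, "gamma": 0.3}
    ),
}

#: Identical profiles for every state: a null dataset carrying no class
#: signal, against which chance-level accuracy is verified.
NULL_PROFILES: dict[str, StateProfile] = {
    state: StateProfile() for state in DEFAULT_PROFILES
}


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 1
    sessions_per_subject: int = 1
    minutes_per_state: float = 10.0
    fs: float = 128.0
    channels: int = 14
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    master_seed: int = 0
    amplitude_uv: float = 20.0  # overall RMS scale in microvolts

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.sessions_per_subject, self.channels) < 1:
            raise ValueError("counts must be positive")
        n = self.fs * 60.0 * self.minutes_per_state
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * minutes must give an integer sample count")


def _stream(cfg: SimConfig, *tokens) -> np.random.Generator:
    """Reproducible per-(subject, session, state) random stream."""
    key = zlib.crc32("|".join(str(t) for t in tokens).encode())
    return np.random.default_rng(np.random.SeedSequence([cfg.master_seed, key]))


def _shaped_noise(rng: np.random.Generator, n: int, mag: np.ndarray,
                  power: float) -> np.ndarray:
    """Stationary Gaussian noise with rfft magnitude shape ``mag``.

    The scale is set so the EXPECTED variance equals ``power`` -- no
    per-realisation normalisation.  Normalising each realisation exactly
    would give every recording its own tell-tale gain, i.e. a spurious
    recording fingerprint that a pooled-fold classifier can exploit even
    when the state profiles are identical.
    """
    spec = mag * (rng.standard_normal(mag.size) + 1j * rng.standard_normal(mag.size))
    expected_var = 4.0 * np.sum(mag[1:-1] ** 2) / n**2 + 2.0 * (
        mag[0] ** 2 + mag[-1] ** 2
    ) / n**2
    if expected_var == 0:
        return np.zeros(n)
    return np.fft.irfft(spec, n) * np.sqrt(power / expected_var)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float, power: float) -> np.ndarray:
    """Gaussian noise confined to [lo, hi] Hz with expected variance ``power``."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mag = ((freqs >= lo) & (freqs <= hi)).astype(float)
    return _shaped_noise(rng, n, mag, power)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, power: float,
                lo: float = 0.2, hi: float = 43.0) -> np.ndarray:
    """1/f noise over the emulated device bandwidth (0.2-43 Hz).

    The low cut matters: unbounded 1/f puts a third of its power below
    0.03 Hz, which shows up as recording-specific slow drift rather than
    anything an EEG front-end would record.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mag = np.zeros(freqs.size)
    sel = (freqs >= lo) & (freqs <= hi)
    mag[sel] = 1.0 / np.sqrt(freqs[sel])
    return _shaped_noise(rng, n, mag, power)


def generate_recording(
    profile: StateProfile, cfg: SimConfig, subject: int, session: int, state: str
) -> Recording:
    """One labeled multichannel recording, deterministic given the config seed."""
    n = int(round(cfg.fs * 60.0 * cfg.minutes_per_state))
    rng = _stream(cfg, subject, session, state)
    gain_rng = _stream(cfg, "subject-gain", subject)
    gain = 1.0 + profile.gain_jitter_sd * gain_rng.standard_normal()
    total_rel = sum(profile.band_power.values()) + profile.pink_level
    scale = cfg.amplitude_uv**2 / total_rel  # uV^2 per relative power unit
    signal = np.zeros((cfg.channels, n))
    for c in range(cfg.channels):
        x = np.zeros(n)
        for band, (lo, hi) in BANDS.items():
            p = profile.band_power.get(band, 0.0)
            if p > 0:
                x += _band_noise(rng, n, cfg.fs, lo, hi, p * scale)
        if profile.pink_level > 0:
            x += _pink_noise(rng, n, cfg.fs, profile.pink_level * scale)
        signal[c] = gain * x
    return Recording(
        signal=signal,
        fs=cfg.fs,
        channel_names=[f"ch{i}" for i in range(cfg.channels)],
        subject_id=f"S{subject:02d}",
        session_id=f"E{session:02d}",
        state=state,
    )


def generate_dataset(cfg: SimConfig, window_seconds: float = 30.0) -> SegmentSet:
    """Recordings for every (subject, session, state), segmented and labeled.

    With equal minutes per state the classes come out exactly balanced:
    1 subject x 1 session x 10 min per state gives 20 segments per class.
    """
    segments, labels = [], []
    for subject in range(cfg.n_subjects):
        for session in range(cfg.sessions_per_subject):
            for state, profile in cfg.profiles.items():
                rec = generate_recording(profile, cfg, subject, session, state)
                for seg in segment_recording(rec, window_seconds):
                    segments.append(seg)
                    labels.append(state)
    return SegmentSet(segments, labels)
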