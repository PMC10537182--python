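"""Three wavelet filter banks with a uniform subband container.

* MDWT -- multilevel discrete wavelet transform: the classical dyadic
  cascade (db2 by default, 4 levels -> 5 subbands matching the five EEG
  rhythms at 128 Hz).
* TQWT -- tunable Q-factor wavelet transform: an oversampled two-channel
  filter bank parameterised by quality factor ``q``, oversampling rate
  ``R`` and depth ``B``, realised directly in the frequency domain as a
  tight frame.
* FAWT -- flexible analytic wavelet transform: rational sampling-rate
  changes (p/q low-pass, r/s high-pass) and one-sided (analytic) high-pass
  channels, also realised in the frequency domain.

All three expose ``*_decompose`` / ``*_reconstruct`` pairs with perfect
reconstruction, and index subbands SB-1 (highest frequency) down to the
final low-pass band SB-(levels+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt


class ParameterError(ValueError):
    """Invalid transform parameters."""


def _theta(u: np.ndarray) -> np.ndarray:
    """Daubechies 2-vanishing-moment frequency response on [0, pi].

    theta(0) = 1, theta(pi) = 0 and theta(u)^2 + theta(pi - u)^2 = 1,
    which is what makes the two-channel frequency-domain banks below
    power-complementary (hence tight frames with exact inversion).
    """
    u = np.asarray(u, dtype=float)
    return 0.5 * (1.0 + np.cos(u)) * np.sqrt(2.0 - np.cos(u))


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class MDWTParams:
    wavelet_name: str = "db2"
    levels: int = 4
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ParameterError("levels must be >= 1")
        try:
            pywt.Wavelet(self.wavelet_name)
        except ValueError as exc:
            raise ParameterError(f"unknown wavelet {self.wavelet_name!r}") from exc


@dataclass(frozen=True)
class TQWTParams:
    """q >= 1 (oscillatory for q > 1), R >= 3, B decomposition levels.

    The scalings follow from the design equations: beta = 2/(q+1) for the
    high-pass channel and a = 1 - beta/R for the low-pass channel.
    """

    q: float = 2.0
    R: float = 5.0
    B: int = 7

    def __post_init__(self) -> None:
        tqwt_design(self.q, self.R)  # validates q, R
        if self.B < 1:
            raise ParameterError("B must be >= 1")

    @property
    def beta(self) -> float:
        return 2.0 / (self.q + 1.0)

    @property
    def a(self) -> float:
        return 1.0 - self.beta / self.R


@dataclass(frozen=True)
class FAWTParams:
    """Rational-rate analytic filter bank parameters.

    p/q is the low-pass rate change (p < q), r/s the high-pass one.
    ``beta`` and ``eps`` shape the transition bands and must keep the
    frequency edges ordered (validated at construction).
    """

    B: int = 6
    p: int = 3
    q: int = 5
    r: int = 2
    s: int = 3
    beta: float | None = None
    eps: float | None = None

    def __post_init__(self) -> None:
        if self.p >= self.q:
            raise ParameterError("require p < q for a contracting low-pass channel")
        if min(self.p, self.q, self.r, self.s) < 1:
            raise ParameterError("sampling factors must be positive integers")
        if self.B < 1:
            raise ParameterError("B must be >= 1")
        fawt_design(self)  # validates edge ordering

    @property
    def beta_(self) -> float:
        return self.r / self.s if self.beta is None else self.beta

    @property
    def eps_(self) -> float:
        if self.eps is None:
            return (self.q - self.p) / (self.q + self.p) * np.pi
        return self.eps


@dataclass
class SubbandSet:
    """Ordered subbands of one transform applied to one signal.

    ``subbands[0]`` is SB-1, the highest-frequency band; the last entry is
    the low-pass band.  FAWT high-pass bands are stored in their complex
    analytic form; ``real_subbands`` exports every band as a real signal
    (2x the real part for analytic bands).
    """

    transform_id: str
    subbands: list[np.ndarray]
    original_length: int
    params: object
    padded: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_subbands(self) -> int:
        return len(self.subbands)

    @property
    def real_subbands(self) -> list[np.ndarray]:
        return [
            2.0 * b.real if np.iscomplexobj(b) else b for b in self.subbands
        ]

    def energies(self) -> np.ndarray:
        """Per-subband energy; analytic bands count their conjugate pair."""
        return np.array(
            [
                (2.0 if np.iscomplexobj(b) else 1.0) * np.sum(np.abs(b) ** 2)
                for b in self.subbands
            ]
        )


# ---------------------------------------------------------------------------
# MDWT


def mdwt_decompose(x: np.ndarray, params: MDWTParams = MDWTParams()) -> SubbandSet:
    """Dyadic wavelet decomposition into ``levels`` details + 1 approximation.

    SB-1 is the level-1 detail (highest octave), SB-L the level-L detail,
    SB-(L+1) the approximation.
    """
    x = np.asarray(x, dtype=float)
    w = pywt.Wavelet(params.wavelet_name)
    if x.size < w.dec_len * 2**params.levels:
        raise ParameterError(
            f"signal of length {x.size} too short for {params.levels} levels "
            f"of {params.wavelet_name} (needs >= {w.dec_len * 2 ** params.levels})"
        )
    coeffs = pywt.wavedec(x, w, mode=params.mode, level=params.levels)
    # wavedec returns [cA_L, cD_L, ..., cD_1]; reorder to SB-1 .. SB-(L+1)
    subbands = list(coeffs[:0:-1]) + [coeffs[0]]
    return SubbandSet("mdwt", subbands, x.size, params)


def mdwt_reconstruct(sbs: SubbandSet) -> np.ndarray:
    if sbs.transform_id != "mdwt":
        raise ValueError("expected an mdwt SubbandSet")
    params: MDWTParams = sbs.params
    coeffs = [sbs.subbands[-1]] + list(sbs.subbands[-2::-1])
    out = pywt.waverec(coeffs, params.wavelet_name, mode=params.mode)
    return out[: sbs.original_length]


# ---------------------------------------------------------------------------
# TQWT


def tqwt_design(q: float, R: float) -> tuple[float, float]:
    """High-pass and low-pass scalings (beta, a) from (q, R).

    beta = 2/(q+1), a = 1 - beta/R.  The inverse identities
    q = (2-beta)/beta and R = beta/(1-a) hold exactly.
    """
    if q < 1:
        raise ParameterError(f"quality factor q must be >= 1, got {q}")
    if R < 3:
        raise ParameterError(f"oversampling rate R must be >= 3, got {R}")
    beta = 2.0 / (q + 1.0)
    a = 1.0 - beta / R
    return beta, a


def _tqwt_stage_lengths(N: int, a: float, beta: float) -> tuple[int, int]:
    N0 = 2 * int(round(a * N / 2.0))
    N1 = 2 * int(round(beta * N / 2.0))
    if N0 + N1 <= N:
        raise ParameterError("degenerate transition band; signal too short")
    return N0, N1


def _tqwt_weights(N: int, N0: int, N1: int) -> tuple[np.ndarray, np.ndarray]:
    """Low/high-pass weights on DFT bins 0..N/2 (power complementary)."""
    P = (N - N1) // 2          # last full-gain low-pass bin
    T = (N0 + N1 - N) // 2     # transition length in bins
    k = np.arange(N // 2 + 1)
    u = np.clip((k - P) / T, 0.0, 1.0) * np.pi
    w0 = np.where(k <= N0 // 2, _theta(u), 0.0)
    w1 = np.where(k >= P, _theta(np.pi - u), 0.0)
    return w0, w1


def _hermitian(half: np.ndarray, n: int) -> np.ndarray:
    """Full-length DFT from bins 0..n/2 of a real signal."""
    full = np.zeros(n, dtype=complex)
    full[: n // 2 + 1] = half
    full[n // 2 + 1 :] = np.conj(half[1 : n // 2][::-1])
    return full


def tqwt_decompose(x: np.ndarray, params: TQWTParams = TQWTParams()) -> SubbandSet:
    """B high-pass subbands (SB-1 highest frequency) + 1 low-pass subband.

    Frequency-domain tight-frame implementation: at each stage the input
    spectrum is split by power-complementary tapers and critically mapped
    onto subband spectra of (even, rounded) lengths a*N and beta*N.
    """
    x = np.asarray(x, dtype=float)
    padded = x.size % 2
    if padded:
        x = np.concatenate([x, [0.0]])
    a, beta = params.a, params.beta
    X = np.fft.fft(x)
    N = x.size
    subbands: list[np.ndarray] = []
    stage_lengths: list[int] = []
    for _ in range(params.B):
        stage_lengths.append(N)
        N0, N1 = _tqwt_stage_lengths(N, a, beta)
        if N1 < 8 or N0 < 8:
            raise ParameterError(
                f"signal too short: a level-{len(subbands) + 1} subband would "
                f"have fewer than 8 samples"
            )
        w0, w1 = _tqwt_weights(N, N0, N1)
        P = (N - N1) // 2
        V0 = X[: N0 // 2 + 1] * w0[: N0 // 2 + 1] * np.sqrt(N0 / N)
        V1 = X[P : P + N1 // 2 + 1] * w1[P : P + N1 // 2 + 1] * np.sqrt(N1 / N)
        subbands.append(np.fft.ifft(_hermitian(V1, N1)).real)
        X = _hermitian(V0, N0)
        N = N0
    subbands.append(np.fft.ifft(X).real)
    return SubbandSet(
        "tqwt", subbands, x.size - padded, params, padded,
        meta={"stage_lengths": stage_lengths},
    )


def tqwt_reconstruct(sbs: SubbandSet) -> np.ndarray:
    if sbs.transform_id != "tqwt":
        raise ValueError("expected a tqwt SubbandSet")
    params: TQWTParams = sbs.params
    stage_lengths = sbs.meta["stage_lengths"]
    X = np.fft.fft(sbs.subbands[-1])
    for lvl in range(params.B - 1, -1, -1):
        N0 = X.size
        N1 = sbs.subbands[lvl].size
        N = stage_lengths[lvl]
        if _tqwt_stage_lengths(N, params.a, params.beta) != (N0, N1):
            raise ValueError("tampered subband lengths")
        w0, w1 = _tqwt_weights(N, N0, N1)
        P = (N - N1) // 2
        V1 = np.fft.fft(sbs.subbands[lvl])
        half = np.zeros(N // 2 + 1, dtype=complex)
        half[: N0 // 2 + 1] = X[: N0 // 2 + 1] * w0[: N0 // 2 + 1] / np.sqrt(N0 / N)
        half[P : P + N1 // 2 + 1] += (
            V1[: N1 // 2 + 1] * w1[P : P + N1 // 2 + 1] / np.sqrt(N1 / N)
        )
        X = _hermitian(half, N)
    out = np.fft.ifft(X).real
    return out[: sbs.original_length]


# ---------------------------------------------------------------------------
# FAWT


def fawt_design(params: FAWTParams) -> tuple[float, float, float, float, float, float]:
    """Frequency edges (wp, ws, w0, w1, w2, w3) of the two filters.

    Edges in the filters' own rate (low-pass filter runs at p times the
    input rate, high-pass at r times):

        wp = ((1 - beta)*pi + eps) / p      ws = pi / q
        w0 = ((1 - beta)*pi + eps) / r      w1 = p*pi / (q*r)
        w2 = (pi - eps) / r                 w3 = (pi + eps) / r

    Validity requires wp < ws and w0 <= w1 <= w2 < w3; each inequality is
    reported by name on failure.
    """
    p, q, r = params.p, params.q, params.r
    beta, eps = params.beta_, params.eps_
    wp = ((1.0 - beta) * np.pi + eps) / p
    ws = np.pi / q
    w0 = ((1.0 - beta) * np.pi + eps) / r
    w1 = p * np.pi / (q * r)
    w2 = (np.pi - eps) / r
    w3 = (np.pi + eps) / r
    checks = [
        ("wp < ws", wp < ws),
        ("w0 <= w1", w0 <= w1 + 1e-12),
        ("w1 <= w2", w1 <= w2 + 1e-12),
        # eps = 0 collapses the upper transition (w2 == w3): a valid albeit
        # degenerate design point; decomposition itself requires eps > 0
        ("w2 <= w3", w2 <= w3),
    ]
    failed = [name for name, ok in checks if not ok]
    if failed:
        raise ParameterError(
            "frequency-edge ordering violated: " + ", ".join(failed)
        )
    return wp, ws, w0, w1, w2, w3


def _fawt_stage_weights(N: int, params: FAWTParams):
    """Per-bin weights for one analysis stage at input length N.

    Returns (w0half, lp_len, band_bins, w1band, hp_len): the low-pass
    weights on bins 0..lp_len/2, and the high-pass weights w1band on the
    (possibly Nyquist-wrapping) DFT bin range band_bins.
    """
    beta, eps = params.beta_, params.eps_
    if eps <= 0:
        raise ParameterError("decomposition requires eps > 0 (finite transitions)")
    o_pass = (1.0 - beta) * np.pi + eps       # input-rate rad/sample
    o_stop = params.p * np.pi / params.q
    o2 = np.pi - eps
    o3 = np.pi + eps
    if o_stop > o2 + 1e-12:
        raise ParameterError(
            "high-pass plateau vanished (p*pi/q > pi - eps); reduce eps"
        )

    lp_len = 2 * int(np.ceil(params.p * N / (2.0 * params.q)))
    hp_len = 2 * int(np.ceil(params.r * N / (2.0 * params.s)))

    k = np.arange(lp_len // 2 + 1)
    om = 2.0 * np.pi * k / N
    w0 = np.where(
        om <= o_pass,
        1.0,
        np.where(om < o_stop, _theta((om - o_pass) / (o_stop - o_pass) * np.pi), 0.0),
    )

    kA = int(np.floor(o_pass * N / (2.0 * np.pi))) + 1
    kB = int(np.ceil(o3 * N / (2.0 * np.pi))) - 1
    band = np.arange(kA, kB + 1)
    omb = 2.0 * np.pi * band / N
    w1 = np.where(
        omb < o_stop,
        _theta(np.pi - (omb - o_pass) / (o_stop - o_pass) * np.pi),
        np.where(omb <= o2, 1.0, _theta((omb - o2) / (o3 - o2) * np.pi)),
    )
    if band.size > hp_len:
        raise ParameterError("beta too large for the r/s high-pass rate")
    return w0, lp_len, band, w1, hp_len


def fawt_decompose(x: np.ndarray, params: FAWTParams = FAWTParams()) -> SubbandSet:
    """B analytic high-pass subbands + 1 low-pass subband (B+1 total).

    High-pass subbands are complex analytic signals (positive-frequency
    band only); ``SubbandSet.real_subbands`` exports them as real signals
    (2x the real part of the analytic pair).
    """
    x = np.asarray(x, dtype=float)
    padded = x.size % 2
    if padded:
        x = np.concatenate([x, [0.0]])
    min_len = 2 ** params.B * max(params.p, params.q, params.r, params.s)
    if x.size < min_len:
        raise ParameterError(
            f"signal of length {x.size} too short for B={params.B} "
            f"(needs >= {min_len})"
        )
    X = np.fft.fft(x)
    N = x.size
    subbands: list[np.ndarray] = []
    stage_lengths: list[int] = []
    for _ in range(params.B):
        stage_lengths.append(N)
        w0, lp_len, band, w1, hp_len = _fawt_stage_weights(N, params)
        V1 = np.zeros(hp_len, dtype=complex)
        V1[: band.size] = X[band % N] * w1 * np.sqrt(hp_len / N)
        subbands.append(np.fft.ifft(V1))
        V0 = X[: lp_len // 2 + 1] * w0 * np.sqrt(lp_len / N)
        X = _hermitian(V0, lp_len)
        N = lp_len
    subbands.append(np.fft.ifft(X).real)
    return SubbandSet(
        "fawt", subbands, x.size - padded, params, padded,
        meta={"stage_lengths": stage_lengths},
    )


def fawt_reconstruct(sbs: SubbandSet) -> np.ndarray:
    if sbs.transform_id != "fawt":
        raise ValueError("expected a fawt SubbandSet")
    params: FAWTParams = sbs.params
    X = np.fft.fft(sbs.subbands[-1])
    stage_lengths = sbs.meta["stage_lengths"]
    for lvl in range(params.B - 1, -1, -1):
        lp_len = X.size
        N = stage_lengths[lvl]
        w0, lp_len_chk, band, w1, hp_len = _fawt_stage_weights(N, params)
        if lp_len_chk != lp_len or sbs.subbands[lvl].size != hp_len:
            raise ValueError("tampered subband lengths")
        half = np.zeros(N // 2 + 1, dtype=complex)
        half[: lp_len // 2 + 1] = X[: lp_len // 2 + 1] * w0 / np.sqrt(lp_len / N)
        Y = _hermitian(half, N)
        V1 = np.fft.fft(sbs.subbands[lvl])
        C = np.zeros(N, dtype=complex)
        C[band % N] = V1[: band.size] * w1 / np.sqrt(hp_len / N)
        # analytic channel: add the conjugate-mirrored contribution so the
        # taper halves recombine to unit gain for a real parent signal
        Y += C
        Y[(-np.arange(N)) % N] += np.conj(C)
        X = Y
    out = np.fft.ifft(X).real
    return out[: sbs.original_length]


# ---------------------------------------------------------------------------
# nominal frequency spans


def subband_rhythm_map(sbs: SubbandSet, fs: float) -> list[tuple[int, float, float]]:
    """Nominal (SB index, low Hz, high Hz) span for each subband.

    MDWT spans halve per level (dyadic); TQWT spans shrink by the low-pass
    scaling ``a`` per level; FAWT spans shrink by ``p/q`` per level.
    """
    nyq = fs / 2.0
    spans: list[tuple[int, float, float]] = []
    n = sbs.n_subbands
    if sbs.transform_id == "mdwt":
        for b in range(1, n):
            spans.append((b, nyq / 2**b, nyq / 2 ** (b - 1)))
        spans.append((n, 0.0, nyq / 2 ** (n - 1)))
    elif sbs.transform_id == "tqwt":
        p: TQWTParams = sbs.params
        for b in range(1, n):
            hi = p.a ** (b - 1) * nyq
            spans.append((b, (1.0 - p.beta) * hi, hi))
        spans.append((n, 0.0, p.a ** p.B * nyq))
    elif sbs.transform_id == "fawt":
        p: FAWTParams = sbs.params
        c = p.p / p.q
        lo_frac = ((1.0 - p.beta_) * np.pi + p.eps_) / np.pi
        for b in range(1, n):
            hi = c ** (b - 1) * nyq
            spans.append((b, lo_frac * hi, hi))
        spans.append((n, 0.0, c ** p.B * nyq))
    else:
        raise ValueError(f"unknown transform {sbs.transform_id!r}")
    return spans
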