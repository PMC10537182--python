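"""The 27 per-subband features and the segment x feature matrix.

Each subband of each channel of each segment is summarised by 27
statistical and nonlinear scalars (amplitude statistics, energy measures,
difference statistics, quartile statistics, plus Hurst exponent, Higuchi
fractal dimension and the largest Lyapunov exponent).  For the reference
configuration -- 14 channels x 27 features -- one subband of one segment
yields a 378-column row.

Conventions used throughout (N = length, d_i = x_{i+1} - x_i,
g_i = x_{i+2} - x_i):

* standard deviation and variances use the N-1 (sample) divisor;
* skewness/kurtosis are moment ratios m3/m2^1.5 and m4/m2^2 (kurtosis is
  not excess-corrected);
* quartiles use linear interpolation;
* fractional powers are applied to |x| (negative samples would otherwise
  be undefined).

Degenerate inputs never produce NaN: on a constant signal the normalised
difference features and the Lyapunov exponent return 0, and the log-energy
sum is floored by an additive 1e-12 inside the logarithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signal_core import SegmentSet


@dataclass(frozen=True)
class FeatureSpec:
    """A named feature with overridable estimator parameters."""

    name: str
    parameters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# individual features


def _std(x, **_):
    return float(np.std(x, ddof=1))


def _hurst(x, min_window: int = 10, n_windows: int = 10, **_):
    """Rescaled-range Hurst exponent with the Anis-Lloyd-Peters correction.

    R/S is averaged over non-overlapping blocks for log-spaced block sizes
    in [min_window, N/2]; H is 0.5 plus the slope of
    log(R/S) - log(E[R/S]) against log(size), which removes the small-
    sample bias of the raw R/S statistic (white noise -> H near 0.5).
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if N < 2 * min_window:
        return 0.5
    sizes = np.unique(
        np.floor(np.exp(np.linspace(np.log(min_window), np.log(N // 2), n_windows)))
    ).astype(int)
    log_rs, log_exp, log_n = [], [], []
    for n in sizes:
        blocks = x[: (N // n) * n].reshape(-1, n)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        rng = z.max(axis=1) - z.min(axis=1)
        sd = blocks.std(axis=1, ddof=1)
        ok = sd > 0
        if not ok.any():
            continue
        rs = np.mean(rng[ok] / sd[ok])
        if rs <= 0:
            continue
        log_rs.append(np.log(rs))
        log_exp.append(np.log(_expected_rs(n)))
        log_n.append(np.log(n))
    if len(log_n) < 2:
        return 0.5
    slope = np.polyfit(log_n, np.array(log_rs) - np.array(log_exp), 1)[0]
    return float(0.5 + slope)


def _expected_rs(n: int) -> float:
    """Anis-Lloyd expected R/S of i.i.d. Gaussian noise at block size n."""
    i = np.arange(1, n)
    s = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        from scipy.special import gammaln

        front = np.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2.0)
    return (n - 0.5) / n * front * s


def _average_energy(x, **_):
    return float(np.mean(x**2))


def _wavelength(x, **_):
    return float(np.sum(np.abs(np.diff(x))))


def _v_order(x, v: float = 2.0, **_):
    return float(np.mean(np.abs(x) ** v) ** (1.0 / v))


def _skewness(x, **_):
    if np.ptp(x) == 0:
        return 0.0  # moment ratio undefined on a constant signal
    return float(stats.skew(x, bias=True))


def _kurtosis(x, **_):
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.kurtosis(x, fisher=False, bias=True))


def _hjorth_mobility(x, **_):
    vx = np.var(x, ddof=1)
    if vx == 0:
        return 0.0
    return float(np.sqrt(np.var(np.diff(x), ddof=1) / vx))


def _higuchi_fd(x, kmax: int = 10, **_):
    """Higuchi curve-length fractal dimension (slope of log L(k) vs log 1/k)."""
    x = np.asarray(x, dtype=float)
    N = x.size
    lk, invk = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, N, k)
            if idx.size < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (N - 1) / (idx.size - 1) / k
            lengths.append(dist * norm / k)
        if lengths and np.mean(lengths) > 0:
            lk.append(np.log(np.mean(lengths)))
            invk.append(np.log(1.0 / k))
    if len(lk) < 2:
        return 1.0
    return float(np.polyfit(invk, lk, 1)[0])


def _lyapunov(
    x,
    emb_dim: int = 10,
    delay: int = 1,
    fit_steps: int = 20,
    max_samples: int = 512,
    fs: float | None = None,
    **_,
):
    """Largest Lyapunov exponent, Rosenstein nearest-neighbour method.

    The signal is embedded with dimension ``emb_dim`` and delay ``delay``;
    each point's nearest neighbour outside a Theiler window equal to the
    signal's mean period is tracked, and the exponent is the slope of mean
    log divergence over the first ``fit_steps`` steps.  Analysis is capped
    at ``max_samples`` points (an estimator parameter; divergence curves
    saturate long before that on 30 s windows).
    """
    x = np.asarray(x, dtype=float)
    if x.size > max_samples:
        x = x[:max_samples]
    N = x.size
    if np.std(x) == 0:
        return 0.0
    # mean period from the spectral centroid of the power spectrum
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(N)
    denom = np.sum(freqs * spec)
    mean_period = np.sum(spec) / denom if denom > 0 else N
    theiler = max(1, int(round(mean_period)))

    M = N - (emb_dim - 1) * delay
    if M < 2 * (theiler + 1) or M <= fit_steps + 2:
        return 0.0
    from scipy.spatial.distance import cdist

    emb = np.column_stack([x[i * delay : i * delay + M] for i in range(emb_dim)])
    d2 = cdist(emb, emb, "sqeuclidean")
    ii = np.arange(M)
    mask = np.abs(ii[:, None] - ii[None, :]) <= theiler
    d2[mask] = np.inf
    nn = np.argmin(d2, axis=1)

    steps = min(fit_steps, M - 1)
    logs = np.full((M, steps), np.nan)
    for j in range(steps):
        valid = (ii + j < M) & (nn + j < M)
        dist = np.linalg.norm(emb[ii[valid] + j] - emb[nn[valid] + j], axis=1)
        good = dist > 0
        rows = ii[valid][good]
        logs[rows, j] = np.log(dist[good])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_log = np.nanmean(logs, axis=0)
    ok = np.isfinite(mean_log)
    if ok.sum() < 2:
        return 0.0
    return float(np.polyfit(np.arange(steps)[ok], mean_log[ok], 1)[0])


def _dasdv(x, **_):
    d = np.diff(x)
    return float(np.sqrt(np.sum(d**2) / d.size))


def _abs_sum_exp_root(x, power: float = 0.75, **_):
    return float(np.abs(np.sum(np.abs(x) ** power)))


def _abs_sum_sqrt(x, **_):
    return float(np.abs(np.sum(np.abs(x) ** 0.5)))


def _norm_first_diff(x, **_):
    sd = np.std(x, ddof=1)
    if sd == 0:
        warnings.warn("constant signal: normalised first difference set to 0")
        return 0.0
    d = np.abs(np.diff(x))
    return float(np.sum(d) / d.size / sd)


def _norm_second_diff(x, **_):
    sd = np.std(x, ddof=1)
    if sd == 0:
        warnings.warn("constant signal: normalised second difference set to 0")
        return 0.0
    g = np.abs(x[2:] - x[:-2])
    return float(np.sum(g) / g.size / sd)


def _mean_sqrt(x, **_):
    return float(np.mean(np.abs(x) ** 0.5))


def _diff_variance(x, **_):
    return float(np.var(np.diff(x), ddof=1))


def _log_energy(x, floor: float = 1e-12, **_):
    return float(np.sum(np.log(x**2 + floor)))


def _abs_energy(x, **_):
    return float(np.sum(x**2))


def _ssi(x, **_):
    # simple square integral; numerically equal to absolute energy for real
    # signals, kept as its own entry for fidelity to the printed feature list
    return float(np.sum(np.abs(x) ** 2))


def _slope_sign_changes(x, **_):
    d = np.diff(x)
    return float(np.sum(d[:-1] * d[1:] < 0))


def _peak_amplitude(x, **_):
    return float(np.max(x))


def _minima(x, **_):
    return float(np.min(x))


def _peak_to_peak(x, **_):
    return float(np.max(x) - np.min(x))


def _zero_crossing_rate(x, **_):
    return float(np.sum(x[:-1] * x[1:] < 0) / (x.size - 1))


def _iqr(x, **_):
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def _trimean(x, **_):
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return float((q1 + 2 * q2 + q3) / 4.0)


FEATURE_REGISTRY = {
    "std": _std,
    "hurst": _hurst,
    "average_energy": _average_energy,
    "wavelength": _wavelength,
    "v_order": _v_order,
    "skewness": _skewness,
    "kurtosis": _kurtosis,
    "hjorth_mobility": _hjorth_mobility,
    "higuchi_fd": _higuchi_fd,
    "lyapunov": _lyapunov,
    "dasdv": _dasdv,
    "abs_sum_exp_root": _abs_sum_exp_root,
    "abs_sum_sqrt": _abs_sum_sqrt,
    "norm_first_diff": _norm_first_diff,
    "norm_second_diff": _norm_second_diff,
    "mean_sqrt": _mean_sqrt,
    "diff_variance": _diff_variance,
    "log_energy": _log_energy,
    "abs_energy": _abs_energy,
    "ssi": _ssi,
    "slope_sign_changes": _slope_sign_changes,
    "peak_amplitude": _peak_amplitude,
    "minima": _minima,
    "peak_to_peak": _peak_to_peak,
    "zero_crossing_rate": _zero_crossing_rate,
    "iqr": _iqr,
    "trimean": _trimean,
}

#: The 27 default features, in the fixed printed-list order used for
#: ranking tie-breaks.
DEFAULT_FEATURES: tuple[FeatureSpec, ...] = tuple(
    FeatureSpec(name) for name in FEATURE_REGISTRY
)


def compute_feature(x: np.ndarray, spec: FeatureSpec) -> float:
    """One scalar feature of a 1-D signal."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("compute_feature expects a 1-D signal")
    if x.size < 8:
        raise ValueError(f"signal too short ({x.size} < 8) for feature estimation")
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    try:
        fn = FEATURE_REGISTRY[spec.name]
    except KeyError:
        raise ValueError(
            f"unknown feature {spec.name!r}; known: {sorted(FEATURE_REGISTRY)}"
        ) from None
    return fn(x, **spec.parameters)


def compute_feature_vector(
    x: np.ndarray, specs: tuple[FeatureSpec, ...] = DEFAULT_FEATURES
) -> np.ndarray:
    """All features of one signal in spec order (27 by default)."""
    return np.array([compute_feature(x, s) for s in specs])


# ---------------------------------------------------------------------------
# the segment x feature matrix


@dataclass
class FeatureMatrix:
    """Segments x (channels x features) table with column provenance.

    ``column_meta`` is a DataFrame with one row per column:
    (transform, subband, channel, feature).
    """

    values: np.ndarray
    labels: np.ndarray
    column_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape[0] != self.labels.size:
            raise ValueError("one label per row required")
        if self.values.shape[1] != len(self.column_meta):
            raise ValueError("column_meta must describe every column")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        """Feature types in first-appearance (printed-list) order."""
        return list(dict.fromkeys(self.column_meta["feature"]))

    def to_csv(self, path) -> None:
        """Columnar CSV with transform.subband.channel.feature headers."""
        cols = [
            f"{m.transform}.{m.subband}.{m.channel}.{m.feature}"
            for m in self.column_meta.itertuples()
        ]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        meta = pd.DataFrame(
            [c.split(".", 3) for c in df.columns],
            columns=["transform", "subband", "channel", "feature"],
        )
        meta["subband"] = meta["subband"].astype(int)
        return cls(df.to_numpy(dtype=float), labels, meta)


_DECOMPOSERS = {}


def _get_decomposer(transform_id: str):
    global _DECOMPOSERS
    if not _DECOMPOSERS:
        from . import wavelet_bank as wb

        _DECOMPOSERS = {
            "mdwt": wb.mdwt_decompose,
            "tqwt": wb.tqwt_decompose,
            "fawt": wb.fawt_decompose,
        }
    return _DECOMPOSERS[transform_id]


def extract_subband_features(
    segs: SegmentSet,
    transform_id: str,
    params,
    subband_index: int,
    specs: tuple[FeatureSpec, ...] = DEFAULT_FEATURES,
) -> FeatureMatrix:
    """Decompose every channel of every segment and featurise one subband.

    ``subband_index`` is 1-based (SB-1 = highest frequency).  The result
    has ``len(segs)`` rows and ``n_channels * len(specs)`` columns, ordered
    channel-major (all features of channel 0, then channel 1, ...).
    """
    decompose = _get_decomposer(transform_id)
    n_ch = segs.n_channels
    n_sb = len(decompose(segs.segments[0].signal[0], params).subbands)
    if not 1 <= subband_index <= n_sb:
        raise IndexError(
            f"subband {subband_index} out of range for {transform_id} "
            f"(1..{n_sb})"
        )
    rows = np.empty((len(segs), n_ch * len(specs)))
    for i, seg in enumerate(segs.segments):
        for c in range(n_ch):
            sbs = decompose(seg.signal[c], params)
            band = sbs.real_subbands[subband_index - 1]
            rows[i, c * len(specs) : (c + 1) * len(specs)] = compute_feature_vector(
                band, specs
            )
    meta = pd.DataFrame(
        {
            "transform": transform_id,
            "subband": subband_index,
            "channel": np.repeat(np.arange(n_ch), len(specs)),
            "feature": list(s.name for s in specs) * n_ch,
        }
    )
    return FeatureMatrix(rows, np.array(segs.labels), meta)
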