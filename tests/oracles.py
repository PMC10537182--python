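"""Independent brute-force oracles for the feature and MI computations.

Everything here evaluates the defining formulas directly with plain Python
loops (no shared code with the package), so agreement is evidence the
vectorised implementations compute what they claim.
"""

from __future__ import annotations

import math

import numpy as np


def _mean(xs):
    return sum(xs) / len(xs)


def _sample_sd(xs):
    mu = _mean(xs)
    return math.sqrt(sum((v - mu) ** 2 for v in xs) / (len(xs) - 1))


def _slope(us, vs):
    """Least-squares slope of v on u."""
    ubar, vbar = _mean(us), _mean(vs)
    num = sum((u - ubar) * (v - vbar) for u, v in zip(us, vs))
    den = sum((u - ubar) ** 2 for u in us)
    return num / den


def _quartile(xs, p):
    """Linear-interpolation quantile."""
    s = sorted(xs)
    pos = (len(s) - 1) * p
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def o_std(x):
    return _sample_sd(list(x))


def o_average_energy(x):
    return sum(v * v for v in x) / len(x)


def o_wavelength(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def o_v_order(x, v=2.0):
    return (sum(abs(s) ** v for s in x) / len(x)) ** (1.0 / v)


def o_skewness(x):
    mu = _mean(list(x))
    m2 = sum((v - mu) ** 2 for v in x) / len(x)
    m3 = sum((v - mu) ** 3 for v in x) / len(x)
    return 0.0 if m2 == 0 else m3 / m2**1.5


def o_kurtosis(x):
    mu = _mean(list(x))
    m2 = sum((v - mu) ** 2 for v in x) / len(x)
    m4 = sum((v - mu) ** 4 for v in x) / len(x)
    return 0.0 if m2 == 0 else m4 / m2**2


def o_hjorth_mobility(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    vx = _sample_sd(list(x)) ** 2
    return 0.0 if vx == 0 else math.sqrt(_sample_sd(d) ** 2 / vx)


def o_dasdv(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    return math.sqrt(sum(v * v for v in d) / len(d))


def o_abs_sum_exp_root(x, power=0.75):
    return abs(sum(abs(v) ** power for v in x))


def o_abs_sum_sqrt(x):
    return abs(sum(abs(v) ** 0.5 for v in x))


def o_norm_first_diff(x):
    sd = _sample_sd(list(x))
    if sd == 0:
        return 0.0
    d = [abs(x[i + 1] - x[i]) for i in range(len(x) - 1)]
    return sum(d) / len(d) / sd


def o_norm_second_diff(x):
    sd = _sample_sd(list(x))
    if sd == 0:
        return 0.0
    g = [abs(x[i + 2] - x[i]) for i in range(len(x) - 2)]
    return sum(g) / len(g) / sd


def o_mean_sqrt(x):
    return sum(abs(v) ** 0.5 for v in x) / len(x)


def o_diff_variance(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    return _sample_sd(d) ** 2


def o_log_energy(x, floor=1e-12):
    return sum(math.log(v * v + floor) for v in x)


def o_abs_energy(x):
    return sum(v * v for v in x)


def o_ssi(x):
    return sum(abs(v) ** 2 for v in x)


def o_slope_sign_changes(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    return float(sum(1 for i in range(len(d) - 1) if d[i] * d[i + 1] < 0))


def o_peak_amplitude(x):
    return max(x)


def o_minima(x):
    return min(x)


def o_peak_to_peak(x):
    return max(x) - min(x)


def o_zero_crossing_rate(x):
    return sum(1 for i in range(len(x) - 1) if x[i] * x[i + 1] < 0) / (len(x) - 1)


def o_iqr(x):
    return _quartile(x, 0.75) - _quartile(x, 0.25)


def o_trimean(x):
    return (
        _quartile(x, 0.25) + 2 * _quartile(x, 0.5) + _quartile(x, 0.75)
    ) / 4.0


def o_higuchi_fd(x, kmax=10):
    N = len(x)
    lk, invk = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = list(range(m, N, k))
            if len(idx) < 2:
                continue
            dist = sum(abs(x[idx[i + 1]] - x[idx[i]]) for i in range(len(idx) - 1))
            norm = (N - 1) / (len(idx) - 1) / k
            lengths.append(dist * norm / k)
        if lengths and _mean(lengths) > 0:
            lk.append(math.log(_mean(lengths)))
            invk.append(math.log(1.0 / k))
    return _slope(invk, lk)


def _o_expected_rs(n):
    from scipy.special import gammaln

    s = sum(math.sqrt((n - i) / i) for i in range(1, n))
    if n <= 340:
        front = math.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / math.sqrt(math.pi)
    else:
        front = 1.0 / math.sqrt(n * math.pi / 2.0)
    return (n - 0.5) / n * front * s


def o_hurst(x, min_window=10, n_windows=10):
    N = len(x)
    raw = np.exp(np.linspace(np.log(min_window), np.log(N // 2), n_windows))
    sizes = sorted({int(math.floor(v)) for v in raw})
    log_rs, log_exp, log_n = [], [], []
    for n in sizes:
        rs_vals = []
        for b in range(N // n):
            block = list(x[b * n : (b + 1) * n])
            mu = _mean(block)
            dev = [v - mu for v in block]
            z, c = [], 0.0
            for v in dev:
                c += v
                z.append(c)
            sd = _sample_sd(block)
            if sd > 0:
                rs_vals.append((max(z) - min(z)) / sd)
        if rs_vals and _mean(rs_vals) > 0:
            log_rs.append(math.log(_mean(rs_vals)))
            log_exp.append(math.log(_o_expected_rs(n)))
            log_n.append(math.log(n))
    if len(log_n) < 2:
        return 0.5
    return 0.5 + _slope(log_n, [a - b for a, b in zip(log_rs, log_exp)])


def o_lyapunov(x, emb_dim=10, delay=1, fit_steps=20, max_samples=512):
    x = list(x[:max_samples])
    N = len(x)
    if _sample_sd(x) == 0:
        return 0.0
    mu = _mean(x)
    spec = np.abs(np.fft.rfft([v - mu for v in x])) ** 2
    freqs = np.fft.rfftfreq(N)
    denom = sum(f * p for f, p in zip(freqs, spec))
    mean_period = sum(spec) / denom if denom > 0 else N
    theiler = max(1, int(round(mean_period)))

    M = N - (emb_dim - 1) * delay
    if M < 2 * (theiler + 1) or M <= fit_steps + 2:
        return 0.0
    emb = [[x[i + j * delay] for j in range(emb_dim)] for i in range(M)]

    def dist(a, b):
        return math.sqrt(sum((u - v) ** 2 for u, v in zip(a, b)))

    nn = []
    for i in range(M):
        best, best_d = -1, float("inf")
        for j in range(M):
            if abs(i - j) <= theiler:
                continue
            d = dist(emb[i], emb[j])
            if d * d < best_d:
                best_d, best = d * d, j
        nn.append(best)

    steps = min(fit_steps, M - 1)
    mean_log, step_ids = [], []
    for j in range(steps):
        logs = []
        for i in range(M):
            if i + j < M and nn[i] + j < M:
                d = dist(emb[i + j], emb[nn[i] + j])
                if d > 0:
                    logs.append(math.log(d))
        if logs:
            mean_log.append(_mean(logs))
            step_ids.append(j)
    if len(step_ids) < 2:
        return 0.0
    return _slope(step_ids, mean_log)


FEATURE_ORACLES = {
    "std": o_std,
    "hurst": o_hurst,
    "average_energy": o_average_energy,
    "wavelength": o_wavelength,
    "v_order": o_v_order,
    "skewness": o_skewness,
    "kurtosis": o_kurtosis,
    "hjorth_mobility": o_hjorth_mobility,
    "higuchi_fd": o_higuchi_fd,
    "lyapunov": o_lyapunov,
    "dasdv": o_dasdv,
    "abs_sum_exp_root": o_abs_sum_exp_root,
    "abs_sum_sqrt": o_abs_sum_sqrt,
    "norm_first_diff": o_norm_first_diff,
    "norm_second_diff": o_norm_second_diff,
    "mean_sqrt": o_mean_sqrt,
    "diff_variance": o_diff_variance,
    "log_energy": o_log_energy,
    "abs_energy": o_abs_energy,
    "ssi": o_ssi,
    "slope_sign_changes": o_slope_sign_changes,
    "peak_amplitude": o_peak_amplitude,
    "minima": o_minima,
    "peak_to_peak": o_peak_to_peak,
    "zero_crossing_rate": o_zero_crossing_rate,
    "iqr": o_iqr,
    "trimean": o_trimean,
}


def brute_force_mi_bits(a, b) -> float:
    """Plug-in mutual information from joint counts, in bits."""
    a, b = list(a), list(b)
    n = len(a)
    pa, pb, pab = {}, {}, {}
    for u, v in zip(a, b):
        pa[u] = pa.get(u, 0) + 1
        pb[v] = pb.get(v, 0) + 1
        pab[(u, v)] = pab.get((u, v), 0) + 1
    mi = 0.0
    for (u, v), c in pab.items():
        p = c / n
        mi += p * math.log2(p / (pa[u] / n * pb[v] / n))
    return mi
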