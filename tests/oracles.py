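"""Independent brute-force oracles for the feature bank.

Deliberately straightforward implementations — explicit window loops,
direct moment formulas, normal-equation regressions — kept separate
from the package so tests compare two independently coded routes to
each quantity.  Inner sums use numpy so the full 50-epoch oracle sweep
stays fast, but the algorithmic structure is naive on purpose.
"""

from __future__ import annotations

import numpy as np


def kurtosis_bf(x):
    x = np.asarray(x, float)
    m = x.sum() / len(x)
    d = x - m
    m2 = (d**2).sum() / len(x)
    if m2 == 0:
        return 0.0
    m4 = (d**4).sum() / len(x)
    return m4 / m2**2


def skewness_bf(x):
    x = np.asarray(x, float)
    m = x.sum() / len(x)
    d = x - m
    m2 = (d**2).sum() / len(x)
    if m2 == 0:
        return 0.0
    m3 = (d**3).sum() / len(x)
    return m3 / m2**1.5


def amplitude_change_bf(x, w):
    best = 0.0
    for i in range(len(x) - w + 1):
        win = x[i : i + w]
        best = max(best, win.max() - win.min())
    return best


def mean_local_skew_bf(x, w):
    vals = []
    for i in range(0, len(x) - w + 1, w):
        vals.append(abs(skewness_bf(x[i : i + w])))
    return float(np.mean(vals))


def amplitude_variance_bf(x):
    p = np.asarray(x, float) ** 2
    m = p.sum() / len(p)
    return float(((p - m) ** 2).sum() / len(p))


def derivative_sum_bf(x, w):
    """Sum the first differences inside each window, the long way round."""
    av = amplitude_variance_bf(x)
    if av == 0:
        return 0.0
    d = np.diff(x)
    best = 0.0
    for i in range(len(x) - w + 1):
        best = max(best, abs(d[i : i + w - 1].sum()))
    return best / av


def band_power_bf(freqs, power, lo, hi):
    df = freqs[1] - freqs[0]
    total = 0.0
    for f, p in zip(freqs, power):
        if lo <= f < hi:
            total += p * df
    return total


def spectral_fit_bf(freqs, power, lo, hi):
    """Normal-equation simple linear regression of log10 P on log10 f."""
    keep = [(f, p) for f, p in zip(freqs, power) if lo <= f < hi and f > 0 and p > 0]
    if len(keep) < 3:
        return 0.0, 0.0, 0.0
    xs = np.log10([f for f, _ in keep])
    ys = np.log10([p for _, p in keep])
    sxx = np.mean(xs * xs) - np.mean(xs) ** 2
    sxy = np.mean(xs * ys) - np.mean(xs) * np.mean(ys)
    slope = sxy / sxx
    intercept = np.mean(ys) - slope * np.mean(xs)
    resid = ys - (slope * xs + intercept)
    return slope, intercept, float(np.sqrt(np.mean(resid**2)))


def katz_bf(x):
    x = np.asarray(x, float)
    n = len(x) - 1
    length = float(np.abs(x[1:] - x[:-1]).sum())
    diam = float(np.abs(x - x[0]).max())
    if length == 0 or diam == 0:
        return 1.0
    return np.log10(n) / (np.log10(n) + np.log10(diam / length))


def higuchi_bf(x, k_max=8):
    """Higuchi curve-length estimator, written from the definition."""
    x = np.asarray(x, float)
    n = len(x)
    logs = []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            n_int = (n - m - 1) // k
            if n_int < 1:
                continue
            pts = x[m : m + n_int * k + 1 : k]
            total = float(np.abs(pts[1:] - pts[:-1]).sum())
            lengths.append(total * (n - 1) / (n_int * k) / k)
        if lengths:
            logs.append((np.log(1.0 / k), np.log(np.mean(lengths))))
    xs = np.array([p[0] for p in logs])
    ys = np.array([p[1] for p in logs])
    sxx = np.mean(xs * xs) - np.mean(xs) ** 2
    return float((np.mean(xs * ys) - np.mean(xs) * np.mean(ys)) / sxx)


def fd_series_bf(x, fs, estimator, win_s=0.1, overlap=0.5):
    w = int(round(win_s * fs))
    step = int(round(w * (1 - overlap)))
    return np.array([estimator(x[s : s + w]) for s in range(0, len(x) - w + 1, step)])


def haar_details_bf(x):
    """Manual average/difference pyramid, edge-padded to a power of two."""
    x = list(np.asarray(x, float))
    n2 = 1
    while n2 < len(x):
        n2 *= 2
    x = x + [x[-1]] * (n2 - len(x))
    details = []
    approx = x
    while len(approx) > 1:
        nxt, det = [], []
        for i in range(0, len(approx), 2):
            nxt.append((approx[i] + approx[i + 1]) / np.sqrt(2))
            det.append((approx[i] - approx[i + 1]) / np.sqrt(2))
        details.append(det)
        approx = nxt
    return np.concatenate([np.asarray(d) for d in details])


def auc_pair_counting(posteriors, truth):
    """AUC as the fraction of correctly ordered (artefact, clean) pairs."""
    pos = [p for p, t in zip(posteriors, truth) if t == 1]
    neg = [p for p, t in zip(posteriors, truth) if t == 0]
    wins = 0.0
    for a in pos:
        for c in neg:
            if a > c:
                wins += 1.0
            elif a == c:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def feature_vector_bf(epoch, bands, deriv_windows_ms):
    """The whole 31-feature vector by the brute-force route."""
    from epochsift.features import periodogram  # shared input spectrum

    x = epoch.samples
    fs = epoch.fs
    spec = periodogram(epoch)
    out = {
        "amplitude_change_50ms": amplitude_change_bf(x, int(round(0.05 * fs))),
        "mean_local_skew_15ms": mean_local_skew_bf(x, int(round(0.015 * fs))),
        "temporal_kurtosis": kurtosis_bf(x),
        "amplitude_variance": amplitude_variance_bf(x),
    }
    for w_ms in deriv_windows_ms:
        out[f"deriv_sum_{w_ms}ms"] = derivative_sum_bf(
            x, int(round(w_ms / 1000 * fs))
        )
    out["power_below_0p5hz"] = band_power_bf(
        spec.freqs[1:], spec.power[1:], 0.0, 0.5
    )
    for name, (lo, hi) in bands.items():
        out[f"bandpower_{name}"] = band_power_bf(spec.freqs, spec.power, lo, hi)
        lam, _c, err = spectral_fit_bf(spec.freqs, spec.power, lo, hi)
        out[f"lambda_{name}"] = lam
        out[f"fiterror_{name}"] = err
    out["fd_kurtosis_higuchi"] = kurtosis_bf(fd_series_bf(x, fs, higuchi_bf))
    out["fd_kurtosis_katz"] = kurtosis_bf(fd_series_bf(x, fs, katz_bf))
    out["haar_kurtosis"] = kurtosis_bf(haar_details_bf(x))
    return out
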