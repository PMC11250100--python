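"""The 31-scalar feature bank computed per epoch.

Time-domain descriptors (amplitude change, local skewness, kurtosis,
amplitude variance, windowed derivative sums), spectral descriptors per
EEG band (band power, power-law slope lambda and its fit error, from a
whole-epoch rectangular periodogram), sub-0.5 Hz power, the kurtosis of
sliding-window fractal-dimension series (Higuchi and Katz estimators)
and the kurtosis of the full Haar wavelet detail coefficients.

Conventions used throughout:

* kurtosis is Pearson's (a normal distribution scores 3);
* moments are population moments (``ddof = 0``);
* any feature whose defining moment is degenerate (0/0) returns 0,
  never NaN, so downstream ensembles are total functions.

The canonical feature order is frozen in ``feature_manifest.json``;
feature tables and trained models carry it and refuse mismatches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sp_signal

from .epoch_io import Epoch

logger = logging.getLogger(__name__)

#: EEG frequency bands in Hz, half-open [lo, hi).  ``broadband`` covers
#: the whole spectrum above 2 Hz, below which EEG departs from a power law.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.2, 3.5),
    "theta": (4.0, 7.5),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 70.0),
    "broadband": (2.0, 70.0),
}

DERIV_WINDOWS_MS = (50, 100, 200, 300, 500)

FEATURE_NAMES: tuple[str, ...] = (
    "amplitude_change_50ms",
    "mean_local_skew_15ms",
    "temporal_kurtosis",
    "amplitude_variance",
    *(f"deriv_sum_{w}ms" for w in DERIV_WINDOWS_MS),
    "power_below_0p5hz",
    *(f"{kind}_{band}" for band in BANDS for kind in ("bandpower", "lambda", "fiterror")),
    "fd_kurtosis_higuchi",
    "fd_kurtosis_katz",
    "haar_kurtosis",
)

MANIFEST_VERSION = "1"

#: Zero-padding factor for the periodogram frequency grid.  A 1.5 s
#: epoch has a native resolution of 0.67 Hz, too coarse to resolve the
#: sub-0.5 Hz band; padding refines the grid without changing total power.
PERIODOGRAM_OVERSAMPLE = 8


def load_manifest() -> dict:
    """The shipped feature manifest (version + canonical order)."""
    with resources.files("epochsift").joinpath("feature_manifest.json").open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# moment helpers (population convention, degenerate -> 0)

def _kurtosis(x: np.ndarray) -> float:
    """Pearson kurtosis m4/m2^2; 0 when the variance is degenerate."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 <= 0 or not np.isfinite(m2):
        return 0.0
    return float(np.mean((x - m) ** 4) / m2**2)


def _skewness(x: np.ndarray) -> float:
    """Population sample skewness m3/m2^1.5; 0 when degenerate."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 <= 0:
        return 0.0
    return float(np.mean((x - m) ** 3) / m2**1.5)


def _window_len(window_s: float, fs: float) -> int:
    w = int(round(window_s * fs))
    if w < 2:
        raise ValueError(f"window {window_s} s too short at fs={fs}")
    return w


# ---------------------------------------------------------------------------
# time-domain features

def amplitude_change(epoch: Epoch, window_s: float = 0.05) -> float:
    """Maximum peak-to-peak amplitude change over any ``window_s`` period (µV)."""
    x = epoch.samples
    w = _window_len(window_s, epoch.fs)
    if w > len(x):
        raise ValueError("window longer than epoch")
    views = sliding_window_view(x, w)
    return float(np.max(views.max(axis=1) - views.min(axis=1)))


def mean_local_skewness(epoch: Epoch, seg_s: float = 0.015) -> float:
    """Mean absolute skewness over contiguous non-overlapping segments.

    A trailing partial segment is dropped; zero-variance segments
    contribute 0.
    """
    x = epoch.samples
    w = _window_len(seg_s, epoch.fs)
    n_seg = len(x) // w
    if n_seg < 1:
        raise ValueError("epoch shorter than one segment")
    segs = x[: n_seg * w].reshape(n_seg, w)
    return float(np.mean([abs(_skewness(s)) for s in segs]))


def temporal_kurtosis(epoch: Epoch) -> float:
    """Pearson kurtosis of the full voltage series."""
    return _kurtosis(epoch.samples)


def amplitude_variance(epoch: Epoch) -> float:
    """Variance of the point-wise signal power x²(t), in µV⁴."""
    x = epoch.samples
    return float(np.var(x * x))


def derivative_sum(epoch: Epoch, window_s: float) -> float:
    """Max absolute summed derivative in a window, over amplitude variance.

    The sum of first differences inside a window telescopes to the net
    change across it, so this is the sliding maximum of
    ``|x[i+w-1] - x[i]|`` normalised by :func:`amplitude_variance`;
    0 when that variance is 0.
    """
    x = epoch.samples
    w = _window_len(window_s, epoch.fs)
    if w > len(x):
        raise ValueError("window longer than epoch")
    av = amplitude_variance(epoch)
    if av == 0.0:
        return 0.0
    net = np.abs(x[w - 1 :] - x[: len(x) - w + 1])
    return float(net.max() / av)


# ---------------------------------------------------------------------------
# spectral features

@dataclass
class Spectrum:
    """One-sided PSD in µV²/Hz on a strictly increasing frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def periodogram(epoch: Epoch, oversample: int = PERIODOGRAM_OVERSAMPLE) -> Spectrum:
    """Whole-epoch rectangular-window periodogram (FFT-based).

    The FFT is zero-padded by ``oversample`` to refine the frequency
    grid.  The signal mean is removed before padding and its power
    restored at the DC bin, so a DC offset cannot leak into the
    low-frequency bins; Parseval's identity (integral of the PSD =
    mean squared amplitude) holds exactly either way.
    """
    x = epoch.samples
    nfft = len(x) * max(1, int(oversample))
    mean = float(x.mean())
    freqs, power = sp_signal.periodogram(
        x - mean, fs=epoch.fs, window="boxcar", nfft=nfft, detrend=False,
        scaling="density",
    )
    power = power.copy()
    power[0] += mean**2 * nfft / epoch.fs  # mean power / df, at DC only
    return Spectrum(freqs=freqs, power=power)


def band_power(spec: Spectrum, band: tuple[float, float]) -> float:
    """Integral of the PSD over bins with centre frequency in [lo, hi) µV²."""
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs < hi)
    if not mask.any():
        logger.warning("band [%g, %g) Hz empty at this resolution; power 0", lo, hi)
        return 0.0
    return float(spec.power[mask].sum() * spec.df)


def power_below_0p5hz(spec: Spectrum) -> float:
    """Total power in 0 < f < 0.5 Hz (DC bin excluded), in µV²."""
    mask = (spec.freqs > 0) & (spec.freqs < 0.5)
    if not mask.any():
        logger.warning("no bins below 0.5 Hz at this resolution; power 0")
        return 0.0
    return float(spec.power[mask].sum() * spec.df)


def spectral_fit(
    spec: Spectrum, band: tuple[float, float]
) -> tuple[float, float, float]:
    """Least-squares power-law fit of the PSD inside a band.

    Fits log10(power) = lambda * log10(f) + C over bins in [lo, hi)
    with f > 0 and power > 0.  Returns ``(lambda, C, fit_error)`` where
    ``fit_error`` is the RMSE of the residuals in log-power units.
    Fewer than 3 usable bins yields ``(0, 0, 0)`` with a warning.
    """
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs < hi) & (spec.freqs > 0) & (spec.power > 0)
    if mask.sum() < 3:
        logger.warning("band [%g, %g) Hz has <3 usable bins; fit (0, 0, 0)", lo, hi)
        return 0.0, 0.0, 0.0
    logf = np.log10(spec.freqs[mask])
    logp = np.log10(spec.power[mask])
    slope, intercept = np.polyfit(logf, logp, 1)
    resid = logp - (slope * logf + intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return float(slope), float(intercept), rmse


# ---------------------------------------------------------------------------
# fractal dimension

def higuchi_fd(x: np.ndarray, k_max: int = 8) -> float:
    """Higuchi fractal dimension of a short series.

    Builds k-decimated curve lengths L(k) and returns the slope of
    log L(k) against log(1/k).  A flat series returns 1.0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    lks = []
    ks = []
    for k in range(1, k_max + 1):
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            n_int = len(idx) - 1
            length = np.abs(np.diff(x[idx])).sum() * (n - 1) / (n_int * k) / k
            lm.append(length)
        if lm:
            lks.append(np.mean(lm))
            ks.append(k)
    lks = np.asarray(lks)
    if np.any(lks <= 0):  # flat (sub)series
        return 1.0
    slope = np.polyfit(np.log(1.0 / np.asarray(ks)), np.log(lks), 1)[0]
    return float(slope)


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension: D = log10(n) / (log10(n) + log10(d/L)).

    ``L`` is the summed absolute first difference (waveform length),
    ``d`` the maximum excursion from the first point, ``n`` the number
    of steps.  A straight segment scores exactly 1.
    """
    x = np.asarray(x, dtype=float)
    n = len(x) - 1
    if n < 1:
        return 1.0
    length = np.abs(np.diff(x)).sum()
    diameter = np.abs(x - x[0]).max()
    if length <= 0 or diameter <= 0:
        return 1.0
    return float(np.log10(n) / (np.log10(n) + np.log10(diameter / length)))


def fd_series(
    epoch: Epoch, method: str, fd_window_s: float = 0.1, overlap: float = 0.5,
    k_max: int = 8,
) -> np.ndarray:
    """Fractal dimension in sliding windows (default 100 ms, 50 % overlap)."""
    est = {"higuchi": lambda w: higuchi_fd(w, k_max), "katz": katz_fd}
    if method not in est:
        raise ValueError(f"unknown FD method {method!r}")
    x = epoch.samples
    w = _window_len(fd_window_s, epoch.fs)
    step = max(1, int(round(w * (1.0 - overlap))))
    starts = range(0, len(x) - w + 1, step)
    fds = np.array([est[method](x[s : s + w]) for s in starts])
    if len(fds) < 4:
        raise ValueError("need at least 4 FD windows")
    return fds


def fd_kurtosis(
    epoch: Epoch, method: str, fd_window_s: float = 0.1, overlap: float = 0.5
) -> float:
    """Pearson kurtosis of the sliding-window FD series; degenerate -> 0."""
    return _kurtosis(fd_series(epoch, method, fd_window_s, overlap))


# ---------------------------------------------------------------------------
# wavelets

def haar_details(x: np.ndarray) -> np.ndarray:
    """All detail coefficients of a full-depth Haar decomposition.

    The series is padded to the next power of two with its final value
    (edge padding, so padding itself introduces no detail); level-1
    details equal (x[2i] - x[2i+1]) / sqrt(2).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    n2 = 1 << int(np.ceil(np.log2(len(x))))
    padded = np.full(n2, x[-1])
    padded[: len(x)] = x
    coeffs = pywt.wavedec(padded, "haar")
    return np.concatenate(coeffs[1:][::-1])  # details, finest level first


def haar_kurtosis(epoch: Epoch) -> float:
    """Pearson kurtosis of the concatenated Haar detail coefficients."""
    return _kurtosis(haar_details(epoch.samples))


# ---------------------------------------------------------------------------
# the full bank

def extract_all(epoch: Epoch) -> dict[str, float]:
    """Compute the full 31-feature vector in canonical manifest order."""
    spec = periodogram(epoch)
    out: dict[str, float] = {
        "amplitude_change_50ms": amplitude_change(epoch),
        "mean_local_skew_15ms": mean_local_skewness(epoch),
        "temporal_kurtosis": temporal_kurtosis(epoch),
        "amplitude_variance": amplitude_variance(epoch),
    }
    for w_ms in DERIV_WINDOWS_MS:
        out[f"deriv_sum_{w_ms}ms"] = derivative_sum(epoch, w_ms / 1000.0)
    out["power_below_0p5hz"] = power_below_0p5hz(spec)
    for band_name, band in BANDS.items():
        lam, _c, err = spectral_fit(spec, band)
        out[f"bandpower_{band_name}"] = band_power(spec, band)
        out[f"lambda_{band_name}"] = lam
        out[f"fiterror_{band_name}"] = err
    out["fd_kurtosis_higuchi"] = fd_kurtosis(epoch, "higuchi")
    out["fd_kurtosis_katz"] = fd_kurtosis(epoch, "katz")
    out["haar_kurtosis"] = haar_kurtosis(epoch)
    assert tuple(out.keys()) == FEATURE_NAMES
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise AssertionError(f"non-finite features {bad}")
    return out


def extract_table(epochs: list[Epoch]) -> "np.ndarray":
    """Feature matrix (n_epochs x 31) in canonical order."""
    return np.array([list(extract_all(ep).values()) for ep in epochs])
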