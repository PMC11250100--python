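"""Signal conditioning: non-causal windowed-sinc FIR filtering and epoching.

The canonical chain band-passes the continuous recording to 0.1–70 Hz,
applies a 49–51 Hz band-stop against mains interference, then cuts a
1.5 s epoch (−0.5 s to +1 s) around each stimulus.  Filters are
linear-phase symmetric FIR kernels applied centred (zero phase).

A 0.1 Hz low edge demands a kernel far longer than one epoch, so
filtering is done on the continuous recording whenever one is
available.  For stand-alone epochs a relaxed low edge (default 0.5 Hz)
with reflection padding is offered instead, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .epoch_io import Epoch, Recording

logger = logging.getLogger(__name__)

#: Hamming-window transition widths in Hz (low edge, high edge, band-stop).
DEFAULT_TRANSITIONS = {"low": 0.1, "high": 5.0, "stop": 1.0}

#: Relaxed band-pass low edge used when only stand-alone epochs exist.
EPOCH_RELAXED_LOW_HZ = 0.5


@dataclass(frozen=True)
class FilterSpec:
    """A band-pass or band-stop FIR specification."""

    kind: str  # "bandpass" | "bandstop"
    low_hz: float
    high_hz: float
    transition_hz: float | tuple[float, float] = 1.0
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "bandstop"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")

    @property
    def transitions(self) -> tuple[float, float]:
        t = self.transition_hz
        return (t, t) if np.isscalar(t) else tuple(t)  # type: ignore[return-value]


def _numtaps(transition_hz: float, fs: float) -> int:
    """Odd Hamming-window kernel length for a given transition width."""
    n = int(np.ceil(3.3 * fs / transition_hz))
    return n + 1 if n % 2 == 0 else n


def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design a linear-phase symmetric FIR kernel for ``spec`` at ``fs``.

    A band-pass is built as the convolution of a high-pass (narrow
    transition at the low edge) and a low-pass (wide transition at the
    high edge), so the two edges can have independent transition widths.
    """
    if spec.high_hz >= fs / 2:
        raise ValueError(f"high edge {spec.high_hz} Hz >= Nyquist {fs / 2} Hz")
    t_lo, t_hi = spec.transitions
    if spec.kind == "bandpass":
        # high-pass by spectral inversion of a unity-DC low-pass, so the
        # band-pass blocks DC exactly
        lp_low = signal.firwin(
            _numtaps(t_lo, fs), spec.low_hz, window=spec.window,
            pass_zero=True, fs=fs,
        )
        hp = -lp_low
        hp[len(hp) // 2] += 1.0
        lp = signal.firwin(
            _numtaps(t_hi, fs), spec.high_hz, window=spec.window,
            pass_zero=True, fs=fs,
        )
        kernel = np.convolve(hp, lp)
    else:
        kernel = signal.firwin(
            _numtaps(t_lo, fs), [spec.low_hz, spec.high_hz], window=spec.window,
            pass_zero=True, fs=fs,
        )
    return kernel


def frequency_response(kernel: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Magnitude response of ``kernel`` at ``freqs`` (Hz)."""
    _, h = signal.freqz(kernel, worN=np.asarray(freqs, dtype=float), fs=fs)
    return np.abs(h)


def filter_signal(samples: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR kernel with zero phase and no length change.

    The input is reflection-padded by half the kernel length (repeated
    reflection when the kernel outgrows the signal), convolved, and
    trimmed, so an in-band sinusoid emerges with zero measured delay.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 3:
        raise ValueError("need at least 3 samples to filter")
    half = len(kernel) // 2
    pad = half
    x = samples
    while pad > 0:
        chunk = min(pad, len(x) - 1 if len(x) > 1 else 1)
        left = x[1 : chunk + 1][::-1]
        right = x[-chunk - 1 : -1][::-1]
        x = np.concatenate([left, x, right])
        pad -= chunk
    y = signal.fftconvolve(x, kernel, mode="same")
    start = (len(x) - len(samples)) // 2
    return y[start : start + len(samples)]


def bandpass_bandstop(
    samples: np.ndarray,
    fs: float,
    low_hz: float = 0.1,
    high_hz: float = 70.0,
    notch: tuple[float, float] | None = (49.0, 51.0),
) -> np.ndarray:
    """The canonical conditioning chain on a continuous signal."""
    bp = design_fir(
        FilterSpec("bandpass", low_hz, high_hz,
                   (DEFAULT_TRANSITIONS["low"], DEFAULT_TRANSITIONS["high"])),
        fs,
    )
    out = filter_signal(samples, bp)
    if notch is not None:
        bs = design_fir(
            FilterSpec("bandstop", notch[0], notch[1], DEFAULT_TRANSITIONS["stop"]),
            fs,
        )
        out = filter_signal(out, bs)
    return out


def preprocess_recording(
    rec: Recording,
    low_hz: float = 0.1,
    high_hz: float = 70.0,
    notch: tuple[float, float] | None = (49.0, 51.0),
) -> Recording:
    """Filter a continuous recording in place of the acquisition chain."""
    filtered = bandpass_bandstop(rec.samples, rec.fs, low_hz, high_hz, notch)
    return Recording(
        samples=filtered, fs=rec.fs, events=list(rec.events),
        channel_name=rec.channel_name, infant_id=rec.infant_id,
        age_group=rec.age_group,
    )


def preprocess_epoch(
    epoch: Epoch,
    low_hz: float = EPOCH_RELAXED_LOW_HZ,
    high_hz: float = 70.0,
    notch: tuple[float, float] | None = (49.0, 51.0),
) -> Epoch:
    """Relaxed conditioning for a stand-alone epoch (no continuous data).

    The low edge defaults to 0.5 Hz because a 0.1 Hz edge needs a kernel
    much longer than the epoch itself; a warning notes the divergence
    from the continuous-data chain.
    """
    if low_hz < EPOCH_RELAXED_LOW_HZ:
        logger.warning(
            "epoch-mode low edge %.2f Hz below the relaxed default; kernel "
            "greatly exceeds the epoch length", low_hz,
        )
    logger.warning(
        "filtering a stand-alone epoch (relaxed %.2f Hz low edge, reflection "
        "padding); the canonical chain filters continuous recordings", low_hz,
    )
    return epoch.with_samples(
        bandpass_bandstop(epoch.samples, epoch.fs, low_hz, high_hz, notch)
    )


def extract_epochs(
    rec: Recording, pre_s: float = 0.5, post_s: float = 1.0
) -> list[Epoch]:
    """Cut one epoch per event: ``pre_s`` before to ``post_s`` after.

    The event maps to the first sample with time >= event time
    (half-open convention).  Events too close to an edge are skipped
    with a logged warning, never fatally.
    """
    n_epoch = int(round((pre_s + post_s) * rec.fs))
    n_pre = int(round(pre_s * rec.fs))
    epochs: list[Epoch] = []
    for t, stim in rec.events:
        idx = int(np.ceil(t * rec.fs - 1e-9))  # first sample at/after t
        start = idx - n_pre
        if start < 0 or start + n_epoch > len(rec.samples):
            logger.warning(
                "event at %.3f s too close to a recording edge; skipped", t
            )
            continue
        epochs.append(
            Epoch(
                samples=rec.samples[start : start + n_epoch].copy(),
                fs=rec.fs,
                event_offset=pre_s,
                stimulus=stim,
                infant_id=rec.infant_id,
                age_group=rec.age_group,
            )
        )
    return epochs


def first_stimulus_only(epochs: list[Epoch]) -> list[Epoch]:
    """Keep at most one epoch per (infant, stimulus): the earliest seen.

    Limits inter-subject variation so each infant contributes a single
    epoch per stimulus type; input order is preserved.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[Epoch] = []
    for ep in epochs:
        key = (ep.infant_id, ep.stimulus)
        if key not in seen:
            seen.add(key)
            kept.append(ep)
    return kept
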