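"""Synthetic neonatal ERP epochs, artefacts and rater panels.

Emulates the statistical shape of the data the detector assumes: 1.5 s
single-channel epochs at 2 kHz with the stimulus at +0.5 s, a 1/f-like
background, a Gaussian-windowed evoked deflection, artefact classes of
both high-variance (movement burst, step, mains breakthrough, spike)
and low-variance (detachment flatline, slow drift) kinds, and a
seven-rater panel whose members flip the ground truth independently at
tier-specific error rates.

The default panel error rates (7.5 % for the three expert raters,
14.5 % for the four experienced raters, at 21 % artefact prevalence)
are chosen so that within-tier pairwise Cohen's kappa sits near 0.61
and 0.40 respectively — the agreement levels reported for real expert
and experienced raters of this kind of data.

Rater errors are independent across raters and epochs; real raters
correlate, so closed-form kappa is only claimed under this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import RaterMatrix
from .epoch_io import AGE_GROUPS, STIMULI, Epoch, Recording

ARTEFACT_KINDS = (
    "movement_burst",
    "step",
    "mains_50hz",
    "flatline",
    "slow_drift",
    "spike",
)

#: Default artefact mix: absolute epoch-level probabilities per kind,
#: summing to 0.21 (the artefact prevalence seen in rater-labelled
#: training data of this kind); the remainder of epochs stay clean.
DEFAULT_ARTEFACT_MIX: dict[str, float] = {
    "movement_burst": 0.05,
    "step": 0.03,
    "mains_50hz": 0.03,
    "flatline": 0.04,
    "slow_drift": 0.03,
    "spike": 0.03,
}


@dataclass(frozen=True)
class Rater:
    rater_id: str
    tier: str  # "experienced" | "expert"
    fp_rate: float  # P(label artefact | truth clean)
    fn_rate: float  # P(label clean | truth artefact)


#: Seven-rater default panel: A-D experienced, E-G expert.
DEFAULT_PANEL: tuple[Rater, ...] = tuple(
    [Rater(r, "experienced", 0.145, 0.145) for r in "ABCD"]
    + [Rater(r, "expert", 0.075, 0.075) for r in "EFG"]
)


@dataclass
class GeneratorSpec:
    """Study conditions for the generator; the seed is mandatory."""

    seed: int
    fs: float = 2000.0
    epoch_s: float = 1.5
    event_offset: float = 0.5
    background_exponent: float = 1.0  # 1/f^exponent PSD
    background_rms: float = 20.0  # µV
    erp_amplitude: float = 30.0  # µV peak
    erp_latency: float = 0.4  # s post-stimulus
    erp_width: float = 0.2  # s
    artefact_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARTEFACT_MIX)
    )
    panel: tuple[Rater, ...] = DEFAULT_PANEL

    def __post_init__(self) -> None:
        unknown = set(self.artefact_mix) - set(ARTEFACT_KINDS)
        if unknown:
            raise ValueError(f"unknown artefact kinds {sorted(unknown)}")
        if sum(self.artefact_mix.values()) > 1.0 + 1e-12:
            raise ValueError("artefact probabilities must sum to <= 1")
        for r in self.panel:
            if not (0 <= r.fp_rate < 0.5 and 0 <= r.fn_rate < 0.5):
                raise ValueError("rater error rates must be in [0, 0.5)")

    @property
    def prevalence(self) -> float:
        return float(sum(self.artefact_mix.values()))

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_s * self.fs))


# ---------------------------------------------------------------------------
# clean epochs

def one_over_f_noise(
    n: int, fs: float, exponent: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Coloured noise with PSD proportional to 1/f^exponent, scaled to rms (µV)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    x_rms = np.sqrt(np.mean(x * x))
    return x * (rms / x_rms) if x_rms > 0 else x


def erp_waveform(spec: GeneratorSpec, amplitude: float | None = None) -> np.ndarray:
    """Gaussian-windowed half-sine deflection, peak = amplitude µV."""
    amp = spec.erp_amplitude if amplitude is None else amplitude
    t = np.arange(spec.n_samples) / spec.fs - spec.event_offset
    centre = spec.erp_latency
    width = spec.erp_width
    half_sine = np.where(
        np.abs(t - centre) < width,
        np.sin(np.pi * (t - centre + width) / (2 * width)),
        0.0,
    )
    gauss = np.exp(-((t - centre) ** 2) / (2 * (width / 2) ** 2))
    wave = half_sine * gauss
    peak = np.max(np.abs(wave))
    return amp * wave / peak if peak > 0 else wave


def gen_clean_epoch(
    spec: GeneratorSpec,
    rng: np.random.Generator,
    stimulus: str = "auditory",
    infant_id: str = "",
    age_group: str = "term",
) -> Epoch:
    """Background 1/f noise plus an evoked deflection (none for background)."""
    x = one_over_f_noise(
        spec.n_samples, spec.fs, spec.background_exponent, spec.background_rms, rng
    )
    if stimulus != "background" and spec.erp_amplitude > 0:
        x = x + erp_waveform(spec)
    return Epoch(
        samples=x,
        fs=spec.fs,
        event_offset=spec.event_offset,
        stimulus=stimulus,
        infant_id=infant_id,
        age_group=age_group,
    )


# ---------------------------------------------------------------------------
# artefact injection

def inject_artefact(
    epoch: Epoch,
    kind: str,
    rng: np.random.Generator,
    severity: float = 1.0,
) -> Epoch:
    """Superimpose (or, for flatline, suppress) one artefact class.

    At default severity each kind measurably shifts its designated
    feature: mains breakthrough multiplies gamma band power, detachment
    divides the amplitude variance, drift multiplies the sub-0.5 Hz
    power, and burst/step/spike multiply the 50 ms amplitude change.
    ``severity = 0`` returns the epoch unchanged.
    """
    if kind not in ARTEFACT_KINDS:
        raise ValueError(f"unknown artefact kind {kind!r}")
    if severity < 0:
        raise ValueError("severity must be >= 0")
    if severity == 0:
        return epoch.with_samples(epoch.samples.copy())
    x = epoch.samples.copy()
    n, fs = len(x), epoch.fs
    rms = np.sqrt(np.mean(x * x)) or 1.0
    if kind == "movement_burst":
        dur = int(round(0.3 * fs))
        start = int(rng.integers(0, n - dur))
        burst = one_over_f_noise(dur, fs, 0.5, severity * 6.0 * rms, rng)
        burst *= np.hanning(dur)
        x[start : start + dur] += burst
    elif kind == "step":
        at = int(rng.integers(n // 10, n - n // 10))
        x[at:] += severity * 20.0 * rms * (1 if rng.random() < 0.5 else -1)
    elif kind == "mains_50hz":
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        x += severity * 1.5 * rms * np.sin(2 * np.pi * 50.0 * t + phase)
    elif kind == "flatline":
        # electrode detachment: signal collapses towards sensor noise
        atten = max(0.0, 1.0 - 0.98 * min(severity, 1.0))
        x *= atten
        x += 0.01 * rms * rng.standard_normal(n)
    elif kind == "slow_drift":
        t = np.arange(n) / fs
        f_drift = rng.uniform(0.15, 0.35)
        phase = rng.uniform(0, 2 * np.pi)
        x += severity * 8.0 * rms * np.sin(2 * np.pi * f_drift * t + phase)
    elif kind == "spike":
        dur = max(3, int(round(0.005 * fs)))
        start = int(rng.integers(0, n - dur))
        x[start : start + dur] += severity * 20.0 * rms * np.hanning(dur)
    return epoch.with_samples(x)


# ---------------------------------------------------------------------------
# rater simulation

def simulate_raters(
    truths: np.ndarray, panel: tuple[Rater, ...], rng: np.random.Generator
) -> RaterMatrix:
    """Independent per-rater flips of the ground truth."""
    truths = np.asarray(truths).astype(int)
    cols = []
    for r in panel:
        u = rng.random(len(truths))
        flip_rate = np.where(truths == 1, r.fn_rate, r.fp_rate)
        cols.append(np.where(u < flip_rate, 1 - truths, truths))
    return RaterMatrix(
        labels=np.column_stack(cols),
        rater_ids=[r.rater_id for r in panel],
        rater_tiers=[r.tier for r in panel],
    )


def expected_kappa(a: Rater, b: Rater, prevalence: float) -> float:
    """Closed-form Cohen's kappa for two independent-flip raters.

    Valid only under the generator's independence assumption: each
    rater flips the truth independently with their own fp/fn rates.
    """
    pi = prevalence
    p_o = pi * ((1 - a.fn_rate) * (1 - b.fn_rate) + a.fn_rate * b.fn_rate) + (
        1 - pi
    ) * ((1 - a.fp_rate) * (1 - b.fp_rate) + a.fp_rate * b.fp_rate)
    pa = pi * (1 - a.fn_rate) + (1 - pi) * a.fp_rate
    pb = pi * (1 - b.fn_rate) + (1 - pi) * b.fp_rate
    p_e = pa * pb + (1 - pa) * (1 - pb)
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# full datasets

#: Epoch counts per (age group, stimulus) emulating a balanced neonatal
#: multimodal registry: 410 epochs over three age groups and seven
#: stimulus types.
DEFAULT_GRID: dict[tuple[str, str], int] = {
    ("premature1", "background"): 18, ("premature2", "background"): 9,  ("term", "background"): 31,
    ("premature1", "auditory"): 14,   ("premature2", "auditory"): 16,   ("term", "auditory"): 31,
    ("premature1", "visual"): 13,     ("premature2", "visual"): 14,     ("term", "visual"): 24,
    ("premature1", "tactile"): 13,    ("premature2", "tactile"): 13,    ("term", "tactile"): 27,
    ("premature1", "experimental_noxious"): 10, ("premature2", "experimental_noxious"): 11, ("term", "experimental_noxious"): 39,
    ("premature1", "control_lance"): 18, ("premature2", "control_lance"): 10, ("term", "control_lance"): 35,
    ("premature1", "heel_lance"): 19,  ("premature2", "heel_lance"): 10,  ("term", "heel_lance"): 35,
}

#: Infants available per age group (160 total for the default grid).
DEFAULT_INFANTS_PER_GROUP: dict[str, int] = {
    "premature1": 41,
    "premature2": 32,
    "term": 87,
}


def gen_dataset(
    spec: GeneratorSpec,
    grid: dict[tuple[str, str], int] | None = None,
    infants_per_group: dict[str, int] | None = None,
):
    """Generate a full labelled dataset with a subject registry.

    Each infant contributes at most one epoch per stimulus type (the
    first-stimulus rule is pre-satisfied), artefacts are drawn from the
    spec's mix, and a rater panel labels every epoch.  Returns
    ``(epochs, truths, rater_matrix, registry)`` where the registry is
    a list of dicts with infant_id / age_group / stimulus / artefact
    kind per epoch, in epoch order.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    infants_per_group = dict(
        DEFAULT_INFANTS_PER_GROUP if infants_per_group is None else infants_per_group
    )
    rng = np.random.default_rng(spec.seed)
    for (group, stim), count in grid.items():
        if group not in AGE_GROUPS or stim not in STIMULI:
            raise ValueError(f"bad grid cell {(group, stim)}")
        if count > infants_per_group.get(group, 0):
            raise ValueError(
                f"{count} {stim} epochs need {count} distinct {group} infants, "
                f"only {infants_per_group.get(group, 0)} available"
            )

    infants = {
        g: [f"{g}_{i:03d}" for i in range(infants_per_group[g])]
        for g in infants_per_group
    }
    kinds = list(spec.artefact_mix)
    kind_p = np.array([spec.artefact_mix[k] for k in kinds])

    epochs: list[Epoch] = []
    truths: list[int] = []
    registry: list[dict] = []
    for (group, stim) in sorted(grid):
        count = grid[(group, stim)]
        chosen = rng.choice(infants[group], size=count, replace=False)
        for infant in chosen:
            ep = gen_clean_epoch(spec, rng, stimulus=stim, infant_id=str(infant),
                                 age_group=group)
            kind = None
            if rng.random() < kind_p.sum():
                kind = str(rng.choice(kinds, p=kind_p / kind_p.sum()))
                ep = inject_artefact(ep, kind, rng)
            epochs.append(ep)
            truths.append(int(kind is not None))
            registry.append(
                {
                    "infant_id": str(infant),
                    "age_group": group,
                    "stimulus": stim,
                    "artefact_kind": kind,
                }
            )
    truths_arr = np.array(truths, dtype=int)
    matrix = simulate_raters(truths_arr, spec.panel, rng)
    return epochs, truths_arr, matrix, registry


def gen_recording(
    spec: GeneratorSpec,
    rng: np.random.Generator,
    duration_s: float = 10.0,
    events: list[tuple[float, str]] | None = None,
    infant_id: str = "synthetic",
) -> Recording:
    """A continuous synthetic recording with stimulus events (for EDF I/O)."""
    n = int(round(duration_s * spec.fs))
    x = one_over_f_noise(n, spec.fs, spec.background_exponent, spec.background_rms, rng)
    if events is None:
        events = [(duration_s / 2, "auditory")]
    for t, stim in events:
        if stim == "background":
            continue
        wave = erp_waveform(spec)
        start = int(round((t - spec.event_offset) * spec.fs))
        lo, hi = max(0, start), min(n, start + len(wave))
        x[lo:hi] += wave[lo - start : hi - start]
    return Recording(samples=x, fs=spec.fs, events=list(events),
                     infant_id=infant_id)
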