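"""Reading and writing of recordings, epoch tables and feature tables.

The unit of exchange is the 1.5 s single-channel epoch.  Continuous
recordings come in as EDF/EDF+ with an annotation track; pre-cut epochs
travel in a documented CSV/TSV dialect with one row per epoch
(``infant_id, age_group, stimulus, fs, event_offset, s0001...sNNNN``).
All voltages are in microvolts throughout the package; EDF physical
dimensions are converted on load.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Stimulus taxonomy.  ``control_lance`` is the sham ("rotated") heel lance.
STIMULI = (
    "background",
    "auditory",
    "visual",
    "tactile",
    "experimental_noxious",
    "control_lance",
    "heel_lance",
)

#: Age groups: infants born prematurely and recorded <2 weeks from birth
#: (premature1), prematurely and >=2 weeks from birth (premature2), and
#: term-born infants recorded <2 weeks from birth (term).
AGE_GROUPS = ("premature1", "premature2", "term")


class EpochValidationError(ValueError):
    """Raised when an epoch table or epoch fails validation."""


class ChannelNotFoundError(KeyError):
    """Raised when the requested channel is absent from a recording."""


@dataclass
class Epoch:
    """One single-channel EEG segment around a stimulus.

    ``samples`` are in µV.  Epoch-local time runs from ``-event_offset``
    to ``n/fs - event_offset`` seconds, so the stimulus sits at t = 0.
    """

    samples: np.ndarray
    fs: float
    event_offset: float = 0.5
    stimulus: str = "background"
    infant_id: str = ""
    age_group: str = "term"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise EpochValidationError("epoch samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise EpochValidationError("epoch samples contain NaN/Inf")
        if self.fs <= 0:
            raise EpochValidationError(f"invalid sampling rate {self.fs}")
        if not 0.0 <= self.event_offset <= self.n / self.fs:
            raise EpochValidationError(
                f"event_offset {self.event_offset} outside epoch [0, {self.n / self.fs}]"
            )
        if self.stimulus not in STIMULI:
            raise EpochValidationError(f"unknown stimulus {self.stimulus!r}")
        if self.age_group not in AGE_GROUPS:
            raise EpochValidationError(f"unknown age group {self.age_group!r}")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        """Epoch-local time axis in seconds, stimulus at t = 0."""
        return np.arange(self.n) / self.fs - self.event_offset

    def with_samples(self, samples: np.ndarray) -> "Epoch":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class Recording:
    """A continuous single-channel recording with stimulus events."""

    samples: np.ndarray
    fs: float
    events: list[tuple[float, str]] = field(default_factory=list)
    channel_name: str = "Cz"
    infant_id: str = ""
    age_group: str = "term"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        dur = len(self.samples) / self.fs
        for t, stim in self.events:
            if not 0.0 < t < dur:
                raise EpochValidationError(f"event at {t} s outside recording (0, {dur})")
            if stim not in STIMULI:
                raise EpochValidationError(f"unknown stimulus {stim!r}")
        self.events = sorted(self.events, key=lambda ev: ev[0])

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


# ---------------------------------------------------------------------------
# EDF/EDF+ ingestion

def read_recording(path: str | Path, channel: str = "Cz") -> Recording:
    """Read one channel of an EDF/EDF+ file as a :class:`Recording`.

    Annotations whose text matches a stimulus name (case-insensitive)
    become events; anything else is skipped with a logged warning.
    Voltages are returned in µV regardless of the file's physical unit.
    """
    import mne

    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surfaced as a format error
        raise OSError(f"could not read EDF file {path}: {exc}") from exc

    if channel in raw.ch_names:
        picked = channel
    else:  # tolerate the conventional "EEG <name>" label prefix
        matches = [c for c in raw.ch_names if c == f"EEG {channel}"]
        if not matches:
            raise ChannelNotFoundError(
                f"channel {channel!r} not in {path.name} (has {raw.ch_names})"
            )
        picked = matches[0]
    data = raw.get_data(picks=[picked])[0] * 1e6  # MNE works in volts

    events: list[tuple[float, str]] = []
    stim_lookup = {s.lower(): s for s in STIMULI}
    for onset, _dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        key = str(desc).strip().lower().replace(" ", "_")
        if key in stim_lookup:
            events.append((float(onset), stim_lookup[key]))
        else:
            logger.warning("skipping unmapped annotation %r at %.3f s", desc, onset)
    return Recording(
        samples=data, fs=float(raw.info["sfreq"]), events=events, channel_name=channel
    )


def write_edf(rec: Recording, path: str | Path, physical_max: float = 3200.0) -> None:
    """Write a single-channel EDF+ file (16-bit samples, TAL annotations).

    Intended for exporting synthetic recordings; voltages are quantised
    to 16 bits over ±``physical_max`` µV.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n = len(rec.samples)
    n_records = int(np.ceil(n / fs))  # 1 s data records
    padded = np.zeros(n_records * fs)
    padded[:n] = rec.samples
    if np.max(np.abs(padded), initial=0.0) > physical_max:
        raise ValueError("signal exceeds EDF physical range; raise physical_max")

    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * physical_max)
    digital = np.round((padded + physical_max) * scale + dig_min).astype("<i2")
    digital = np.clip(digital, dig_min, dig_max)

    # annotation channel: one 64-byte TAL block per record
    ann_bytes_per_rec = 64
    ann_samples_per_rec = ann_bytes_per_rec // 2
    tals = []
    events = list(rec.events)
    for rec_i in range(n_records):
        tal = f"+{rec_i}\x14\x14\x00".encode("ascii")
        while events and rec_i <= events[0][0] < rec_i + 1:
            t, stim = events.pop(0)
            tal += f"+{t:.4f}\x14{stim}\x14\x00".encode("ascii")
        if len(tal) > ann_bytes_per_rec:
            raise ValueError("too many events in one second for the TAL block")
        tals.append(tal.ljust(ann_bytes_per_rec, b"\x00"))

    def _fix(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            _fix("0", 8),
            _fix(f"X X X {rec.infant_id or 'X'}", 80),
            _fix("Startdate X X X X", 80),
            _fix("01.01.00", 8),
            _fix("00.00.00", 8),
            _fix(str(256 * 3), 8),
            _fix("EDF+C", 44),
            _fix(str(n_records), 8),
            _fix("1", 8),
            _fix("2", 4),
        ]
    )
    labels = [f"EEG {rec.channel_name}", "EDF Annotations"]
    per_sig = b"".join(
        [
            b"".join(_fix(lbl, 16) for lbl in labels),
            b"".join(_fix("", 80) for _ in labels),
            _fix("uV", 8) + _fix("", 8),
            _fix(str(-physical_max), 8) + _fix("-1", 8),
            _fix(str(physical_max), 8) + _fix("1", 8),
            _fix(str(dig_min), 8) + _fix(str(dig_min), 8),
            _fix(str(dig_max), 8) + _fix(str(dig_max), 8),
            b"".join(_fix("", 80) for _ in labels),
            _fix(str(fs), 8) + _fix(str(ann_samples_per_rec), 8),
            b"".join(_fix("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + per_sig)
        for rec_i in range(n_records):
            fh.write(digital[rec_i * fs : (rec_i + 1) * fs].tobytes())
            fh.write(tals[rec_i])


# ---------------------------------------------------------------------------
# Epoch tables

_META_COLS = ["infant_id", "age_group", "stimulus", "fs", "event_offset"]


def write_epoch_table(epochs: list[Epoch], path: str | Path, sep: str = ",") -> None:
    """Write epochs to the long-row CSV/TSV dialect, one row per epoch."""
    if epochs:
        n = epochs[0].n
        if any(ep.n != n for ep in epochs):
            raise EpochValidationError("all epochs in one table must share a length")
    else:
        n = 0
    cols = _META_COLS + [f"s{i + 1:04d}" for i in range(n)]
    rows = [
        [ep.infant_id, ep.age_group, ep.stimulus, repr(float(ep.fs)),
         repr(float(ep.event_offset))] + [repr(float(v)) for v in ep.samples]
        for ep in epochs
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def read_epoch_table(path: str | Path, sep: str | None = None) -> list[Epoch]:
    """Read an epoch table; validation failures name the offending row."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise EpochValidationError(f"{path.name}: missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in _META_COLS]
    epochs: list[Epoch] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = dict(zip(df.columns, row))
        try:
            fs = float(rec["fs"])
            samples = np.array([float(rec[c]) for c in sample_cols])
            ep = Epoch(
                samples=samples,
                fs=fs,
                event_offset=float(rec["event_offset"]),
                stimulus=rec["stimulus"],
                infant_id=rec["infant_id"],
                age_group=rec["age_group"],
            )
        except (ValueError, EpochValidationError) as exc:
            raise EpochValidationError(f"{path.name} row {i}: {exc}") from exc
        expected = int(round(1.5 * fs))
        if ep.n != expected and abs(ep.event_offset - 0.5) < 1e-12:
            raise EpochValidationError(
                f"{path.name} row {i}: {ep.n} samples, expected {expected} "
                f"for a 1.5 s epoch at fs={fs}"
            )
        epochs.append(ep)
    return epochs


# ---------------------------------------------------------------------------
# Feature tables

def write_feature_table(
    features: list[dict[str, float]],
    path: str | Path,
    labels: list[int] | None = None,
) -> None:
    """Write feature vectors as CSV, header = canonical feature names.

    Values are written with full ``repr`` precision so a re-read table
    is bit-for-bit identical.  All vectors must share one ordering.
    """
    if not features:
        from .features import FEATURE_NAMES

        names = list(FEATURE_NAMES)
    else:
        names = list(features[0].keys())
        for i, fv in enumerate(features):
            if list(fv.keys()) != names:
                raise EpochValidationError(f"feature vector {i} has inconsistent ordering")
    if labels is not None and len(labels) != len(features):
        raise EpochValidationError("labels length must match features length")
    cols = names + (["label"] if labels is not None else [])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(cols) + "\n")
        for i, fv in enumerate(features):
            vals = [repr(float(v)) for v in fv.values()]
            if labels is not None:
                vals.append(str(int(labels[i])))
            fh.write(",".join(vals) + "\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table back into a DataFrame (row order preserved)."""
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Rater matrices

def write_rater_matrix(
    labels: np.ndarray, rater_ids: list[str], path: str | Path
) -> None:
    """Rater matrix CSV: rows = epoch ids, columns = rater ids, cells 0/1."""
    df = pd.DataFrame(np.asarray(labels, dtype=int), columns=rater_ids)
    df.index.name = "epoch"
    df.to_csv(path)


def read_rater_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    labels = df.to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise EpochValidationError("rater matrix cells must be 0 or 1")
    return labels.astype(int), [str(c) for c in df.columns]
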