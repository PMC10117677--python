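"""Reading PSG recordings and hypnograms, and turning them into labeled
30-s epochs at 100 Hz.

The preprocessing pipeline applies, in order: a 0.3-35 Hz band-pass filter,
downsampling to 100 Hz, segmentation into non-overlapping 30-s epochs, and
three label-driven cleanup rules:

* epochs scored as movement time (M) or not scored (?) are dropped;
* the older S3/S4 scores are merged into a single N3 stage;
* wake epochs are kept only within 30 minutes before the first and after
  the last sleep epoch (in-bed wake padding is otherwise discarded).

EDF reading is delegated to :mod:`mne`; a minimal EDF/EDF+ *writer* is also
provided so synthetic fixtures and the ``synth`` CLI can produce files the
read path consumes. Hypnograms are accepted either as EDF+ annotation files
or as a simple CSV dialect with columns ``onset,duration,stage``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

EPOCH_S = 30  #: scoring epoch length in seconds
TARGET_RATE = 100.0  #: Hz after preprocessing
EPOCH_SAMPLES = int(EPOCH_S * TARGET_RATE)  # T = 3000

#: raw hypnogram stage tokens -> integer class labels (W, N1, N2, N3, REM)
STAGE_TO_LABEL = {"W": 0, "1": 1, "2": 2, "3": 3, "4": 3, "R": 4}
DROP_STAGES = frozenset({"M", "?"})
VALID_STAGES = frozenset(STAGE_TO_LABEL) | DROP_STAGES
LABEL_NAMES = ("W", "N1", "N2", "N3", "REM")

#: Sleep-EDFx style annotation texts -> canonical single-character stages
_TOKEN_ALIASES = {
    "sleep stage w": "W",
    "sleep stage 1": "1",
    "sleep stage 2": "2",
    "sleep stage 3": "3",
    "sleep stage 4": "4",
    "sleep stage r": "R",
    "sleep stage ?": "?",
    "movement time": "M",
}

__all__ = [
    "RawRecording",
    "HypnogramAnnotation",
    "EpochedRecording",
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram_edf",
    "bandpass_filter",
    "resample_to_100hz",
    "epoch_and_label",
    "save_epochs",
    "load_epochs",
    "EPOCH_SAMPLES",
    "STAGE_TO_LABEL",
    "LABEL_NAMES",
]


@dataclass
class RawRecording:
    """One channel of continuous signal, in µV."""

    samples: np.ndarray
    rate: float
    channel: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size < 1:
            raise ValueError("recording is empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class HypnogramAnnotation:
    """Ordered (onset_s, duration_s, stage) entries, stages in {W,1,2,3,4,R,M,?}."""

    entries: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self):
        onsets = [e[0] for e in self.entries]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("hypnogram onsets must be non-decreasing")
        for onset, dur, stage in self.entries:
            if stage not in VALID_STAGES:
                raise ValueError(
                    f"unknown stage token {stage!r}; expected one of "
                    f"{sorted(VALID_STAGES)}"
                )
            if dur % EPOCH_S != 0:
                warnings.warn(
                    f"duration {dur} s at onset {onset} s is not a multiple of "
                    f"{EPOCH_S} s; the trailing partial epoch is ignored",
                    stacklevel=2,
                )

    def epoch_stages(self) -> list[str]:
        """Expand entries into one stage token per 30-s epoch."""
        out: list[str] = []
        for onset, dur, stage in self.entries:
            out.extend([stage] * int(dur // EPOCH_S))
        return out

    @property
    def span_s(self) -> float:
        if not self.entries:
            return 0.0
        last = self.entries[-1]
        return last[0] + last[1] - self.entries[0][0]


@dataclass
class EpochedRecording:
    """(n, 1, 3000) float32 epoch tensor with integer labels in {0..4}."""

    epochs: np.ndarray
    labels: np.ndarray
    rate: float = TARGET_RATE

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3 or self.epochs.shape[1] != 1:
            raise ValueError(f"epochs must be (n, 1, T), got {self.epochs.shape}")
        if self.epochs.shape[0] != self.labels.shape[0]:
            raise ValueError("epoch/label count mismatch")
        if self.labels.size and not (
            (self.labels >= 0).all() and (self.labels < 5).all()
        ):
            raise ValueError("labels must lie in {0..4}")
        if not np.all(np.isfinite(self.epochs)):
            raise ValueError("epochs contain non-finite values")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=5)


# ---------------------------------------------------------------------------
# EDF reading (mne) and a minimal EDF/EDF+ writer for fixtures
# ---------------------------------------------------------------------------

def read_edf(path, channel: str) -> RawRecording:
    """Read one channel from an EDF/EDF+ file, returning samples in µV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(
            f"channel {channel!r} not found; available channels: {raw.ch_names}"
        )
    raw = raw.pick([channel])
    raw.load_data(verbose="error")
    data = raw.get_data()[0]
    # mne converts µV-dimensioned channels to volts; undo to keep µV
    unit = getattr(raw, "_orig_units", {}).get(channel, "")
    if unit in ("µV", "uV"):
        data = data * 1e6
    return RawRecording(samples=data, rate=float(raw.info["sfreq"]), channel=channel)


def _edf_header(n_records: int, record_dur: float, signal_headers: list[dict]) -> bytes:
    """Fixed-width ASCII EDF header for the given signals."""

    def f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    ns = len(signal_headers)
    h = io.BytesIO()
    h.write(f("0", 8))
    h.write(f("X X X X", 80))  # patient id
    h.write(f("Startdate 01-JAN-2000 X X X", 80))
    h.write(f("01.01.00", 8))
    h.write(f("00.00.00", 8))
    h.write(f(256 * (1 + ns), 8))
    h.write(f("EDF+C" if any(s["label"] == "EDF Annotations" for s in signal_headers) else "", 44))
    h.write(f(n_records, 8))
    g = f"{record_dur:.6f}".rstrip("0").rstrip(".")
    h.write(f(g, 8))
    h.write(f(ns, 4))
    for key, width in (
        ("label", 16), ("transducer", 80), ("dimension", 8),
        ("phys_min", 8), ("phys_max", 8), ("dig_min", 8), ("dig_max", 8),
        ("prefilter", 80), ("n_samples", 8),
    ):
        for s in signal_headers:
            h.write(f(s.get(key, ""), width))
    h.write(b" " * (32 * ns))  # reserved
    return h.getvalue()


def write_edf(path, rec: RawRecording, record_dur: float = 1.0) -> None:
    """Write a single-channel EDF file (int16 records, µV physical units)."""
    spr = rec.rate * record_dur
    if spr != int(spr):
        raise ValueError("rate * record duration must be an integer sample count")
    spr = int(spr)
    n_records = int(np.ceil(rec.samples.size / spr))
    x = np.zeros(n_records * spr)
    x[: rec.samples.size] = rec.samples
    pmax = max(np.abs(x).max(), 1e-6)
    dig = np.round(x / pmax * 32767).astype("<i2")
    hdr = _edf_header(n_records, record_dur, [{
        "label": rec.channel or "EEG", "transducer": "", "dimension": "uV",
        "phys_min": f"{-pmax:.5g}"[:8], "phys_max": f"{pmax:.5g}"[:8],
        "dig_min": -32767, "dig_max": 32767, "prefilter": "", "n_samples": spr,
    }])
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(dig.tobytes())


def write_hypnogram_edf(path, hyp: HypnogramAnnotation) -> None:
    """Write an EDF+ annotation-only file (TAL-encoded stage list)."""
    tals = [b"+0\x14\x14\x00"]  # record timestamp TAL
    names = {v: k for k, v in _TOKEN_ALIASES.items()}
    for onset, dur, stage in hyp.entries:
        text = names[stage].title() if stage != "?" else "Sleep stage ?"
        tal = f"+{onset:g}\x15{dur:g}\x14{text}\x14\x00"
        tals.append(tal.encode("ascii"))
    payload = b"".join(tals)
    if len(payload) % 2:
        payload += b"\x00"
    spr = len(payload) // 2  # 2 bytes per int16 sample
    hdr = _edf_header(1, 1.0, [{
        "label": "EDF Annotations", "transducer": "", "dimension": "",
        "phys_min": -1, "phys_max": 1, "dig_min": -32768, "dig_max": 32767,
        "prefilter": "", "n_samples": spr,
    }])
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(payload)


def _normalize_stage(token: str) -> str:
    t = token.strip()
    if t in VALID_STAGES:
        return t
    alias = _TOKEN_ALIASES.get(t.lower())
    if alias is None:
        raise ValueError(
            f"unknown stage token {token!r}; expected one of "
            f"{sorted(VALID_STAGES)} or a Sleep-EDFx annotation text"
        )
    return alias


def read_hypnogram(path) -> HypnogramAnnotation:
    """Read a hypnogram from an EDF+ annotation file or an onset,duration,stage CSV."""
    p = Path(path)
    if p.suffix.lower() in (".csv", ".txt", ".tsv"):
        entries = []
        sep = "\t" if p.suffix.lower() == ".tsv" else ","
        for line in p.read_text().splitlines():
            line = line.strip()
            if not line or line.lower().startswith("onset"):
                continue
            onset, dur, stage = line.split(sep)[:3]
            entries.append((float(onset), float(dur), _normalize_stage(stage)))
        return HypnogramAnnotation(entries=entries)
    import mne

    ann = mne.read_annotations(str(p))
    entries = [
        (float(on), float(du), _normalize_stage(desc))
        for on, du, desc in zip(ann.onset, ann.duration, ann.description)
    ]
    return HypnogramAnnotation(entries=entries)


# ---------------------------------------------------------------------------
# Signal conditioning
# ---------------------------------------------------------------------------

def bandpass_filter(rec: RawRecording, low: float = 0.3, high: float = 35.0) -> RawRecording:
    """Zero-phase 4th-order Butterworth band-pass (default 0.3-35 Hz)."""
    nyq = rec.rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    return RawRecording(
        samples=signal.sosfiltfilt(sos, rec.samples), rate=rec.rate, channel=rec.channel
    )


def resample_to_100hz(rec: RawRecording) -> RawRecording:
    """Anti-aliased polyphase downsampling to exactly 100 Hz."""
    if rec.rate < TARGET_RATE:
        raise ValueError(
            f"rate {rec.rate} Hz is below {TARGET_RATE} Hz; upsampling is unsupported"
        )
    if rec.rate == TARGET_RATE:
        return rec
    frac = Fraction(TARGET_RATE / rec.rate).limit_denominator(10000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return RawRecording(samples=out, rate=TARGET_RATE, channel=rec.channel)


# ---------------------------------------------------------------------------
# Epoching and label rules
# ---------------------------------------------------------------------------

def epoch_and_label(
    rec: RawRecording,
    hyp: HypnogramAnnotation,
    trim_wake_min: float = 30.0,
) -> EpochedRecording:
    """Cut a 100 Hz recording into labeled 30-s epochs with the cleanup rules.

    Epoch i covers samples [i*3000, (i+1)*3000). Epochs scored M or ? are
    dropped, S3/S4 map to N3, and wake epochs survive only if they start
    within ``trim_wake_min`` minutes of the first/last sleep-epoch boundary.
    """
    if rec.rate != TARGET_RATE:
        raise ValueError(f"recording must be at {TARGET_RATE} Hz; resample first")
    stages = hyp.epoch_stages()
    n_avail = rec.samples.size // EPOCH_SAMPLES
    if len(stages) > n_avail:
        raise ValueError(
            f"hypnogram covers {len(stages)} epochs but recording has only {n_avail}"
        )
    sleep_idx = [i for i, s in enumerate(stages) if s in ("1", "2", "3", "4", "R")]
    if not sleep_idx:
        raise ValueError("hypnogram contains no sleep epoch; wake trimming undefined")
    margin = trim_wake_min * 60.0
    first_s, last_s = sleep_idx[0], sleep_idx[-1]
    first_start = first_s * EPOCH_S
    last_end = (last_s + 1) * EPOCH_S

    keep: list[tuple[int, int]] = []  # (epoch index, label)
    for i, s in enumerate(stages):
        if s in DROP_STAGES:
            continue
        if s == "W":
            start = i * EPOCH_S
            if not (first_start - margin <= start < last_end + margin):
                continue
        keep.append((i, STAGE_TO_LABEL[s]))

    n = len(keep)
    epochs = np.empty((n, 1, EPOCH_SAMPLES), dtype=np.float32)
    labels = np.empty(n, dtype=np.int64)
    for j, (i, lab) in enumerate(keep):
        epochs[j, 0] = rec.samples[i * EPOCH_SAMPLES : (i + 1) * EPOCH_SAMPLES]
        labels[j] = lab
    return EpochedRecording(epochs=epochs, labels=labels)


# ---------------------------------------------------------------------------
# NPZ container
# ---------------------------------------------------------------------------

def save_epochs(path, rec: EpochedRecording) -> None:
    np.savez(path, epochs=rec.epochs, labels=rec.labels, rate=rec.rate)


def load_epochs(path) -> EpochedRecording:
    with np.load(path) as z:
        return EpochedRecording(
            epochs=z["epochs"], labels=z["labels"], rate=float(z["rate"])
        )
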