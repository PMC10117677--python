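"""Synthetic two-domain EEG-like epoch generator.

Real cross-dataset sleep staging suffers a domain shift (different montages,
amplifiers, sampling chains). This module emulates that situation without
any download: five stage classes are given band-limited spectral prototypes
mimicking the canonical sleep rhythms —

* W    : alpha 8-12 Hz over a broadband background
* N1   : low-amplitude theta 4-7 Hz
* N2   : theta background plus a 12-14 Hz spindle band
* N3   : high-amplitude delta 0.5-2 Hz
* REM  : mixed low-amplitude theta/beta

and target-domain epochs are additionally transformed by a shift triple
(amplitude gain, extra white noise, frequency offset of the prototype
bands). With a null shift the two domains are draws from the same process;
the default shift (gain 2.0, +50% noise, +1 Hz) degrades direct transfer
noticeably while remaining recoverable by adaptation.

Band-limited components are produced by band-pass filtering white noise
with the package's own Butterworth filter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import (
    EPOCH_S,
    EPOCH_SAMPLES,
    TARGET_RATE,
    EpochedRecording,
    HypnogramAnnotation,
    RawRecording,
    bandpass_filter,
)

#: per-class spectral prototypes: list of (center Hz, bandwidth Hz, amplitude µV)
DEFAULT_PROTOTYPES: dict[int, list[tuple[float, float, float]]] = {
    0: [(10.0, 4.0, 30.0), (20.0, 20.0, 10.0)],   # W: alpha + broadband
    1: [(5.5, 3.0, 15.0)],                          # N1: weak theta
    2: [(5.5, 3.0, 20.0), (13.0, 2.0, 25.0)],      # N2: theta + spindle band
    3: [(1.25, 1.5, 60.0)],                         # N3: large delta
    4: [(6.0, 4.0, 12.0), (22.0, 8.0, 8.0)],       # REM: mixed theta/beta
}

__all__ = ["SynthConfig", "gen_domain_pair", "gen_toy_hypnogram", "DEFAULT_PROTOTYPES"]


@dataclass
class SynthConfig:
    n_per_class: int = 100
    prototypes: dict[int, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PROTOTYPES.items()}
    )
    #: target-domain shift: (gain multiplier, added noise SD µV, frequency offset Hz)
    shift: tuple[float, float, float] = (2.0, 5.0, 1.0)
    noise_sd: float = 10.0  # white-noise floor in both domains, µV
    seed: int = 0

    def __post_init__(self):
        if len(self.prototypes) != 5:
            raise ValueError("exactly 5 classes are required")
        if self.shift[0] <= 0:
            raise ValueError("gain must be positive")
        for comps in self.prototypes.values():
            for c, bw, _ in comps:
                if c + bw / 2 + abs(self.shift[2]) >= TARGET_RATE / 2:
                    raise ValueError("prototype band exceeds the 50 Hz Nyquist limit")


def _band_noise(rng: np.random.Generator, n: int, center: float, bw: float) -> np.ndarray:
    """White noise band-passed to [center-bw/2, center+bw/2], unit RMS."""
    low = max(center - bw / 2, 0.05)
    high = min(center + bw / 2, TARGET_RATE / 2 - 0.5)
    white = RawRecording(rng.standard_normal(n), rate=TARGET_RATE)
    x = bandpass_filter(white, low, high).samples
    rms = np.sqrt(np.mean(x**2))
    return x / max(rms, 1e-12)


def _gen_epochs(
    rng: np.random.Generator,
    cfg: SynthConfig,
    gain: float,
    extra_noise: float,
    freq_offset: float,
) -> EpochedRecording:
    n_cls = cfg.n_per_class
    labels = np.repeat(np.arange(5), n_cls)
    epochs = np.empty((labels.size, 1, EPOCH_SAMPLES), dtype=np.float32)
    for i, lab in enumerate(labels):
        x = np.zeros(EPOCH_SAMPLES)
        for center, bw, amp in cfg.prototypes[int(lab)]:
            x += amp * _band_noise(rng, EPOCH_SAMPLES, center + freq_offset, bw)
        x += cfg.noise_sd * rng.standard_normal(EPOCH_SAMPLES)
        x *= gain
        if extra_noise > 0:
            x += extra_noise * rng.standard_normal(EPOCH_SAMPLES)
        epochs[i, 0] = x
    # interleave classes so ordered 80/20 splits stay balanced
    order = np.arange(labels.size).reshape(5, n_cls).T.reshape(-1)
    return EpochedRecording(epochs=epochs[order], labels=labels[order])


def gen_domain_pair(cfg: SynthConfig | None = None
                    ) -> tuple[EpochedRecording, EpochedRecording]:
    """Source and shifted-target epoch sets, deterministic under cfg.seed.

    The target's true labels are returned for *evaluation only*; the
    training API never reads them.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    src_rng, tgt_rng = rng.spawn(2)
    source = _gen_epochs(src_rng, cfg, gain=1.0, extra_noise=0.0, freq_offset=0.0)
    gain, noise, offset = cfg.shift
    target = _gen_epochs(tgt_rng, cfg, gain=gain, extra_noise=noise, freq_offset=offset)
    return source, target


def gen_toy_hypnogram(pattern: list[tuple[str, int]]
                      ) -> tuple[HypnogramAnnotation, RawRecording]:
    """Run-length hypnogram plus a matching 100 Hz noise recording.

    `pattern` is a list of (stage token, epoch count) runs, e.g.
    [("W", 120), ("2", 10), ("W", 120)].
    """
    if not pattern:
        raise ValueError("pattern must contain at least one run")
    entries = []
    onset = 0.0
    for stage, k in pattern:
        if k < 1:
            raise ValueError("run length must be >= 1")
        entries.append((onset, float(k * EPOCH_S), stage))
        onset += k * EPOCH_S
    hyp = HypnogramAnnotation(entries=entries)
    n = int(onset * TARGET_RATE)
    rng = np.random.default_rng(zlib.crc32(repr(pattern).encode()) % (2**31))
    rec = RawRecording(rng.standard_normal(n) * 10.0, rate=TARGET_RATE, channel="synthetic")
    return hyp, rec
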