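"""Sliding-window oversampling of a minority sleep stage.

N1 typically accounts for only 2-5% of a night while N2 covers about half,
and the imbalance hurts stage classifiers. Each maximal run of consecutive
minority-stage epochs is treated as one continuous signal and re-cut into
overlapping windows (default 30 s window, 25 s step), so a run of k epochs
yields floor((30k - 30)/25) + 1 windows instead of k. Windows never cross a
run boundary, so every augmented window carries a pure stage label; other
stages pass through untouched, in recording order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import EpochedRecording

__all__ = ["AugmentConfig", "sliding_window_augment", "window_count"]


@dataclass
class AugmentConfig:
    target_stage: int = 1  # N1
    window_s: float = 30.0
    step_s: float = 25.0

    def __post_init__(self):
        if not 0 < self.step_s <= self.window_s:
            raise ValueError("need 0 < step_s <= window_s")


def window_count(run_epochs: int, window_s: float = 30.0, step_s: float = 25.0,
                 epoch_s: float = 30.0) -> int:
    """Number of windows cut from a run of `run_epochs` consecutive epochs."""
    run_s = run_epochs * epoch_s
    if run_s < window_s:
        return run_epochs  # run too short to re-cut: epochs pass unchanged
    return int((run_s - window_s) // step_s) + 1


def sliding_window_augment(rec: EpochedRecording, cfg: AugmentConfig | None = None
                           ) -> EpochedRecording:
    """Re-cut runs of the target stage into overlapping windows.

    Intended for training data only; augmenting an evaluation split would
    leak overlapping copies of the same signal into the test metric.
    """
    cfg = cfg or AugmentConfig()
    t = rec.epochs.shape[2]
    rate = rec.rate
    win = int(round(cfg.window_s * rate))
    step = int(round(cfg.step_s * rate))
    if win != cfg.window_s * rate:
        raise ValueError("window_s * rate must be an integer sample count")

    out_epochs: list[np.ndarray] = []
    out_labels: list[int] = []
    n = len(rec)
    i = 0
    while i < n:
        if rec.labels[i] != cfg.target_stage:
            out_epochs.append(rec.epochs[i])
            out_labels.append(int(rec.labels[i]))
            i += 1
            continue
        j = i
        while j < n and rec.labels[j] == cfg.target_stage:
            j += 1
        run = rec.epochs[i:j, 0].reshape(-1)  # concatenated run signal
        if run.size < win:
            for idx in range(i, j):
                out_epochs.append(rec.epochs[idx])
                out_labels.append(cfg.target_stage)
        else:
            for start in range(0, run.size - win + 1, step):
                out_epochs.append(run[start : start + win][None, :])
                out_labels.append(cfg.target_stage)
        i = j

    epochs = (
        np.stack(out_epochs) if out_epochs
        else np.empty((0, 1, t), dtype=np.float32)
    )
    return EpochedRecording(
        epochs=epochs, labels=np.asarray(out_labels, dtype=np.int64), rate=rate
    )
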