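"""Physiological-noise filtering, smoothing, epoching and trial averaging.

Hemodynamic task responses live well below 0.2 Hz, while cardiac (~1 Hz),
respiratory (~0.25 Hz) and very-low-frequency drift contaminate the raw
concentration traces. The standard cleanup is a band-pass around the task
frequency followed by polynomial smoothing; trials are then cut into
fixed-length epochs relative to task onset and averaged per stimulus type.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io import EventSchedule, Recording

__all__ = [
    "EpochSet",
    "bandpass_filter",
    "savgol_smooth",
    "epoch_trials",
    "average_trials",
]


@dataclass(frozen=True)
class EpochSet:
    """Trial-locked windows of a recording.

    ``epochs`` has shape (n_trials, n_times, n_channels); ``window`` is the
    (start, end) offset in seconds relative to task onset, half-open.
    """

    epochs: np.ndarray
    window: tuple[float, float]
    fs: float
    labels: tuple[str, ...]
    channel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ep = np.asarray(self.epochs, dtype=float)
        if ep.ndim != 3:
            raise ValueError("epochs must be trial x time x channel")
        if ep.shape[1] < 2:
            raise ValueError("epochs must span at least 2 samples")
        if len(self.labels) != ep.shape[0]:
            raise ValueError("one label per trial required")
        if len(self.channel_ids) != ep.shape[2]:
            raise ValueError("one channel id per channel required")
        object.__setattr__(self, "epochs", ep)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[2]

    def subset(self, mask_or_idx) -> "EpochSet":
        idx = np.arange(self.n_channels)[mask_or_idx]
        return replace(
            self,
            epochs=self.epochs[:, :, idx],
            channel_ids=tuple(self.channel_ids[i] for i in idx),
        )


def bandpass_filter(rec: Recording, low: float = 0.03, high: float = 0.15, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass, channel-wise.

    A forward–backward pass (effective magnitude order ``2*order``) avoids
    the group delay that would bias cross-correlation lags downstream.
    Defaults pass 0.03–0.15 Hz, bracketing task-locked hemodynamics while
    rejecting drift, respiration and cardiac pulsation.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz must sit inside (0, {nyq}) Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if rec.n_samples <= padlen:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than filter warm-up ({padlen})"
        )
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=0))


def savgol_smooth(rec: Recording, window_s: float = 1.0, polyorder: int = 3) -> Recording:
    """Savitzky–Golay smoothing, channel-wise; window forced to odd samples."""
    w = int(round(window_s * rec.fs))
    if w % 2 == 0:
        w += 1
    if w == 1:
        return rec
    if w > rec.n_samples:
        raise ValueError(f"smoothing window of {w} samples exceeds recording length")
    if w < polyorder + 2:
        raise ValueError("window must cover at least polyorder + 2 samples")
    return rec.with_data(signal.savgol_filter(rec.data, w, polyorder, axis=0))


def epoch_trials(rec: Recording, events: EventSchedule, window: tuple[float, float]) -> EpochSet:
    """Cut trial epochs of ``window = (start, end)`` seconds around each onset.

    Sample count per epoch is ``round((end - start) * fs)``; the window is
    half-open so abutting epochs do not share samples.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    n = int(round((end - start) * rec.fs))
    if n < 2:
        raise ValueError("window shorter than 2 samples")
    first = np.round((events.onsets + start) * rec.fs).astype(int)
    bad = [
        int(j)
        for j, f in enumerate(first)
        if f < 0 or f + n > rec.n_samples
    ]
    if bad:
        raise ValueError(f"epoch window exceeds recording bounds for trial(s) {bad}")
    epochs = np.stack([rec.data[f : f + n] for f in first])
    return EpochSet(
        epochs=epochs,
        window=(float(start), float(end)),
        fs=rec.fs,
        labels=events.labels,
        channel_ids=rec.channel_ids,
    )


def average_trials(ep: EpochSet, label: str | None = None) -> np.ndarray:
    """Element-wise mean over trials of one stimulus type → time x channel."""
    if label is None:
        keep = np.ones(ep.n_trials, dtype=bool)
    else:
        keep = np.array([lab == label for lab in ep.labels])
        if not keep.any():
            raise ValueError(f"no epochs labelled {label!r}")
    return ep.epochs[keep].mean(axis=0)
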