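"""End-to-end session analysis: preprocess → select → features → LOOCV.

Thin composition layer over the library modules, with the study's default
settings: 0.03–0.15 Hz fourth-order zero-phase band-pass, 1 s / order-3
Savitzky–Golay smoothing, a 24 s analysis epoch from task onset (300 samples
at 12.5 Hz), the 10 s task window for task-class features, and an equally
long rest window starting 5 s after task offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import loocv_accuracy
from .features import DEFAULT_FEATURES, FeatureMatrix, build_feature_matrix
from .hrf import HRFParams, trial_template
from .io import EventSchedule, Recording
from .preprocess import bandpass_filter, epoch_trials, savgol_smooth, average_trials
from .select import (
    BaselineSelector,
    SelectionResult,
    TValueSelector,
    ZScoreSelector,
)

__all__ = ["AnalysisConfig", "preprocess_recording", "select_channels", "session_features", "session_accuracy"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline settings (all windows in seconds relative to task onset)."""

    band: tuple[float, float] = (0.03, 0.15)
    filter_order: int = 4
    smooth_window_s: float = 1.0
    smooth_polyorder: int = 3
    epoch_window: tuple[float, float] = (0.0, 24.0)
    task_window: tuple[float, float] = (0.0, 10.0)
    rest_window: tuple[float, float] = (15.0, 25.0)
    task_duration: float = 10.0
    feature_set: tuple[str, ...] = DEFAULT_FEATURES
    hrf: HRFParams = field(default_factory=HRFParams)


def preprocess_recording(rec: Recording, cfg: AnalysisConfig | None = None) -> Recording:
    """Band-pass then Savitzky–Golay smooth, channel-wise."""
    cfg = cfg or AnalysisConfig()
    rec = bandpass_filter(rec, *cfg.band, order=cfg.filter_order)
    return savgol_smooth(rec, cfg.smooth_window_s, cfg.smooth_polyorder)


def select_channels(
    rec: Recording,
    events: EventSchedule,
    method: str = "zscore",
    cfg: AnalysisConfig | None = None,
    preprocessed: bool = False,
    **selector_kw,
) -> SelectionResult:
    """Run one channel-selection method on a session recording.

    ``method`` is ``'zscore'``, ``'tvalue'`` or ``'baseline'``. The
    recording is preprocessed unless ``preprocessed=True``; the z-score and
    t-value methods operate on the averaged trial over the analysis epoch,
    with the dHRF template built from the same window.
    """
    cfg = cfg or AnalysisConfig()
    if not preprocessed:
        rec = preprocess_recording(rec, cfg)
    if method == "baseline":
        task_ep = epoch_trials(rec, events, cfg.task_window)
        rest_ep = epoch_trials(rec, events, cfg.rest_window)
        return BaselineSelector(task_ep, rest_ep).fit()
    ep = epoch_trials(rec, events, cfg.epoch_window)
    avg = average_trials(ep)
    template = trial_template(rec.fs, cfg.epoch_window, cfg.task_duration, cfg.hrf)
    if method == "zscore":
        model = ZScoreSelector(avg, template, rec.channel_ids, **selector_kw)
    elif method == "tvalue":
        model = TValueSelector(avg, template, rec.channel_ids, **selector_kw)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return model.fit()


def session_features(
    rec: Recording,
    events: EventSchedule,
    selection: SelectionResult | None,
    cfg: AnalysisConfig | None = None,
    preprocessed: bool = False,
) -> FeatureMatrix:
    """Normalized task/rest feature matrix for one session."""
    cfg = cfg or AnalysisConfig()
    if not preprocessed:
        rec = preprocess_recording(rec, cfg)
    task_ep = epoch_trials(rec, events, cfg.task_window)
    rest_ep = epoch_trials(rec, events, cfg.rest_window)
    return build_feature_matrix(task_ep, rest_ep, selection, cfg.feature_set)


def session_accuracy(
    rec: Recording,
    events: EventSchedule,
    method: str | None = "zscore",
    cfg: AnalysisConfig | None = None,
) -> tuple[float, SelectionResult | None]:
    """LOOCV accuracy (%) of task-vs-rest classification for one session.

    ``method=None`` is the all-channels arm (no selection). Returns the
    accuracy and the selection result used.
    """
    cfg = cfg or AnalysisConfig()
    rec = preprocess_recording(rec, cfg)
    selection = None
    if method is not None:
        selection = select_channels(rec, events, method, cfg, preprocessed=True)
    fm = session_features(rec, events, selection, cfg, preprocessed=True)
    acc, _ = loocv_accuracy(fm)
    return acc, selection
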