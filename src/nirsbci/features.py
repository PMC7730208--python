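"""Spatio-temporal feature extraction and min-max normalization.

Features are computed from ΔHbO in two steps: the selected channels are
averaged spatially, then a temporal statistic summarises each trial window.
The default statistic set is (mean, peak, slope); the extended set adds
variance, skewness and kurtosis. Task-class rows come from the task window,
rest-class rows from an equally long window inside the following rest
period, and each feature column is rescaled to [0, 1] over both classes
jointly before classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import EpochSet
from .select import SelectionResult, apply_selection

__all__ = [
    "FeatureMatrix",
    "extract_features",
    "minmax_normalize",
    "build_feature_matrix",
    "DEFAULT_FEATURES",
    "EXTENDED_FEATURES",
]

DEFAULT_FEATURES = ("mean", "peak", "slope")
EXTENDED_FEATURES = ("mean", "peak", "slope", "skewness", "kurtosis", "variance")


@dataclass(frozen=True)
class FeatureMatrix:
    """Rows = samples (trials), columns = features, with per-row class labels."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D samples x features")
        if len(self.feature_names) != v.shape[1]:
            raise ValueError("one name per feature column required")
        if len(self.labels) != v.shape[0]:
            raise ValueError("one label per row required")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def classes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def rows_of(self, label: str) -> np.ndarray:
        return self.values[[lab == label for lab in self.labels]]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "label", list(self.labels))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _stat(name: str, x: np.ndarray, fs: float) -> float:
    if name == "mean":
        return float(x.mean())
    if name == "peak":
        return float(x.max())
    if name == "slope":
        # least-squares line coefficient, per second (fs-invariant)
        t = np.arange(x.size) / fs
        return float(np.polyfit(t, x, 1)[0])
    if name == "variance":
        return float(x.var(ddof=1))
    if name == "skewness":
        return float(stats.skew(x, bias=False))
    if name == "kurtosis":
        return float(stats.kurtosis(x, fisher=True, bias=False))
    raise ValueError(f"unknown feature {name!r}")

_MOMENT_FEATURES = {"variance", "skewness", "kurtosis"}


def extract_features(
    ep: EpochSet,
    selected: SelectionResult | None,
    feature_set=DEFAULT_FEATURES,
) -> np.ndarray:
    """Per-trial feature rows: spatial average of selected channels, then
    one temporal statistic per feature over the epoch window.

    ``selected=None`` keeps all channels (the no-selection arm). Returns an
    (n_trials, n_features) array of raw (un-normalized) values.
    """
    if ep.n_trials == 0:
        raise ValueError("epoch set is empty")
    ep = apply_selection(ep, selected)
    if _MOMENT_FEATURES & set(feature_set) and ep.n_times < 3:
        raise ValueError("moment features need windows of at least 3 samples")
    spatial = ep.epochs.mean(axis=2)  # trial x time
    return np.array(
        [[_stat(name, trial, ep.fs) for name in feature_set] for trial in spatial]
    )


def minmax_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Rescale each feature column to [0, 1] over all rows jointly.

    ``Y′ = (Y − min Y)/(max Y − min Y)``; a constant column maps to zeros
    (guarded 0/0).
    """
    if fm.n_samples < 2:
        raise ValueError("normalization needs at least 2 rows")
    v = fm.values
    lo = v.min(axis=0)
    span = v.max(axis=0) - lo
    out = np.zeros_like(v)
    ok = span > 0
    out[:, ok] = (v[:, ok] - lo[ok]) / span[ok]
    return FeatureMatrix(out, fm.feature_names, fm.labels)


def build_feature_matrix(
    task_ep: EpochSet,
    rest_ep: EpochSet,
    selected: SelectionResult | None,
    feature_set=DEFAULT_FEATURES,
    labels: tuple[str, str] = ("task", "rest"),
) -> FeatureMatrix:
    """Stack task- and rest-class feature rows and normalize jointly.

    With n trials per class and f features the result is a labelled
    2n x f matrix (each class block n x f)."""
    if task_ep.n_trials != rest_ep.n_trials:
        warnings.warn(
            f"unbalanced classes: {task_ep.n_trials} task vs {rest_ep.n_trials} rest trials",
            UserWarning,
        )
    task_rows = extract_features(task_ep, selected, feature_set)
    rest_rows = extract_features(rest_ep, selected, feature_set)
    fm = FeatureMatrix(
        np.vstack([task_rows, rest_rows]),
        tuple(feature_set),
        (labels[0],) * task_rows.shape[0] + (labels[1],) * rest_rows.shape[0],
    )
    return minmax_normalize(fm)
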