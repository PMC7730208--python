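"""Fisher linear discriminant analysis and leave-one-out cross-validation.

Fisher's criterion J(w) = (wᵀS_B w)/(wᵀS_W w) is maximized by the leading
generalized eigenvector of (S_B, S_W); for two classes this reduces to the
closed form w ∝ S_W⁻¹(μ₁ − μ₂). Classification projects a feature row onto
w and thresholds at the midpoint of the projected class means (equal
priors). Performance is estimated by leave-one-trial-out cross-validation:
each fold holds out one trial's task row together with its paired rest row,
so both classes are tested in every fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .features import FeatureMatrix

__all__ = ["FisherLDA", "LDAResults", "loocv_accuracy"]

_RIDGE = 1e-6  # relative ridge for a singular within-class scatter


def _scatter_matrices(rows_by_class: list[np.ndarray]):
    mu = [r.mean(axis=0) for r in rows_by_class]
    grand = np.vstack(rows_by_class).mean(axis=0)
    d = rows_by_class[0].shape[1]
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for r, m in zip(rows_by_class, mu):
        c = r - m
        sw += c.T @ c
        dm = (m - grand)[:, None]
        sb += r.shape[0] * (dm @ dm.T)
    return sw, sb, mu


class FisherLDA:
    """Two-class Fisher discriminant model.

    Parameters
    ----------
    fm : FeatureMatrix
        Labelled feature rows; exactly two classes. Single-row classes are
        tolerated (the within-class scatter degenerates and is ridged).
    """

    def __init__(self, fm: FeatureMatrix):
        classes = fm.classes
        if len(classes) != 2:
            raise ValueError(f"exactly 2 classes required, got {classes}")
        self.fm = fm
        self.classes = classes
        self._rows = [fm.rows_of(c) for c in classes]
        if any(r.shape[0] < 1 for r in self._rows):
            raise ValueError("each class needs at least 1 sample")

    def fit(self, method: str = "closed_form") -> "LDAResults":
        """Estimate the projection.

        ``method='closed_form'`` uses w = S_W⁻¹(μ₁ − μ₂);
        ``method='eig'`` solves the generalized eigenproblem S_B w = λ S_W w.
        Both give the same direction on nonsingular problems.
        """
        sw, sb, mu = _scatter_matrices(self._rows)
        d = sw.shape[0]
        try:
            w = self._solve(sw, sb, mu, method)
        except linalg.LinAlgError:
            sw = sw + _RIDGE * (np.trace(sw) / d + 1.0) * np.eye(d)
            w = self._solve(sw, sb, mu, method)
        if not np.all(np.isfinite(w)) or not np.any(w):
            sw = sw + _RIDGE * (np.trace(sw) / d + 1.0) * np.eye(d)
            w = self._solve(sw, sb, mu, method)
        # orient toward class 0 having the higher projected mean
        if w @ (mu[0] - mu[1]) < 0:
            w = -w
        proj_means = (float(w @ mu[0]), float(w @ mu[1]))
        return LDAResults(
            projection=w,
            class_means=(mu[0], mu[1]),
            projected_means=proj_means,
            threshold=0.5 * (proj_means[0] + proj_means[1]),
            classes=self.classes,
            sw=sw,
            sb=sb,
        )

    @staticmethod
    def _solve(sw, sb, mu, method):
        if method == "closed_form":
            w = linalg.solve(sw, mu[0] - mu[1], assume_a="sym")
        elif method == "eig":
            vals, vecs = linalg.eigh(sb, sw)
            w = vecs[:, -1]
        else:
            raise ValueError(f"unknown method {method!r}")
        return np.asarray(w, dtype=float)


@dataclass(frozen=True)
class LDAResults:
    """Fitted discriminant: projection vector, class geometry, decision rule."""

    projection: np.ndarray
    class_means: tuple[np.ndarray, np.ndarray]
    projected_means: tuple[float, float]
    threshold: float
    classes: tuple[str, str]
    sw: np.ndarray
    sb: np.ndarray

    def decision_values(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != self.projection.size:
            raise ValueError(
                f"feature dimension {rows.shape[1]} does not match model "
                f"({self.projection.size})"
            )
        return rows @ self.projection - self.threshold

    def predict(self, rows: np.ndarray) -> list[str]:
        """Label by side of the threshold; exact ties go to the first class."""
        dv = self.decision_values(rows)
        return [self.classes[0] if v >= 0 else self.classes[1] for v in dv]

    def summary(self) -> str:
        lines = [
            "Fisher LDA",
            f"classes: {self.classes[0]} vs {self.classes[1]}",
            f"projection: {np.array2string(self.projection, precision=4)}",
            f"projected means: {self.projected_means[0]:.4f} / {self.projected_means[1]:.4f}",
            f"threshold: {self.threshold:.4f}",
        ]
        return "\n".join(lines)


def loocv_accuracy(fm: FeatureMatrix) -> tuple[float, pd.DataFrame]:
    """Leave-one-trial-out cross-validated accuracy, in percent (1 decimal).

    The matrix must hold n task rows followed (or interleaved row-for-row)
    by n rest rows; fold j removes the j-th row of each class, trains on the
    remaining 2(n−1) rows and classifies the 2 held-out rows. Returns the
    percentage of correct predictions over all 2n held-out rows plus a
    per-fold record.
    """
    classes = fm.classes
    if len(classes) != 2:
        raise ValueError("two-class matrix required")
    idx = {c: [i for i, lab in enumerate(fm.labels) if lab == c] for c in classes}
    n = len(idx[classes[0]])
    if n != len(idx[classes[1]]):
        raise ValueError("unbalanced classes: trial pairing undefined")
    if n < 2:
        raise ValueError("need at least 2 trials per class")
    records = []
    correct = 0
    for j in range(n):
        held = [idx[classes[0]][j], idx[classes[1]][j]]
        keep = np.ones(fm.n_samples, dtype=bool)
        keep[held] = False
        train = FeatureMatrix(
            fm.values[keep],
            fm.feature_names,
            tuple(lab for i, lab in enumerate(fm.labels) if keep[i]),
        )
        res = FisherLDA(train).fit()
        pred = res.predict(fm.values[held])
        truth = [fm.labels[i] for i in held]
        hits = sum(p == t for p, t in zip(pred, truth))
        correct += hits
        records.append(
            {"fold": j, "held_out_rows": held, "truth": truth, "predicted": pred, "correct": hits}
        )
    accuracy = round(100.0 * correct / (2 * n), 1)
    return accuracy, pd.DataFrame.from_records(records)
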