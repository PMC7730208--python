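"""Cortically active channel selection.

Three methods decide which fNIRS channels carry task-locked hemodynamic
activity:

* **z-score method** — each channel's averaged trial is cross-correlated
  with the dHRF template; the maximum (signed) correlation per channel is
  standardized across channels and a channel is selected when its z-score is
  strictly positive. Equivalent to "above the channel-population mean".
* **t-value method** — per channel, a robust (bisquare-IRLS) linear
  regression of the averaged trial on the dHRF with an intercept for
  baseline drift; a channel is selected when the coefficient's t-statistic
  exceeds the one-tailed critical value and its p-value is below 0.05.
* **baseline correction** — a channel is selected when the peak of its
  averaged task epoch strictly exceeds the peak of its averaged rest epoch.

Each method is a small model object (constructed from data, ``fit()``
returns a :class:`SelectionResult`); module-level functions wrap the same
surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import correlate, correlation_lags
import statsmodels.api as sm

from .io import Recording
from .preprocess import EpochSet, average_trials

__all__ = [
    "SelectionResult",
    "ZScoreSelector",
    "TValueSelector",
    "BaselineSelector",
    "cross_correlate_max",
    "irls_fit",
    "zscore_select",
    "tvalue_select",
    "baseline_select",
    "apply_selection",
    "DegenerateInputError",
    "EmptySelectionError",
]

BISQUARE_TUNING = 4.685  # default tuning constant of the bisquare ψ-function
IRLS_TOL = 1e-8
IRLS_MAXITER = 50


class DegenerateInputError(ValueError):
    """All-equal scores or otherwise degenerate input to a selector."""


class EmptySelectionError(ValueError):
    """A selection mask retained zero channels."""


@dataclass(frozen=True)
class SelectionResult:
    """Per-channel scores and the boolean selection mask of one method.

    ``scores`` holds the method's primary score per channel (z, t, or
    task-minus-rest peak difference); ``aux`` carries the method's
    auxiliaries aligned with ``channel_ids`` (r and best lag for the z-score
    method; coefficient, intercept, SE and p for the t-value method;
    task/rest peaks for baseline).
    """

    method: str
    scores: np.ndarray
    selected: np.ndarray
    channel_ids: tuple[str, ...]
    aux: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        selected = np.asarray(self.selected, dtype=bool)
        n = len(self.channel_ids)
        if scores.shape != (n,) or selected.shape != (n,):
            raise ValueError("scores/selected must align with channel_ids")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "selected", selected)
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"channel": list(self.channel_ids), "score": self.scores, "selected": self.selected}
        )
        return pd.concat([df, self.aux.reset_index(drop=True)], axis=1)

    def to_report(self) -> dict:
        return {
            "method": self.method,
            "params": dict(self.params),
            "channels": self.to_frame().to_dict(orient="records"),
            "n_selected": self.n_selected,
        }

    def summary(self) -> str:
        lines = [
            f"Channel selection — {self.method} method",
            f"selected {self.n_selected} of {len(self.channel_ids)} channels",
            f"params: {self.params}",
            "",
            self.to_frame().to_string(index=False, float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------

def cross_correlate_max(
    x: np.ndarray, template: np.ndarray, normalized: bool = False
) -> tuple[float, int]:
    """Maximum of the raw sliding cross-correlation and the lag attaining it.

    Computes ``r(τ) = Σ_t x(t)·y(t−τ)`` over every full zero-padded overlap
    lag and returns the signed maximum (not max ``|r|``: an anti-correlated
    channel must score low). Ties are broken toward the smallest ``|τ|``,
    then the negative lag. With ``normalized=True`` the product sum is
    divided by the vectors' root energy product (unit-energy variant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(template, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both vectors need at least 2 samples")
    r = correlate(x, y, mode="full", method="direct")
    lags = correlation_lags(x.size, y.size, mode="full")
    if normalized:
        denom = np.sqrt(np.sum(x**2) * np.sum(y**2))
        r = r / denom if denom > 0 else np.zeros_like(r)
    m = r.max()
    cand = lags[np.nonzero(r == m)[0]]
    lag = min(cand, key=lambda t: (abs(t), t))
    return float(m), int(lag)


# ---------------------------------------------------------------------------
# robust regression
# ---------------------------------------------------------------------------

class IRLSFit(NamedTuple):
    phi: float       # dHRF coefficient
    psi: float       # baseline (intercept)
    se_phi: float
    t: float
    p: float         # one-tailed upper-tail, df = k - 1
    converged: bool


def irls_fit(y: np.ndarray, x: np.ndarray) -> IRLSFit:
    """Robust linear fit ``y = φ·x + ψ·1 + ε`` by bisquare IRLS.

    The t-statistic is ``φ / SE(φ)`` with a one-tailed upper-tail p-value at
    ``k − 1`` degrees of freedom (activation is a positive-coefficient
    hypothesis). A numerically exact fit (zero residuals) reports ``t = +∞``
    and ``p = 0`` — the analytic limit.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be equal-length 1-D vectors")
    k = y.size
    if k < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("design vector x is constant; coefficient unidentifiable")
    exog = np.column_stack([x, np.ones(k)])
    df = k - 1

    coef, *_ = np.linalg.lstsq(exog, y, rcond=None)
    resid = y - exog @ coef
    scale = max(1.0, float(np.abs(y).max()))
    if np.abs(resid).max() <= 1e-10 * scale:
        # analytic limit of t = phi/SE as SE -> 0, sign following phi
        phi = float(coef[0])
        t = np.inf if phi > 0 else (-np.inf if phi < 0 else 0.0)
        return IRLSFit(phi, float(coef[1]), 0.0, t, float(stats.t.sf(t, df)), True)

    model = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_TUNING))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL, conv="coefs")
    converged = bool(getattr(res, "converged", True))
    if not converged:
        warnings.warn("IRLS did not converge; returning last iterate", RuntimeWarning)
    phi, psi = float(res.params[0]), float(res.params[1])
    se = float(res.bse[0])
    if se == 0:
        t = np.inf if phi > 0 else (-np.inf if phi < 0 else 0.0)
    else:
        t = phi / se
    p = float(stats.t.sf(t, df))
    return IRLSFit(phi, psi, se, float(t), p, converged)


# ---------------------------------------------------------------------------
# selector models
# ---------------------------------------------------------------------------

def _as_matrix(avg_trial, channel_ids):
    m = np.asarray(avg_trial, dtype=float)
    if m.ndim != 2:
        raise ValueError("avg_trial must be time x channel")
    if channel_ids is None:
        channel_ids = tuple(f"ch{i}" for i in range(m.shape[1]))
    if len(channel_ids) != m.shape[1]:
        raise ValueError("channel_ids must match column count")
    return m, tuple(channel_ids)


class ZScoreSelector:
    """Cross-correlation/z-score channel selection (the proposed method).

    Parameters
    ----------
    avg_trial : ndarray, time x channel
        Averaged trial response per channel (one stimulus type).
    template : ndarray
        dHRF template on the same grid.
    channel_ids : sequence of str, optional
    normalized : bool
        Use the unit-energy cross-correlation variant (default False — raw
        product sums, so response amplitude contributes by design).
    ddof : int
        Degrees-of-freedom convention for the score standard deviation
        (0 = population, 1 = sample). The selected set is invariant to this
        choice since ``z > 0 ⇔ r > mean(r)``.
    """

    def __init__(self, avg_trial, template, channel_ids=None, normalized=False, ddof=0):
        self.avg_trial, self.channel_ids = _as_matrix(avg_trial, channel_ids)
        self.template = np.asarray(template, dtype=float)
        self.normalized = bool(normalized)
        self.ddof = int(ddof)
        if self.avg_trial.shape[1] < 2:
            raise ValueError("z-scoring needs at least 2 channels")

    def fit(self) -> SelectionResult:
        pairs = [
            cross_correlate_max(self.avg_trial[:, i], self.template, self.normalized)
            for i in range(self.avg_trial.shape[1])
        ]
        r = np.array([p[0] for p in pairs])
        lag = np.array([p[1] for p in pairs])
        sigma = r.std(ddof=self.ddof)
        if sigma == 0:
            raise DegenerateInputError(
                "all channels have identical maximum cross-correlation; "
                "z-scores undefined (check preprocessing)"
            )
        z = (r - r.mean()) / sigma
        return SelectionResult(
            method="zscore",
            scores=z,
            selected=z > 0,
            channel_ids=self.channel_ids,
            aux=pd.DataFrame({"r_max": r, "lag": lag}),
            params={"normalized": self.normalized, "ddof": self.ddof},
        )


class TValueSelector:
    """Robust-GLM t-statistic channel selection (the conventional method).

    A channel is active when its averaged trial regresses on the dHRF with
    ``t > t_crt`` and one-tailed ``p < p_max``. ``t_crt`` defaults to the
    one-tailed critical value at α = 0.05 for ``k − 1`` degrees of freedom
    (1.65 at k = 300).
    """

    def __init__(self, avg_trial, template, channel_ids=None, t_crt=None, p_max=0.05):
        self.avg_trial, self.channel_ids = _as_matrix(avg_trial, channel_ids)
        self.template = np.asarray(template, dtype=float)
        if self.template.size != self.avg_trial.shape[0]:
            raise ValueError("template length must equal the epoch length")
        k = self.avg_trial.shape[0]
        self.t_crt = float(stats.t.ppf(0.95, k - 1)) if t_crt is None else float(t_crt)
        self.p_max = float(p_max)

    def fit(self) -> SelectionResult:
        fits = [
            irls_fit(self.avg_trial[:, i], self.template)
            for i in range(self.avg_trial.shape[1])
        ]
        t = np.array([f.t for f in fits])
        p = np.array([f.p for f in fits])
        return SelectionResult(
            method="tvalue",
            scores=t,
            selected=(t > self.t_crt) & (p < self.p_max),
            channel_ids=self.channel_ids,
            aux=pd.DataFrame(
                {
                    "phi": [f.phi for f in fits],
                    "psi": [f.psi for f in fits],
                    "se_phi": [f.se_phi for f in fits],
                    "p": p,
                }
            ),
            params={"t_crt": self.t_crt, "p_max": self.p_max},
        )


class BaselineSelector:
    """Baseline-correction channel selection.

    Compares the peak of the averaged task epoch against the peak of the
    averaged rest epoch per channel; strictly greater task peak selects.
    """

    def __init__(self, task_epochs: EpochSet, rest_epochs: EpochSet):
        if task_epochs.channel_ids != rest_epochs.channel_ids:
            raise ValueError("task and rest epochs cover different channels")
        if task_epochs.n_trials == 0 or rest_epochs.n_trials == 0:
            raise ValueError("both epoch sets must be non-empty")
        self.task_epochs = task_epochs
        self.rest_epochs = rest_epochs

    def fit(self) -> SelectionResult:
        task_peak = average_trials(self.task_epochs).max(axis=0)
        rest_peak = average_trials(self.rest_epochs).max(axis=0)
        return SelectionResult(
            method="baseline",
            scores=task_peak - rest_peak,
            selected=task_peak > rest_peak,
            channel_ids=self.task_epochs.channel_ids,
            aux=pd.DataFrame({"task_peak": task_peak, "rest_peak": rest_peak}),
            params={},
        )


# ---------------------------------------------------------------------------
# functional wrappers & mask application
# ---------------------------------------------------------------------------

def zscore_select(avg_trial, template, channel_ids=None, **kw) -> SelectionResult:
    return ZScoreSelector(avg_trial, template, channel_ids, **kw).fit()


def tvalue_select(avg_trial, template, channel_ids=None, t_crt=None, p_max=0.05) -> SelectionResult:
    return TValueSelector(avg_trial, template, channel_ids, t_crt, p_max).fit()


def baseline_select(task_epochs: EpochSet, rest_epochs: EpochSet) -> SelectionResult:
    return BaselineSelector(task_epochs, rest_epochs).fit()


def apply_selection(obj: Recording | EpochSet, result: SelectionResult | None):
    """Channel-subset view keeping only selected channels, order preserved.

    ``result=None`` is the all-channels comparison arm and returns the input
    unchanged.
    """
    if result is None:
        return obj
    n = len(obj.channel_ids)
    if len(result.channel_ids) != n:
        raise ValueError("selection and input disagree on channel count")
    if result.n_selected == 0:
        raise EmptySelectionError(
            f"{result.method} selection retained no channels; downstream needs >= 1"
        )
    return obj.subset(result.selected)
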