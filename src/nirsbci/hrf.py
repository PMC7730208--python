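"""Canonical hemodynamic response and task-design templates.

The canonical HRF (cHRF) is the standard two-gamma impulse response: a
positive lobe peaking ~5–6 s after a neural event followed by a shallow
undershoot. Convolving it with the binary task indicator (boxcar) gives the
desired hemodynamic response (dHRF) — the template a cortically active
channel is expected to resemble, used both as the cross-correlation template
and as the regression design vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as gamma_fn

from .io import EventSchedule

__all__ = ["HRFParams", "canonical_hrf", "boxcar", "desired_hrf", "trial_template"]


@dataclass(frozen=True)
class HRFParams:
    """Two-gamma HRF shape parameters.

    ``alpha1``/``beta1`` set the delay and dispersion of the positive peak,
    ``alpha2``/``beta2`` those of the undershoot, ``c`` the peak-to-undershoot
    ratio and ``A`` an overall amplitude scale. Defaults follow the widespread
    canonical convention: peak delay 6, undershoot delay 16, unit dispersions,
    ratio 1/6.
    """

    A: float = 1.0
    alpha1: float = 6.0
    beta1: float = 1.0
    alpha2: float = 16.0
    beta2: float = 1.0
    c: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if not (self.alpha1 > 1 and self.alpha2 > 1):
            raise ValueError("alpha1 and alpha2 must exceed 1")
        if not (self.beta1 > 0 and self.beta2 > 0):
            raise ValueError("beta1 and beta2 must be positive")
        if self.c < 0:
            raise ValueError("peak-to-undershoot ratio c must be >= 0")


def canonical_hrf(
    params: HRFParams | None = None, fs: float = 12.5, duration_s: float = 32.0
) -> np.ndarray:
    """Sample the two-gamma canonical HRF on the acquisition grid.

    .. math::

        h_c(t) = A\\left[\\frac{t^{\\alpha_1-1}\\beta_1^{\\alpha_1}
        e^{-\\beta_1 t}}{\\Gamma(\\alpha_1)}
        - c\\,\\frac{t^{\\alpha_2-1}\\beta_2^{\\alpha_2}
        e^{-\\beta_2 t}}{\\Gamma(\\alpha_2)}\\right]

    with t in seconds; h_c(0) = 0 since both shape exponents exceed 1.
    """
    params = params or HRFParams()
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError("duration_s * fs must give at least 2 samples")
    t = np.arange(n) / fs

    def lobe(alpha: float, beta: float) -> np.ndarray:
        out = np.zeros_like(t)
        pos = t > 0
        out[pos] = (
            t[pos] ** (alpha - 1) * beta**alpha * np.exp(-beta * t[pos]) / gamma_fn(alpha)
        )
        return out

    return params.A * (lobe(params.alpha1, params.beta1) - params.c * lobe(params.alpha2, params.beta2))


def boxcar(events: EventSchedule, fs: float, n_samples: int) -> np.ndarray:
    """Binary task indicator: 1 on task samples, 0 on rest.

    Each event occupies the half-open sample interval
    ``[round(onset*fs), round((onset+duration)*fs))``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    s = np.zeros(n_samples)
    for onset, dur in zip(events.onsets, events.durations):
        if onset < 0 or onset + dur > n_samples / fs + 1e-9:
            raise ValueError("event outside the sampled interval")
        a = int(round(onset * fs))
        b = a + int(round(dur * fs))  # count from duration: rounding the
        s[a:b] = 1.0                  # endpoint would drop/add edge samples
    return s


def desired_hrf(hc: np.ndarray, s: np.ndarray) -> np.ndarray:
    """dHRF: discrete convolution of the cHRF with the boxcar.

    ``out[k] = Σ_{n=0..k} hc[n]·s[k−n]``, truncated to ``len(s)``.
    """
    hc = np.asarray(hc, dtype=float)
    s = np.asarray(s, dtype=float)
    if hc.size == 0 or s.size == 0:
        raise ValueError("hc and s must be non-empty")
    return np.convolve(hc, s)[: s.size]


def trial_template(
    fs: float,
    window: tuple[float, float],
    task_duration: float,
    params: HRFParams | None = None,
    kernel_duration_s: float = 32.0,
) -> np.ndarray:
    """dHRF template for a single averaged trial.

    Builds the boxcar of one task bout of ``task_duration`` seconds starting
    at the epoch origin within the analysis window ``(start, end)`` seconds
    relative to onset, convolves with the canonical HRF, and returns the
    template sampled like the epoch (length ``round((end-start)*fs)``).
    """
    start, end = window
    n = int(round((end - start) * fs))
    ev = EventSchedule(np.array([max(0.0, -start)]), np.array([task_duration]), ("task",))
    s = boxcar(ev, fs, n)
    hc = canonical_hrf(params, fs, kernel_duration_s)
    return desired_hrf(hc, s)
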