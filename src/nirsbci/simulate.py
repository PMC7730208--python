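"""Seeded synthetic fNIRS session generator with known active channels.

Emulates a block-design session: 60 s initial rest, 20 trials of
(2 s cue + 10 s task + 15–17 s jittered rest), 60 s final rest, 36 channels
at 12.5 Hz. Active channels carry the boxcar⊗cHRF response (normalized to
unit peak and scaled to ``activation_amplitude`` µM of ΔHbO); every channel
carries additive physiological noise: cardiac (~1.1 Hz), respiratory
(~0.25 Hz) and Mayer-wave (~0.1 Hz) sinusoids with per-channel random
phases, a low-frequency random-walk drift, and white noise. The Mayer wave
deliberately sits inside the 0.03–0.15 Hz analysis passband so selection is
tested against an in-band confound. ΔHbR is generated as anti-correlated
scaled activation with independent noise. All randomness is drawn from one
seeded generator, so identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .hrf import HRFParams, boxcar, canonical_hrf, desired_hrf
from .io import EventSchedule, Recording
from .mbll import MBLLParams, inverse_mbll

__all__ = ["SimConfig", "SimTruth", "make_paradigm", "simulate_recording", "default_montage"]

DEFAULT_ACTIVE = (2, 5, 9, 12, 17, 22, 28, 33)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults reproduce the emulated block paradigm.

    Noise components are (amplitude µM, frequency Hz) pairs; ``drift_step``
    is the per-sample standard deviation of the random-walk drift and
    ``white_sd`` the white-noise standard deviation, both in µM.
    """

    n_channels: int = 36
    fs: float = 12.5
    n_trials: int = 20
    cue_s: float = 2.0
    task_s: float = 10.0
    rest_range: tuple[float, float] = (15.0, 17.0)
    lead_in_s: float = 60.0
    lead_out_s: float = 60.0
    active_channels: tuple[int, ...] = DEFAULT_ACTIVE
    activation_amplitude: float = 1.0
    hbr_ratio: float = 1.0 / 3.0
    cardiac: tuple[float, float] = (0.3, 1.1)
    respiratory: tuple[float, float] = (0.2, 0.25)
    mayer: tuple[float, float] = (0.1, 0.1)
    drift_step: float = 0.005
    white_sd: float = 0.15
    hrf: HRFParams = field(default_factory=HRFParams)
    task_label: str = "task"
    seed: int = 42

    def __post_init__(self) -> None:
        if any(c < 0 or c >= self.n_channels for c in self.active_channels):
            raise ValueError("active_channels must lie in [0, n_channels)")
        amps = [self.activation_amplitude, self.cardiac[0], self.respiratory[0],
                self.mayer[0], self.drift_step, self.white_sd]
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be non-negative")
        if not (self.rest_range[0] <= self.rest_range[1]):
            raise ValueError("rest_range must be (lo, hi) with lo <= hi")
        object.__setattr__(self, "active_channels", tuple(sorted(set(self.active_channels))))


@dataclass(frozen=True)
class SimTruth:
    """Simulator manifest: which channels are truly active, and how much."""

    active: np.ndarray
    amplitudes: np.ndarray
    events: EventSchedule
    seed: int

    def to_report(self) -> dict:
        return {
            "active": self.active,
            "amplitudes": self.amplitudes,
            "events": self.events.to_frame().to_dict(orient="records"),
            "seed": self.seed,
        }


def make_paradigm(cfg: SimConfig, rng: np.random.Generator | None = None) -> EventSchedule:
    """Event schedule of the block paradigm; rest jitter from the seeded stream."""
    rng = rng or np.random.default_rng(cfg.seed)
    lo, hi = cfg.rest_range
    rests = rng.uniform(lo, hi, cfg.n_trials)
    onsets = np.empty(cfg.n_trials)
    t = cfg.lead_in_s
    for j in range(cfg.n_trials):
        onsets[j] = t + cfg.cue_s
        t = onsets[j] + cfg.task_s + rests[j]
    return EventSchedule(
        onsets, np.full(cfg.n_trials, cfg.task_s), (cfg.task_label,) * cfg.n_trials
    )


def default_montage(n_channels: int, n_cols: int = 6) -> np.ndarray:
    """Simple grid layout in head-schematic units."""
    idx = np.arange(n_channels)
    return np.column_stack([idx % n_cols, idx // n_cols]).astype(float)


def _noise(cfg: SimConfig, rng: np.random.Generator, t: np.ndarray, scale: float = 1.0) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, freq in (cfg.cardiac, cfg.respiratory, cfg.mayer):
        phase = rng.uniform(0, 2 * np.pi)
        out += scale * amp * np.sin(2 * np.pi * freq * t + phase)
    out += scale * np.cumsum(rng.normal(0.0, cfg.drift_step, t.size))
    out += rng.normal(0.0, scale * cfg.white_sd, t.size)
    return out


def simulate_recording(
    cfg: SimConfig | None = None,
    emit_absorbance: bool = False,
    mbll_params: MBLLParams | None = None,
):
    """Generate a synthetic session.

    Returns ``(hbo, hbr, truth)`` — ΔHbO and ΔHbR :class:`Recording` objects
    plus the :class:`SimTruth` manifest. With ``emit_absorbance=True`` a
    fourth element holds the dual-wavelength absorbance recording obtained
    through the forward Beer–Lambert law, for end-to-end conversion tests.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    events = make_paradigm(cfg, rng)
    total_s = events.end + cfg.rest_range[1] + cfg.lead_out_s
    n = int(round(total_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    s = boxcar(events, cfg.fs, n)
    hc = canonical_hrf(cfg.hrf, cfg.fs)
    act = desired_hrf(hc, s)
    peak = np.abs(act).max()
    if peak > 0:
        act = act / peak  # unit peak: amplitude is peak ΔHbO in µM

    active = np.zeros(cfg.n_channels, dtype=bool)
    active[list(cfg.active_channels)] = True
    amps = np.where(active, cfg.activation_amplitude, 0.0)

    hbo = np.empty((n, cfg.n_channels))
    hbr = np.empty((n, cfg.n_channels))
    for i in range(cfg.n_channels):
        hbo[:, i] = amps[i] * act + _noise(cfg, rng, t)
        hbr[:, i] = -cfg.hbr_ratio * amps[i] * act + _noise(cfg, rng, t, scale=cfg.hbr_ratio)

    ids = tuple(f"ch{i:02d}" for i in range(cfg.n_channels))
    montage = default_montage(cfg.n_channels)
    rec_hbo = Recording(hbo, cfg.fs, "HbO", ids, montage=montage)
    rec_hbr = Recording(hbr, cfg.fs, "HbR", ids, montage=montage)
    truth = SimTruth(active=active, amplitudes=amps, events=events, seed=cfg.seed)
    if emit_absorbance:
        raw = inverse_mbll(rec_hbo, rec_hbr, mbll_params)
        return rec_hbo, rec_hbr, truth, raw
    return rec_hbo, rec_hbr, truth
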