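"""Modified Beer–Lambert law (MBLL) hemoglobin conversion.

Continuous-wave fNIRS measures absorbance change ΔA(t, λ) at two near-infrared
wavelengths. With molar extinction coefficients ε of oxy- and
deoxy-hemoglobin, a differential path-length factor d (accounting for photon
path elongation through scattering tissue) and emitter–detector separation l,
the concentration changes follow from inverting a 2x2 linear system per time
sample:

    [ΔHbO; ΔHbR] = ε⁻¹ · [ΔA(λ1)/(d1·l); ΔA(λ2)/(d2·l)]

Units: ε in µM⁻¹·cm⁻¹, l in cm, d dimensionless — concentrations in µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Recording

__all__ = ["MBLLParams", "mbll_convert", "inverse_mbll", "DEFAULT_EXTINCTION"]

# Molar extinction coefficients of hemoglobin at 760/850 nm in µM⁻¹·cm⁻¹,
# from the standard compiled absorption tables used throughout CW-NIRS
# (values 1e-6 x the customary cm⁻¹/M entries). Rows: wavelength;
# columns: (HbO, HbR).
DEFAULT_EXTINCTION = np.array(
    [
        [586.0e-6, 1548.52e-6],   # 760 nm
        [1058.0e-6, 691.32e-6],   # 850 nm
    ]
)


@dataclass(frozen=True)
class MBLLParams:
    """Parameters of the modified Beer–Lambert law.

    Attributes
    ----------
    extinction : ndarray, shape (2, 2)
        ``extinction[w, 0]`` = ε_HbO(λ_w), ``extinction[w, 1]`` = ε_HbR(λ_w),
        in µM⁻¹·cm⁻¹.
    dpf : tuple of float
        Differential path-length factor per wavelength (dimensionless).
    separation : float
        Emitter–detector distance in cm.
    """

    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    dpf: tuple[float, float] = (6.0, 6.0)
    separation: float = 3.0

    def __post_init__(self) -> None:
        ext = np.asarray(self.extinction, dtype=float)
        if ext.shape != (2, 2):
            raise ValueError("extinction must be 2x2")
        cond = np.linalg.cond(ext)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError("extinction matrix is singular or near-singular")
        if not (self.separation > 0 and all(d > 0 for d in self.dpf)):
            raise ValueError("separation and dpf must be positive")
        object.__setattr__(self, "extinction", ext)
        object.__setattr__(self, "dpf", tuple(float(d) for d in self.dpf))

    @property
    def pathlength(self) -> np.ndarray:
        """Effective optical path d·l per wavelength, cm."""
        return np.asarray(self.dpf) * self.separation


def _split_wavelengths(rec: Recording) -> tuple[np.ndarray, np.ndarray, int]:
    if rec.wavelengths is None or len(rec.wavelengths) != 2:
        raise ValueError("MBLL requires a recording with exactly two wavelengths")
    if rec.n_channels % 2:
        raise ValueError("dual-wavelength recording must have an even column count")
    c = rec.n_channels // 2
    return rec.data[:, :c], rec.data[:, c:], c


def mbll_convert(absorbance: Recording, params: MBLLParams | None = None) -> tuple[Recording, Recording]:
    """Convert dual-wavelength absorbance change to (ΔHbO, ΔHbR) recordings.

    ``absorbance.data`` columns are wavelength-major: the first half holds all
    physiological channels at ``wavelengths[0]``, the second half the same
    channels at ``wavelengths[1]``.
    """
    params = params or MBLLParams()
    a1, a2, c = _split_wavelengths(absorbance)
    dl = params.pathlength
    inv = np.linalg.inv(params.extinction)
    # stack per-sample RHS: (2, time*chan)
    rhs = np.stack([a1 / dl[0], a2 / dl[1]])
    conc = inv @ rhs.reshape(2, -1)
    hbo = conc[0].reshape(a1.shape)
    hbr = conc[1].reshape(a1.shape)
    ids = _strip_wavelength_suffix(absorbance.channel_ids[:c])
    common = dict(fs=absorbance.fs, channel_ids=ids, montage=None)
    return (
        Recording(data=hbo, chromophore="HbO", **common),
        Recording(data=hbr, chromophore="HbR", **common),
    )


def inverse_mbll(hbo: Recording, hbr: Recording, params: MBLLParams | None = None) -> Recording:
    """Forward Beer–Lambert: (ΔHbO, ΔHbR) → dual-wavelength absorbance change.

    The algebraic inverse of :func:`mbll_convert`; used by the simulator to
    emit raw-style data for end-to-end testing.
    """
    params = params or MBLLParams()
    if hbo.data.shape != hbr.data.shape:
        raise ValueError("HbO and HbR recordings must have identical shapes")
    if abs(hbo.fs - hbr.fs) > 1e-12:
        raise ValueError("HbO and HbR sampling rates differ")
    conc = np.stack([hbo.data.ravel(), hbr.data.ravel()])
    ab = (params.extinction @ conc).reshape(2, *hbo.data.shape)
    dl = params.pathlength
    data = np.concatenate([ab[0] * dl[0], ab[1] * dl[1]], axis=1)
    wls = (760.0, 850.0)
    ids = tuple(
        f"{ch}@{int(w)}" for w in wls for ch in hbo.channel_ids
    )
    return Recording(
        data=data, fs=hbo.fs, chromophore="absorbance", channel_ids=ids, wavelengths=wls
    )


def _strip_wavelength_suffix(ids) -> tuple[str, ...]:
    return tuple(i.split("@")[0] for i in ids)
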