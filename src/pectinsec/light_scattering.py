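"""Per-slice Zimm analysis of multi-angle light scattering (MALLS) data.

Each chromatographic slice is treated as a dilute, nearly monodisperse
solution.  The Zimm relation

    K c / R(theta) = 1/Mw + (16 pi^2 / (3 lambda^2)) (Rg^2 / Mw) sin^2(theta/2)

is fitted by ordinary least squares across the detector angles: the
intercept gives the absolute weight-average molar mass of the slice and
the slope its z-average radius of gyration.  ``lambda`` is the in-medium
wavelength lambda_0 / n_0.  The second virial term is neglected
(dilute-slice assumption, standard in SEC-MALLS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import AVOGADRO

__all__ = [
    "OpticalConfig",
    "ZimmFit",
    "optical_constant",
    "slice_concentration",
    "zimm_fit_slice",
    "conformation_slope",
]

#: Default MALLS detector angles (degrees).
DEFAULT_ANGLES = (35.0, 50.0, 75.0, 90.0, 105.0, 130.0, 145.0)


@dataclass(frozen=True)
class OpticalConfig:
    """Scattering optics: vacuum wavelength (nm), solvent refractive index,
    analyte dn/dc (mL/g) and detector angles (degrees)."""

    wavelength_nm: float = 660.0
    solvent_refractive_index: float = 1.333
    dndc: float = 0.146
    angles: tuple = DEFAULT_ANGLES

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0 or self.solvent_refractive_index <= 0:
            raise ValueError("wavelength and refractive index must be positive")
        if self.dndc < 0:
            raise ValueError("dn/dc must be >= 0")
        ang = np.asarray(self.angles, float)
        if ang.size < 1 or np.any((ang <= 0) | (ang >= 180)):
            raise ValueError("need >= 1 angle, each in (0, 180) degrees")
        if len(np.unique(ang)) != ang.size:
            raise ValueError("angles must be distinct")

    @property
    def wavelength_medium_nm(self) -> float:
        """In-medium wavelength lambda_0 / n_0 (nm)."""
        return self.wavelength_nm / self.solvent_refractive_index


def optical_constant(cfg: OpticalConfig) -> float:
    """Light-scattering optical constant K in mol cm^2 g^-2.

    K = 4 pi^2 n0^2 (dn/dc)^2 / (N_A lambda_0^4), with lambda_0 the vacuum
    wavelength in cm and dn/dc in cm^3/g.  Quadratic in dn/dc.
    """
    lam_cm = cfg.wavelength_nm * 1e-7
    n0 = cfg.solvent_refractive_index
    return 4.0 * np.pi**2 * n0**2 * cfg.dndc**2 / (AVOGADRO * lam_cm**4)


def slice_concentration(
    dri: np.ndarray,
    dndc: float,
    response_factor: float,
    elution_volume: np.ndarray | None = None,
    injected_mass: float | None = None,
) -> np.ndarray:
    """Per-slice concentration (g/mL) from the DRI signal.

    The DRI detector responds as S = response_factor * (dn/dc) * c.  When
    ``injected_mass`` (g) is given the profile is rescaled so the eluted
    mass integral equals it, which removes any response-factor error.
    """
    if response_factor == 0:
        raise ValueError("DRI response factor must be non-zero")
    if dndc <= 0:
        raise ValueError("dn/dc must be positive to convert DRI to concentration")
    c = np.asarray(dri, float) / (response_factor * dndc)
    if injected_mass is not None:
        if elution_volume is None:
            raise ValueError("elution_volume required to rescale to injected mass")
        eluted = np.trapezoid(c, np.asarray(elution_volume, float))
        if eluted <= 0:
            raise ValueError("cannot rescale: non-positive eluted mass")
        c = c * (injected_mass / eluted)
    return c


@dataclass(frozen=True)
class ZimmFit:
    """Result of a single-slice Zimm fit."""

    mw: float | None  # Da; None if the fit failed
    rg: float | None  # nm; None if slope <= 0 or single angle
    r_squared: float
    intercept: float
    slope: float

    @property
    def ok(self) -> bool:
        return self.mw is not None


def zimm_fit_slice(kc_over_r: np.ndarray, cfg: OpticalConfig) -> ZimmFit:
    """Fit K c / R against sin^2(theta/2) for one slice.

    Returns the slice Mw from the intercept and Rg from the slope.  A
    non-positive intercept marks the slice as failed; a negative slope
    (downward Zimm line, unphysical for Rg) yields Mw only.
    """
    y = np.asarray(kc_over_r, float)
    ang = np.asarray(cfg.angles, float)
    if y.size != ang.size:
        raise ValueError("one Kc/R value per configured angle required")
    x = np.sin(np.radians(ang) / 2.0) ** 2

    if y.size == 1:
        # single angle: Rg fixed to zero, Mw straight from Kc/R
        if y[0] <= 0:
            return ZimmFit(None, None, 0.0, float(y[0]), 0.0)
        return ZimmFit(1.0 / float(y[0]), None, 1.0, float(y[0]), 0.0)

    slope, intercept = np.polyfit(x, y, 1)
    yhat = intercept + slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if intercept <= 0:
        return ZimmFit(None, None, r2, float(intercept), float(slope))
    mw = 1.0 / intercept
    rg = None
    if slope > 1e-9 * abs(intercept):  # a numerically flat line carries no Rg
        lam = cfg.wavelength_medium_nm
        rg = float(np.sqrt(slope / intercept * 3.0 * lam**2 / (16.0 * np.pi**2)))
    return ZimmFit(float(mw), rg, r2, float(intercept), float(slope))


def conformation_slope(mw: np.ndarray, rh: np.ndarray, min_slices: int = 5) -> float:
    """Scaling exponent of molar mass with hydrodynamic radius.

    Least-squares slope of log10(Mw) against log10(Rh) over retained
    slices.  The slope reflects hydrodynamic compactness: ~3 for compact
    spheres and hyperbranched structures, ~1.7 for swollen linear coils.
    """
    m = np.asarray(mw, float)
    r = np.asarray(rh, float)
    good = np.isfinite(m) & np.isfinite(r) & (m > 0) & (r > 0)
    if good.sum() < min_slices:
        raise ValueError(
            f"need >= {min_slices} slices with positive Mw and Rh, got {int(good.sum())}"
        )
    res = stats.linregress(np.log10(r[good]), np.log10(m[good]))
    return float(res.slope)
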