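"""Universal SEC calibration via hydrodynamic volume.

Size-exclusion chromatography separates macromolecules by hydrodynamic
volume ``Vh``, which universal-calibration theory ties to the product of
intrinsic viscosity and molar mass.  With Mark-Houwink parameters
``K`` and ``a`` for a standard series (here pullulan),

    Vh = (2/5) * K * M**(1 + a) / N_A

converts the molar mass of each narrow standard into a hydrodynamic
volume, and a low-order polynomial fitted to (log10 Vh, elution volume)
becomes a column calibration valid for any analyte whose own
Mark-Houwink parameters are known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MarkHouwink",
    "Standard",
    "CalibrationCurve",
    "CalibrationError",
    "PULLULAN_MH",
    "hydrodynamic_volume",
    "vh_to_rh",
    "rh_to_vh",
    "fit_calibration",
]

AVOGADRO = 6.02214076e23
#: 1 dL = 100 cm^3 = 1e23 nm^3
DL_TO_NM3 = 1.0e23


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs or a non-monotone fit."""


@dataclass(frozen=True)
class MarkHouwink:
    """Mark-Houwink intrinsic-viscosity parameters [eta] = K * M**a.

    Parameters
    ----------
    k : float
        Prefactor in dL/g (converted internally to nm^3 based units).
    a : float
        Dimensionless exponent, typically 0.5-0.8 for random coils.
    """

    k: float
    a: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise CalibrationError(f"Mark-Houwink K must be > 0, got {self.k}")
        if not 0.0 <= self.a <= 2.0:
            raise CalibrationError(f"Mark-Houwink a must be in [0, 2], got {self.a}")


#: Pullulan in aqueous solution at 40 degC (K in dL/g).
PULLULAN_MH = MarkHouwink(k=1.0176e-3, a=0.525)

#: Specific refractive-index increments in mL/g (aqueous eluent).
PECTIN_DNDC = 0.146
PULLULAN_DNDC = 0.149


@dataclass(frozen=True)
class Standard:
    """A narrow calibration standard: nominal molar mass and peak position."""

    molar_mass: float  # Da
    peak_elution_volume: float  # mL

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise CalibrationError(f"standard molar mass must be > 0, got {self.molar_mass}")
        if not self.peak_elution_volume > 0:
            raise CalibrationError(
                f"standard peak elution volume must be > 0, got {self.peak_elution_volume}"
            )


def hydrodynamic_volume(molar_mass, mh: MarkHouwink):
    """Hydrodynamic volume in nm^3 of a chain of molar mass ``molar_mass`` (Da).

    Implements Vh = (2/5) K M^(1+a) / N_A with K in dL/g; the result is
    strictly increasing in M.  Accepts scalars or arrays.
    """
    m = np.asarray(molar_mass, dtype=float)
    if np.any(m <= 0):
        raise CalibrationError("molar mass must be > 0")
    vh_dl = 0.4 * mh.k * m ** (1.0 + mh.a) / AVOGADRO
    out = vh_dl * DL_TO_NM3
    return float(out) if np.isscalar(molar_mass) else out


def vh_to_rh(vh):
    """Hydrodynamic radius (nm) of a sphere with volume ``vh`` (nm^3)."""
    v = np.asarray(vh, dtype=float)
    if np.any(v < 0):
        raise CalibrationError("hydrodynamic volume must be >= 0")
    out = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
    return float(out) if np.isscalar(vh) else out


def rh_to_vh(rh):
    """Sphere volume (nm^3) for hydrodynamic radius ``rh`` (nm)."""
    r = np.asarray(rh, dtype=float)
    if np.any(r < 0):
        raise CalibrationError("hydrodynamic radius must be >= 0")
    out = 4.0 / 3.0 * np.pi * r**3
    return float(out) if np.isscalar(rh) else out


@dataclass(frozen=True)
class CalibrationCurve:
    """Polynomial map elution volume = P(log10 Vh) with a monotone inverse.

    The curve is strictly decreasing on ``log10_vh_range`` (larger species
    elute earlier).  Analyte slices often extend somewhat beyond the
    standards' span, so evaluation and inversion are permitted on the
    wider ``extended_range`` where the polynomial remains strictly
    decreasing, with a warning; beyond that values are clamped to the
    edge (the column does not separate outside its pore-volume window).
    """

    coefficients: tuple  # ascending powers of log10(Vh/nm^3)
    log10_vh_range: tuple  # (lo, hi) spanned by the standards
    residuals: tuple = ()
    standards: tuple = ()
    #: wider interval on which the polynomial is still strictly decreasing;
    #: inversion extrapolates here (with a warning) before clamping
    extended_range: tuple | None = None

    @property
    def inversion_range(self) -> tuple:
        return self.extended_range if self.extended_range is not None else self.log10_vh_range

    # -- evaluation ------------------------------------------------------
    def _poly(self) -> np.polynomial.Polynomial:
        return np.polynomial.Polynomial(self.coefficients)

    def elution_volume(self, log10_vh):
        """Elution volume (mL) at ``log10_vh``; clamps outside the range."""
        x = np.asarray(log10_vh, dtype=float)
        lo, hi = self.inversion_range
        if np.any(x < lo) or np.any(x > hi):
            warnings.warn(
                "log10(Vh) outside calibrated range "
                f"[{lo:.3g}, {hi:.3g}]; clamping to range edge",
                stacklevel=2,
            )
            x = np.clip(x, lo, hi)
        out = self._poly()(x)
        return float(out) if np.isscalar(log10_vh) else out

    def derivative(self, log10_vh):
        """d(elution volume)/d(log10 Vh), in mL per decade (negative)."""
        x = np.clip(np.asarray(log10_vh, dtype=float), *self.inversion_range)
        out = self._poly().deriv()(x)
        return float(out) if np.isscalar(log10_vh) else out

    def log10_vh(self, elution_volume):
        """Invert the curve by bisection on the monotone range.

        Elution volumes beyond the standards' window but within the
        monotone ``extended_range`` are extrapolated with a warning;
        beyond that they are clamped to the edge.
        """
        lo, hi = self.inversion_range
        p = self._poly()
        v_hi, v_lo = p(lo), p(hi)  # curve decreasing: p(lo) > p(hi)
        vel = np.atleast_1d(np.asarray(elution_volume, dtype=float))
        d_lo, d_hi = self.log10_vh_range
        if np.any(vel > p(d_lo) + 1e-12) or np.any(vel < p(d_hi) - 1e-12):
            warnings.warn(
                "elution volume outside the standards' window "
                f"[{p(d_hi):.4g}, {p(d_lo):.4g}] mL; extrapolating the calibration",
                stacklevel=2,
            )
        if np.any(vel > v_hi) or np.any(vel < v_lo):
            warnings.warn(
                f"elution volume outside the monotone window [{v_lo:.4g}, {v_hi:.4g}] mL; "
                "clamping",
                stacklevel=2,
            )
        vel = np.clip(vel, v_lo, v_hi)
        out = np.empty_like(vel)
        for i, v in enumerate(vel):
            if v >= v_hi:
                out[i] = lo
            elif v <= v_lo:
                out[i] = hi
            else:
                out[i] = brentq(lambda x: p(x) - v, lo, hi, xtol=1e-12)
        return float(out[0]) if np.isscalar(elution_volume) else out

    @property
    def rms_residual(self) -> float:
        if not self.residuals:
            return 0.0
        return float(np.sqrt(np.mean(np.square(self.residuals))))

    # -- persistence -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coefficients": list(self.coefficients),
            "log10_vh_range": list(self.log10_vh_range),
            "residuals": list(self.residuals),
            "extended_range": None if self.extended_range is None else list(self.extended_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        ext = d.get("extended_range")
        return cls(
            coefficients=tuple(d["coefficients"]),
            log10_vh_range=tuple(d["log10_vh_range"]),
            residuals=tuple(d.get("residuals", ())),
            extended_range=None if ext is None else tuple(ext),
        )


def _check_monotone_decreasing(poly: np.polynomial.Polynomial, lo: float, hi: float) -> None:
    xs = np.linspace(lo, hi, 512)
    deriv = poly.deriv()(xs)
    bad = deriv >= 0
    if np.any(bad):
        i = int(np.argmax(bad))
        raise CalibrationError(
            "fitted calibration is not strictly decreasing near "
            f"log10(Vh) = {xs[i]:.4g} (derivative {deriv[i]:.3g} mL/decade >= 0); "
            "reduce the polynomial order or check the standards"
        )


def fit_calibration(
    standards: list[Standard],
    mh: MarkHouwink = PULLULAN_MH,
    order: int = 3,
) -> CalibrationCurve:
    """Fit the universal calibration polynomial from narrow standards.

    Each standard's nominal molar mass is mapped to log10(Vh) with the
    standard series' Mark-Houwink parameters, and elution volume is
    regressed on log10(Vh) by least squares.  The fit must be strictly
    decreasing over the standards' range.

    Parameters
    ----------
    standards : list of Standard
    mh : MarkHouwink
        Parameters of the standard series (default pullulan, aqueous, 40 degC).
    order : int
        Polynomial order, 1-5 (default 3, common SEC practice).
    """
    if not 1 <= order <= 5:
        raise CalibrationError(f"polynomial order must be in 1..5, got {order}")
    if len(standards) < order + 1:
        raise CalibrationError(
            f"need at least {order + 1} standards for order {order}, got {len(standards)}"
        )
    vels = np.array([s.peak_elution_volume for s in standards], float)
    if len(np.unique(vels)) != len(vels):
        raise CalibrationError("standards must have distinct peak elution volumes")
    masses = np.array([s.molar_mass for s in standards], float)
    x = np.log10(hydrodynamic_volume(masses, mh))
    order_idx = np.argsort(x)
    x, vels = x[order_idx], vels[order_idx]

    poly = np.polynomial.Polynomial.fit(x, vels, deg=order).convert()
    resid = vels - poly(x)
    lo, hi = float(x.min()), float(x.max())
    _check_monotone_decreasing(poly, lo, hi)

    # extend the usable window outward (up to 2.5 decades each side) as
    # long as the polynomial keeps decreasing; analyte tails routinely
    # elute slightly outside the standards' span
    deriv = poly.deriv()
    step = 0.01
    ext_lo, ext_hi = lo, hi
    while ext_lo > lo - 2.5 and deriv(ext_lo - step) < 0:
        ext_lo -= step
    while ext_hi < hi + 2.5 and deriv(ext_hi + step) < 0:
        ext_hi += step
    return CalibrationCurve(
        coefficients=tuple(float(c) for c in poly.coef),
        log10_vh_range=(lo, hi),
        residuals=tuple(float(r) for r in resid),
        standards=tuple(standards),
        extended_range=(ext_lo, ext_hi),
    )
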