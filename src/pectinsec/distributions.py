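"""SEC weight distributions w(log Vh) and molar-mass moments.

The differential refractive index (DRI) trace S(Vel) is converted to a
weight density over log10 hydrodynamic volume by the change of variable

    w(log Vh) = -S(Vel) * dVel/d(log Vh)

using the (decreasing) universal calibration curve, then normalised to
unit area.  When per-slice weight-average molar masses from light
scattering are attached, the distribution yields Mn, Mw and the
dispersity D = Mw/Mn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationCurve, vh_to_rh

__all__ = ["Chromatogram", "SizeDistribution", "Moments", "weight_distribution", "moments"]


@dataclass
class Chromatogram:
    """Aligned per-slice multi-detector SEC readings.

    Attributes
    ----------
    elution_volume : array, mL, strictly increasing grid.
    dri : array, baseline-corrected DRI signal (detector units).
    rayleigh : array (n_slices, n_angles) of excess Rayleigh ratios, 1/cm.
    angles : array of scattering angles in degrees, each in (0, 180).
    injected_mass : float or None, g.
    """

    elution_volume: np.ndarray
    dri: np.ndarray
    rayleigh: np.ndarray | None = None
    angles: np.ndarray | None = None
    injected_mass: float | None = None

    def __post_init__(self) -> None:
        self.elution_volume = np.asarray(self.elution_volume, float)
        self.dri = np.asarray(self.dri, float)
        n = self.elution_volume.size
        if self.dri.size != n:
            raise ValueError("elution_volume and dri must have the same length")
        if n >= 2 and not np.all(np.diff(self.elution_volume) > 0):
            raise ValueError("elution volume grid must be strictly increasing")
        if self.rayleigh is not None:
            self.rayleigh = np.atleast_2d(np.asarray(self.rayleigh, float))
            if self.rayleigh.shape[0] != n:
                raise ValueError("rayleigh must have one row per slice")
            if self.angles is None:
                raise ValueError("angles required when rayleigh ratios are given")
            self.angles = np.asarray(self.angles, float)
            if self.angles.size != self.rayleigh.shape[1]:
                raise ValueError("one angle per rayleigh column required")
            if len(np.unique(self.angles)) != self.angles.size:
                raise ValueError("angles must be distinct")
            if np.any((self.angles <= 0) | (self.angles >= 180)):
                raise ValueError("angles must lie in (0, 180) degrees")

    def baseline_corrected(self, start_volume: float, end_volume: float) -> "Chromatogram":
        """Subtract a linear DRI baseline anchored at two elution volumes."""
        v = self.elution_volume
        s0 = float(np.interp(start_volume, v, self.dri))
        s1 = float(np.interp(end_volume, v, self.dri))
        baseline = s0 + (s1 - s0) * (v - start_volume) / (end_volume - start_volume)
        return Chromatogram(
            elution_volume=v.copy(),
            dri=self.dri - baseline,
            rayleigh=None if self.rayleigh is None else self.rayleigh.copy(),
            angles=None if self.angles is None else self.angles.copy(),
            injected_mass=self.injected_mass,
        )


@dataclass
class SizeDistribution:
    """Normalised weight density over log10(Vh/nm^3).

    ``w`` integrates to 1 over the ``log10_vh`` grid (trapezoid rule).
    Optional per-slice arrays carry the light-scattering molar mass,
    radius of gyration and DRI-derived concentration on the same grid.
    """

    log10_vh: np.ndarray
    w: np.ndarray
    mw: np.ndarray | None = None  # Da
    rg: np.ndarray | None = None  # nm
    concentration: np.ndarray | None = None  # g/mL

    def __post_init__(self) -> None:
        self.log10_vh = np.asarray(self.log10_vh, float)
        self.w = np.asarray(self.w, float)
        if self.log10_vh.size != self.w.size:
            raise ValueError("grid and density must have the same length")
        if self.log10_vh.size >= 2 and not np.all(np.diff(self.log10_vh) > 0):
            raise ValueError("log10_vh grid must be strictly increasing")
        if np.any(self.w < -1e-12):
            raise ValueError("weight density must be non-negative")
        for name in ("mw", "rg", "concentration"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, float)
                if arr.size != self.log10_vh.size:
                    raise ValueError(f"{name} must match the grid length")
                setattr(self, name, arr)

    @property
    def rh(self) -> np.ndarray:
        """Hydrodynamic radius (nm) at each grid point."""
        return vh_to_rh(10.0**self.log10_vh)

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.w, self.log10_vh))

    def normalized(self) -> "SizeDistribution":
        a = self.area
        if a <= 0:
            raise ValueError("cannot normalise a distribution with non-positive area")
        return SizeDistribution(self.log10_vh, self.w / a, self.mw, self.rg, self.concentration)


@dataclass(frozen=True)
class Moments:
    """Number- and weight-average molar masses and dispersity."""

    mn: float
    mw: float

    def __post_init__(self) -> None:
        if not self.mn > 0 or not self.mw > 0:
            raise ValueError("Mn and Mw must be positive")
        if self.mw < self.mn * (1 - 1e-9):
            raise ValueError(f"Mw ({self.mw:.6g}) < Mn ({self.mn:.6g}) is impossible")

    @property
    def dispersity(self) -> float:
        return self.mw / self.mn


def weight_distribution(
    chrom: Chromatogram,
    calib: CalibrationCurve,
    dri_threshold: float = 0.01,
    rh_exclude: tuple[float, float] | None = None,
) -> SizeDistribution:
    """Convert a DRI trace to the SEC weight distribution w(log10 Vh).

    Slices with DRI below ``dri_threshold`` times the peak maximum are
    discarded (baseline noise destabilises both the Jacobian here and the
    per-slice light-scattering fits).  ``rh_exclude`` optionally removes a
    hydrodynamic-radius window (e.g. a solvent system peak).

    The Jacobian dVel/d(log10 Vh) is evaluated by central differences on
    the mapped grid (one-sided at the ends) and negated; the result is
    normalised to unit area.
    """
    if chrom.dri.size == 0 or np.all(chrom.dri <= 0):
        raise ValueError("empty distribution: no DRI signal above zero")
    keep = chrom.dri > dri_threshold * chrom.dri.max()
    if keep.sum() < 3:
        raise ValueError("empty distribution: fewer than 3 slices above the DRI threshold")
    vel = chrom.elution_volume[keep]
    dri = chrom.dri[keep]
    x = calib.log10_vh(vel)  # decreasing in vel
    # slices clamped to the inversion window edge have no usable size
    lo_i, hi_i = calib.inversion_range
    interior = (x > lo_i + 1e-9) & (x < hi_i - 1e-9)
    if interior.sum() < 3:
        raise ValueError("empty distribution: calibration covers fewer than 3 slices")
    vel, dri, x = vel[interior], dri[interior], x[interior]

    if rh_exclude is not None:
        rh = vh_to_rh(10.0**x)
        inside = (rh >= rh_exclude[0]) & (rh <= rh_exclude[1])
        if np.count_nonzero(~inside) < 3:
            raise ValueError("empty distribution: exclusion window removed all slices")
        vel, dri, x = vel[~inside], dri[~inside], x[~inside]

    # sort ascending in log10(Vh); early-eluting large species come last
    order = np.argsort(x)
    x, dri = x[order], dri[order]
    vel = vel[order]
    jac = np.gradient(vel, x)  # dVel/dlog10Vh, negative
    w = dri * (-jac)
    w = np.clip(w, 0.0, None)
    dist = SizeDistribution(x, w)
    return dist.normalized()


def moments(dist: SizeDistribution) -> Moments:
    """Molar-mass moments Mn, Mw from a distribution with per-slice Mw.

    Weight-average: Mw = sum(w_i M_i) / sum(w_i); number-average:
    Mn = sum(w_i) / sum(w_i / M_i), with w_i the weight density times the
    trapezoid quadrature weight on the log10(Vh) grid.
    """
    if dist.mw is None:
        raise ValueError(
            "per-slice molar masses are missing; run the light-scattering "
            "per-slice analysis first (pectinsec.light_scattering)"
        )
    good = np.isfinite(dist.mw) & (dist.mw > 0) & (dist.w > 0)
    if good.sum() < 2:
        raise ValueError("fewer than 2 slices with valid molar mass")
    x, w, m = dist.log10_vh[good], dist.w[good], dist.mw[good]
    total = np.trapezoid(w, x)
    mw = np.trapezoid(w * m, x) / total
    mn = total / np.trapezoid(w / m, x)
    return Moments(mn=float(mn), mw=float(mw))
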