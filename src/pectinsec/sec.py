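"""SEC-DRI-MALLS analysis as a model/results pair.

``SECMALLSModel`` holds a chromatogram together with the column
calibration and the optical configuration; ``fit()`` runs the slice-wise
analysis (weight distribution, concentrations, Zimm fits) and returns a
``SECMALLSResults`` carrying the distribution, per-slice table, molar
mass moments, conformation slope and diagnostics, with a ``summary()``
table in the style of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, vh_to_rh
from .distributions import Chromatogram, Moments, SizeDistribution, moments, weight_distribution
from .light_scattering import (
    OpticalConfig,
    conformation_slope,
    optical_constant,
    slice_concentration,
    zimm_fit_slice,
)

__all__ = ["SECMALLSModel", "SECMALLSResults"]

#: Default DRI response factor (detector units per (dn/dc * g/mL)).
DEFAULT_DRI_RESPONSE = 1.0e5


class SECMALLSModel:
    """Slice-wise SEC-DRI-MALLS analysis of one pectin fraction.

    Parameters
    ----------
    chromatogram : Chromatogram
        Baseline-corrected, detector-aligned multi-detector trace.
    calibration : CalibrationCurve
        Universal calibration of the column set-up.
    optics : OpticalConfig
        Wavelength, solvent index, analyte dn/dc and MALLS angles.
    dri_response_factor : float
        DRI response S = f * (dn/dc) * c; superseded by the injected mass
        rescaling when the chromatogram carries one.
    dri_threshold : float
        Slice retention cut as a fraction of the DRI peak maximum.
    min_r_squared : float
        Zimm fits below this r^2 are flagged and excluded from moments
        (they still contribute to the weight distribution).
    rh_exclude : (float, float) or None
        Optional hydrodynamic-radius window (nm) removed from the
        analysis, e.g. a solvent system peak at small Rh.
    """

    def __init__(
        self,
        chromatogram: Chromatogram,
        calibration: CalibrationCurve,
        optics: OpticalConfig | None = None,
        dri_response_factor: float = DEFAULT_DRI_RESPONSE,
        dri_threshold: float = 0.01,
        min_r_squared: float = 0.2,
        rh_exclude: tuple[float, float] | None = None,
    ) -> None:
        if chromatogram.rayleigh is None:
            raise ValueError("chromatogram carries no Rayleigh ratios; MALLS data required")
        self.chromatogram = chromatogram
        self.calibration = calibration
        self.optics = optics if optics is not None else OpticalConfig(angles=tuple(chromatogram.angles))
        if len(self.optics.angles) != chromatogram.rayleigh.shape[1]:
            raise ValueError("optics angle count must match the Rayleigh columns")
        self.dri_response_factor = dri_response_factor
        self.dri_threshold = dri_threshold
        self.min_r_squared = min_r_squared
        self.rh_exclude = rh_exclude

    def fit(self) -> "SECMALLSResults":
        chrom = self.chromatogram
        keep = chrom.dri > self.dri_threshold * chrom.dri.max()
        if keep.sum() < 3:
            raise ValueError("fewer than 3 slices above the DRI retention threshold")
        vel = chrom.elution_volume[keep]
        dri = chrom.dri[keep]
        ray = chrom.rayleigh[keep]

        x = self.calibration.log10_vh(vel)
        lo_i, hi_i = self.calibration.inversion_range
        interior = (x > lo_i + 1e-9) & (x < hi_i - 1e-9)
        if interior.sum() < 3:
            raise ValueError("calibration covers fewer than 3 retained slices")
        vel, dri, ray, x = vel[interior], dri[interior], ray[interior], x[interior]
        if self.rh_exclude is not None:
            rh = vh_to_rh(10.0**x)
            inside = (rh >= self.rh_exclude[0]) & (rh <= self.rh_exclude[1])
            vel, dri, ray, x = vel[~inside], dri[~inside], ray[~inside], x[~inside]

        conc = slice_concentration(
            dri,
            self.optics.dndc,
            self.dri_response_factor,
            elution_volume=vel,
            injected_mass=chrom.injected_mass,
        )
        k_opt = optical_constant(self.optics)

        n = vel.size
        mw = np.full(n, np.nan)
        rg = np.full(n, np.nan)
        r2 = np.full(n, np.nan)
        flags = np.full(n, "ok", dtype=object)
        for i in range(n):
            if conc[i] <= 0 or np.any(ray[i] <= 0):
                flags[i] = "no_signal"
                continue
            fit = zimm_fit_slice(k_opt * conc[i] / ray[i], self.optics)
            r2[i] = fit.r_squared
            if not fit.ok:
                flags[i] = "failed"
                continue
            mw[i] = fit.mw
            if fit.rg is not None:
                rg[i] = fit.rg
            if fit.r_squared < self.min_r_squared:
                flags[i] = "low_r2"

        order = np.argsort(x)
        x, vel, dri, conc = x[order], vel[order], dri[order], conc[order]
        mw, rg, r2, flags = mw[order], rg[order], r2[order], flags[order]

        jac = np.gradient(vel, x)
        w = np.clip(dri * (-jac), 0.0, None)
        area = np.trapezoid(w, x)
        if area <= 0:
            raise ValueError("empty distribution: weight density has non-positive area")
        w = w / area

        # moments over slices with a trustworthy Zimm fit
        mw_for_moments = np.where(flags == "ok", mw, np.nan)
        dist = SizeDistribution(x, w, mw=mw_for_moments, rg=rg, concentration=conc)
        mom = moments(dist)
        rh = dist.rh
        try:
            slope = conformation_slope(mw_for_moments, rh)
        except ValueError:
            slope = np.nan

        slices = pd.DataFrame(
            {
                "elution_ml": vel,
                "log10_vh": x,
                "rh_nm": rh,
                "conc_g_ml": conc,
                "w": w,
                "mw_da": mw,
                "rg_nm": rg,
                "r_squared": r2,
                "flag": flags.astype(str),
            }
        )
        return SECMALLSResults(
            model=self,
            distribution=dist,
            slices=slices,
            moments=mom,
            conformation_slope=float(slope),
        )


@dataclass
class SECMALLSResults:
    """Fitted per-fraction SEC-MALLS results."""

    model: SECMALLSModel
    distribution: SizeDistribution
    slices: pd.DataFrame
    moments: Moments
    conformation_slope: float

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def n_flagged(self) -> int:
        return int((self.slices["flag"] != "ok").sum())

    def summary(self) -> str:
        """Human-readable summary table of the fitted quantities."""
        mom = self.moments
        rh = self.distribution.rh
        lines = [
            "SEC-DRI-MALLS Results",
            "=" * 46,
            f"{'Slices retained':<30}{self.n_slices:>16d}",
            f"{'Slices flagged':<30}{self.n_flagged:>16d}",
            f"{'Rh range (nm)':<30}{rh.min():>7.2f} -{rh.max():>7.2f}",
            f"{'Mn (Da)':<30}{mom.mn:>16.0f}",
            f"{'Mw (Da)':<30}{mom.mw:>16.0f}",
            f"{'Dispersity (D)':<30}{mom.dispersity:>16.2f}",
            f"{'Conformation slope':<30}{self.conformation_slope:>16.3f}",
            "=" * 46,
            "conformation slope: d log Mw / d log Rh (3 = compact sphere,",
            "~1.7 = swollen linear coil)",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-slice results as a DataFrame (column layout of the slice file)."""
        return self.slices.copy()

    def plot(self, ax=None):
        """Plot w(log Vh) and Mw(Vh) against hydrodynamic radius."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rh = self.distribution.rh
        ax.plot(rh, self.distribution.w, label="w(log Vh)")
        ax.set_xscale("log")
        ax.set_xlabel("Rh (nm)")
        ax.set_ylabel("w(log Vh)")
        ax2 = ax.twinx()
        ax2.plot(rh, self.slices["mw_da"], color="C1", label="Mw(Vh)")
        ax2.set_yscale("log")
        ax2.set_ylabel("Mw (Da)")
        return ax
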