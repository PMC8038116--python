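"""Synthetic SEC-MALLS runs and linkage tables with known ground truth.

Every input the analysis consumes can be generated from a fully
specified truth: narrow standards on a known calibration curve;
multi-detector chromatograms from log-normal molar-mass mixtures pushed
through the universal calibration with Gaussian band broadening and
multiplicative detector noise; and linkage tables constructed from a
known domain composition with explicit backbone/branch/terminal
bookkeeping.  The generators are the oracles for recovery tests: at
zero noise the analysis chain inverts them exactly (up to
discretisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .calibration import (
    CalibrationCurve,
    MarkHouwink,
    PULLULAN_MH,
    Standard,
    fit_calibration,
    hydrodynamic_volume,
)
from .distributions import Chromatogram
from .light_scattering import OpticalConfig, optical_constant
from .linkage_domains import LinkageTable
from .sec import DEFAULT_DRI_RESPONSE

__all__ = [
    "MwdSpec",
    "NoiseSpec",
    "BranchingSpec",
    "truth_calibration",
    "simulate_standards_run",
    "simulate_chromatogram",
    "simulate_linkage_table",
    "DEFAULT_STANDARD_MASSES",
]

#: Nominal molar masses (Da) of a pullulan standard kit, 342 Da to 708 kDa.
DEFAULT_STANDARD_MASSES = (342.0, 1320.0, 6300.0, 21700.0, 48800.0, 113000.0, 337000.0, 708000.0)


@dataclass(frozen=True)
class MwdSpec:
    """A molar-mass distribution as a mixture of log-normal components.

    ``components`` is a list of (weight_fraction, median_da, sigma_ln)
    tuples; weight fractions must sum to 1.  ``rg_prefactor_nm`` and
    ``rg_exponent`` define the conformation law Rg = A * M**nu used to
    forward-generate the angular dependence of the scattering.
    """

    components: tuple
    mark_houwink: MarkHouwink = MarkHouwink(k=2.0e-3, a=0.60)  # pectin-like coil
    rg_prefactor_nm: float = 0.03
    rg_exponent: float = 0.55

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("need at least one mixture component")
        wsum = sum(c[0] for c in self.components)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"component weight fractions must sum to 1, got {wsum}")
        if any(c[1] <= 0 or c[2] <= 0 for c in self.components):
            raise ValueError("medians and sigmas must be positive")
        if not 0.2 < self.rg_exponent < 1.0:
            raise ValueError("conformation exponent must lie in (0.2, 1)")

    @classmethod
    def lognormal(cls, mw: float, dispersity: float, **kw) -> "MwdSpec":
        """Single log-normal with target weight-average Mw and dispersity.

        For a log-normal weight distribution D = exp(sigma^2) and
        Mw = median * exp(sigma^2 / 2).
        """
        if dispersity < 1.0:
            raise ValueError("dispersity must be >= 1")
        sigma = np.sqrt(np.log(dispersity)) if dispersity > 1 else 1e-3
        median = mw / np.exp(sigma**2 / 2.0)
        return cls(components=((1.0, float(median), float(sigma)),), **kw)


@dataclass(frozen=True)
class NoiseSpec:
    """Detector noise and band broadening for a simulated run."""

    dri_relative: float = 0.0
    ls_relative: float = 0.0
    band_broadening_ml: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dri_relative < 0 or self.ls_relative < 0 or self.band_broadening_ml < 0:
            raise ValueError("noise levels must be >= 0")


def truth_calibration() -> CalibrationCurve:
    """A realistic ground-truth column calibration.

    Strictly decreasing cubic over log10(Vh) in [-1.5, 7], spanning the
    pullulan kit range on a ~24 mL analytical column set with headroom
    for broad parent-extract distributions.
    """
    return CalibrationCurve(
        coefficients=(22.0, -1.8, -0.03, 0.002),
        log10_vh_range=(-1.5, 7.0),
    )


def simulate_standards_run(
    standard_masses=DEFAULT_STANDARD_MASSES,
    truth: CalibrationCurve | None = None,
    mh: MarkHouwink = PULLULAN_MH,
    noise_ml: float = 0.0,
    seed: int = 0,
) -> list[Standard]:
    """Peak elution volumes of narrow standards on the truth curve."""
    truth = truth or truth_calibration()
    rng = np.random.default_rng(seed)
    masses = np.asarray(standard_masses, float)
    x = np.log10(hydrodynamic_volume(masses, mh))
    vels = truth.elution_volume(x)
    if noise_ml > 0:
        vels = vels + rng.normal(0.0, noise_ml, size=vels.shape)
    return [Standard(float(m), float(v)) for m, v in zip(masses, vels)]


def simulate_chromatogram(
    mwd: MwdSpec,
    truth: CalibrationCurve | None = None,
    optics: OpticalConfig | None = None,
    noise: NoiseSpec | None = None,
    injected_mass: float = 5.0e-4,
    dri_response_factor: float = DEFAULT_DRI_RESPONSE,
    slice_width_ml: float = 0.02,
) -> Chromatogram:
    """Forward-simulate a multi-detector SEC run from a known MWD.

    The mixture is discretised on a log-mass grid, each mass mapped to an
    elution volume through the analyte Mark-Houwink law and the truth
    calibration, deposited on a uniform elution grid, convolved with
    Gaussian band broadening, and converted to detector signals: DRI
    proportional to concentration and per-angle excess Rayleigh ratios
    from the Zimm relation with Rg from the conformation law.
    Multiplicative Gaussian noise is applied last.
    """
    truth = truth or truth_calibration()
    optics = optics or OpticalConfig()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    from scipy.stats import norm

    # support of the mixture out to +-6 sigma
    ln_lo = min(np.log(m) - 6.0 * s for _, m, s in mwd.components)
    ln_hi = max(np.log(m) + 6.0 * s for _, m, s in mwd.components)
    x_ends = np.log10(hydrodynamic_volume(np.exp([ln_lo, ln_hi]), mwd.mark_houwink))
    lo_x, hi_x = truth.log10_vh_range
    if x_ends.min() < lo_x or x_ends.max() > hi_x:
        raise ValueError(
            "molar-mass distribution maps outside the calibrated range: "
            f"log10(Vh) in [{x_ends.min():.2f}, {x_ends.max():.2f}] vs [{lo_x}, {hi_x}]"
        )
    vel_ends = truth.elution_volume(x_ends)

    pad = 4.0 * noise.band_broadening_ml + 5.0 * slice_width_ml
    edges = np.arange(vel_ends.min() - pad, vel_ends.max() + pad + slice_width_ml, slice_width_ml)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # deposit mass analytically: invert each bin edge to ln(M) and use the
    # mixture's closed-form mass within the bin (exact, no grid jitter)
    x_edges = truth.log10_vh(edges)
    # log10 Vh = x0 + (1+a) log10 M  =>  ln M affine in x
    x0 = np.log10(hydrodynamic_volume(1.0, mwd.mark_houwink))
    ln_m_edges = (x_edges - x0) * np.log(10.0) / (1.0 + mwd.mark_houwink.a)
    # elution increases as mass decreases: ln_m_edges is decreasing
    mass_per_bin = np.zeros(centers.size)
    massm_per_bin = np.zeros(centers.size)
    for wf, med, sig in mwd.components:
        z = (ln_m_edges - np.log(med)) / sig
        cdf = norm.cdf(z)
        mass_per_bin += wf * (cdf[:-1] - cdf[1:])
        # partial first moment of a log-normal weight density over the bin
        mean_m = med * np.exp(sig**2 / 2.0)
        cdf_m = norm.cdf(z - sig)
        massm_per_bin += wf * mean_m * (cdf_m[:-1] - cdf_m[1:])

    if noise.band_broadening_ml > 0:
        sigma_bins = noise.band_broadening_ml / slice_width_ml
        mass_per_bin = gaussian_filter1d(mass_per_bin, sigma_bins, mode="constant")
        massm_per_bin = gaussian_filter1d(massm_per_bin, sigma_bins, mode="constant")

    # normalise deposited mass to the injected mass (same factor for both
    # convolutions so the local mass-weighted Mw is unchanged)
    scale = injected_mass / mass_per_bin.sum()
    mass_per_bin = mass_per_bin * scale
    massm_per_bin = massm_per_bin * scale

    conc = mass_per_bin / slice_width_ml  # g/mL per slice
    with np.errstate(invalid="ignore", divide="ignore"):
        mw_local = np.where(mass_per_bin > 0, massm_per_bin / mass_per_bin, np.nan)
    rg_local = mwd.rg_prefactor_nm * np.where(np.isnan(mw_local), 0.0, mw_local) ** mwd.rg_exponent

    dri = dri_response_factor * optics.dndc * conc
    k_opt = optical_constant(optics)
    lam = optics.wavelength_medium_nm
    ang = np.asarray(optics.angles, float)
    s2 = np.sin(np.radians(ang) / 2.0) ** 2
    form = 1.0 + (16.0 * np.pi**2 / (3.0 * lam**2)) * rg_local[:, None] ** 2 * s2[None, :]
    with np.errstate(invalid="ignore"):
        rayleigh = np.where(
            np.isnan(mw_local)[:, None], 0.0, k_opt * conc[:, None] * np.nan_to_num(mw_local)[:, None] / form
        )

    if noise.dri_relative > 0:
        dri = dri * (1.0 + rng.normal(0.0, noise.dri_relative, size=dri.shape))
    if noise.ls_relative > 0:
        rayleigh = rayleigh * (1.0 + rng.normal(0.0, noise.ls_relative, size=rayleigh.shape))

    return Chromatogram(
        elution_volume=centers,
        dri=dri,
        rayleigh=rayleigh,
        angles=ang,
        injected_mass=injected_mass,
    )


@dataclass(frozen=True)
class BranchingSpec:
    """Backbone/branch/terminal proportions for linkage-table synthesis.

    Branch frequencies are the fraction of backbone residues carrying a
    side chain; ``hg_dp``/``xga_dp`` set the terminal fraction of the
    respective backbones (one terminal per chain of DP residues).
    """

    arabinan_branch_freq: float = 0.30
    rgi_rha_branch_freq: float = 0.65
    agi_branch_freq: float = 0.25
    agii_branch_freq: float = 0.20
    hg_dp: float = 30.0
    xga_dp: float = 2.0  # one t-Xylp per substituted backbone residue

    def __post_init__(self) -> None:
        for f in (self.arabinan_branch_freq, self.agi_branch_freq, self.agii_branch_freq):
            if not 0.0 <= f < 1.0:
                raise ValueError("branch frequencies must be in [0, 1)")
        if not 0.0 <= self.rgi_rha_branch_freq <= 1.0:
            raise ValueError("RG-I Rha branch frequency must be in [0, 1]")
        if self.hg_dp <= 1:
            raise ValueError("HG DP must exceed 1")


def simulate_linkage_table(
    domain_mol_percent: dict[str, float],
    branching: BranchingSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    fraction: str | None = None,
) -> LinkageTable:
    """Generate a PMAA linkage table from a known domain composition.

    At zero noise the default assignment rules recover
    ``domain_mol_percent`` exactly (inverse-forward identity): every
    domain's linkages are emitted with the backbone/branch/terminal
    proportions of ``branching``, and shared pools (t-Araf, 4-GalpA,
    t-Galp) are sized so the demand-driven apportionment splits them
    back correctly.  Gaussian noise of ``noise_sd`` mol% is added to each
    emitted linkage, clipping at zero.
    """
    branching = branching or BranchingSpec()
    d = {k: float(v) for k, v in domain_mol_percent.items()}
    if any(v < 0 for v in d.values()):
        raise ValueError("domain percentages must be non-negative")
    if sum(d.values()) > 100.0 + 1e-9:
        raise ValueError("domain percentages must sum to <= 100")

    out: dict[str, float] = {}

    def add(link: str, amount: float) -> None:
        if amount > 0:
            out[link] = out.get(link, 0.0) + amount

    # Homogalacturonan: linear 4-GalpA chain, one terminal per chain
    hg = d.get("HG", 0.0)
    add("t-GalpA", hg / branching.hg_dp)
    add("4-GalpA", hg * (1.0 - 1.0 / branching.hg_dp))

    # Xylogalacturonan: 3,4-GalpA backbone residues each bearing one t-Xylp
    xga = d.get("XGA", 0.0)
    add("3,4-GalpA", xga / 2.0)
    add("t-Xylp", xga / 2.0)

    # RG-I: alternating Rha/GalA backbone; branched Rha are 2,4-linked
    rgi = d.get("RG-I", 0.0)
    b = branching.rgi_rha_branch_freq
    add("2-Rhap", rgi / 2.0 * (1.0 - b))
    add("2,4-Rhap", rgi / 2.0 * b)
    add("4-GalpA", rgi / 2.0)

    # Arabinan: 5-linked backbone, 3,5-branch points matched by terminals
    ara = d.get("Arabinan", 0.0)
    f = branching.arabinan_branch_freq
    backbone = ara / (1.0 + f)
    add("3,5-Araf", backbone * f)
    add("t-Araf", backbone * f)
    add("5-Araf", backbone * (1.0 - f) * 0.70)
    add("3-Araf", backbone * (1.0 - f) * 0.30)

    # AG-I: 4-Galp backbone, 4,6-branch points carrying t-Araf
    agi = d.get("AG-I", 0.0)
    g = branching.agi_branch_freq
    bb = agi / (1.0 + g)
    add("4,6-Galp", bb * g)
    add("t-Araf", bb * g)
    add("4-Galp", bb * (1.0 - g))

    # AG-II: 3- and 6-linked galactan, 3,6-branch points carrying t-Galp
    agii = d.get("AG-II", 0.0)
    h = branching.agii_branch_freq
    bb2 = agii / (1.0 + h)
    add("3,6-Galp", bb2 * h)
    add("t-Galp", bb2 * h)
    add("3-Galp", bb2 * (1.0 - h) * 0.40)
    add("6-Galp", bb2 * (1.0 - h) * 0.40)
    add("2-Araf", bb2 * (1.0 - h) * 0.20)

    # Hemicelluloses and unassigned residues
    add("4-Xylp", d.get("HX", 0.0))
    hm = d.get("HM", 0.0)
    add("4-Manp", hm * 0.6)
    add("4-Glcp", hm * 0.4)
    add("t-Glcp", d.get("Others", 0.0))

    # feasibility: terminals must cover branch points at zero noise
    terminals = out.get("t-Araf", 0.0) + out.get("t-Galp", 0.0)
    branch_points = out.get("3,5-Araf", 0.0) + out.get("4,6-Galp", 0.0) + out.get("3,6-Galp", 0.0)
    if terminals + 1e-9 < branch_points:
        raise ValueError(
            f"infeasible branching: terminals {terminals:.3f} < branch points {branch_points:.3f}"
        )

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for k in list(out):
            out[k] = max(0.0, out[k] + rng.normal(0.0, noise_sd))

    return LinkageTable(mol_percent=out, fraction=fraction)
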