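# Methods

## Scope and data model

The package processes one pectin fraction at a time through two chains
that meet in a per-fraction macromolecular model:

1. **SEC-DRI-MALLS**: standards → universal calibration → weight
   distribution w(log Vh) → per-slice Zimm molar masses → moments
   (Mn, Mw, D), conformation slope, DP.
2. **Linkage → domains**: PMAA mol% table → per-sugar totals →
   rule-based domain apportionment → per-domain mol% and DP.

The central objects are `SECMALLSModel`/`SECMALLSResults` (fit/results
pair), `CalibrationCurve`, `SizeDistribution`, `LinkageTable`,
`DomainComposition` and `FractionModel`.

## Universal calibration

Hydrodynamic volume from molar mass: Vh = (2/5)·K·M^(1+a)/N_A, K in
dL/g (1 dL = 10²³ nm³), applied with the nominal molar mass of each
narrow standard (assumed monodisperse). Elution volume is regressed on
log₁₀ Vh with an ordinary least-squares polynomial, order 3 by default
(configurable 1–5); order 3 is common SEC practice and the data never
constrain it further. The fit must be strictly decreasing over the
standards' range; a non-monotone fit is an error naming the offending
interval.

**Extrapolation.** Analyte slices routinely elute slightly outside the
standards' span, and real columns separate somewhat beyond the largest
standard (708 kDa pullulan corresponds to Rh ≈ 24 nm, yet pectin
extracts show material to ~40 nm). The curve therefore inverts over the
widest interval on which the fitted polynomial remains strictly
decreasing (at most 2.5 decades beyond each end), emitting a warning
when extrapolating; beyond that interval values are clamped to the edge
and such slices are dropped from distributions. Inversion is by
bisection (`brentq`, xtol 10⁻¹²); the round trip V_el→Vh→V_el is exact
to well below 10⁻⁶ mL.

Units throughout: Da, mL, nm, nm³; dn/dc in mL/g (0.146 for pectin,
0.149 for pullulan, selectable per run).

## Weight distribution and moments

Slices with DRI below 1% of the peak maximum are discarded: the
Jacobian of Eq-of-change −dV_el/d log Vh and the per-slice Zimm fits
are both unstable in baseline noise. The Jacobian is evaluated by
central differences on the mapped grid (one-sided at the ends), the
density clipped at zero and normalised to unit trapezoid area
(tolerance 10⁻⁹). A configurable Rh exclusion window can remove solvent
system peaks (common at Rh ~ 1–2 nm); none is excluded by default.
Baseline correction is a linear baseline between two user-chosen
volumes — the simplest reproducible rule.

Moments use the weight density with trapezoid quadrature:
Mw = ∫w·M / ∫w, Mn = ∫w / ∫(w/M), D = Mw/Mn. Note the 1% retention
threshold truncates tails and biases Mw by a few tenths of a percent on
narrow peaks; recovery tests at zero noise lower it explicitly.

## Per-slice light scattering

The Zimm line K·c/R vs sin²(θ/2) is fitted by OLS per slice (the Zimm
form, not Berry or Guinier). λ is the in-medium wavelength λ₀/n₀.
Default optics — 660 nm vacuum wavelength, n₀ = 1.333, seven angles
between 35° and 145° — are instrument-typical configuration values, not
claims about any particular data set. Concentration comes from the DRI
signal (S = f·(dn/dc)·c); when the injected mass is known the profile
is rescaled so the eluted mass matches it, removing response-factor
error. Slices with non-positive intercept are failed (no Mw); a
non-positive slope yields Mw without Rg; fits with r² < 0.2 are flagged
and excluded from the moments but retained in w(log Vh). The second
virial term is neglected (dilute-slice assumption). The conformation
slope is the OLS slope of log₁₀ Mw vs log₁₀ Rh over retained slices
(≥ 5 required): ~3 for compact/hyperbranched, ~1.7 for swollen linear
coils.

## Composition and DP

Anhydro residue masses: pentoses 132.12, hexoses 162.14, rhamnose
146.14, uronic acids 176.13 Da (monomer − 18.02 for water). The average
M_ws defaults to the **number** (harmonic) mean over weight fractions,
because DP converts a molar mass into a residue count; the weight
(arithmetic) mean is also exposed since published tables rarely state
which average was used. DP = Mw/M_ws, reported rounded to the nearest
ten by default (half away from zero), raw value always retained. In the
bundled reference data two fractions (P2, P6) are consistent with
Mn/M_ws rather than Mw/M_ws; this package follows the Mw/M_ws
definition and does not replicate that inconsistency.

## Domain assignment

Rules are data (`data/default_rules.yaml`), not code, because
Pettolino-style assignments vary by tissue. Assignment order:

1. **GalA split**: XGA takes 3,4-GalpA up to the available t-Xylp (and
   an equal amount of t-Xylp); the remaining 3,4-GalpA is RG-I; RG-I
   takes 4-GalpA equal to its Rha backbone units (2- + 2,4-Rhap) minus
   the 3,4-GalpA it already holds (clamped at the available 4-GalpA
   with a warning); the rest of 4-GalpA is HG.
2. **Direct claims**: arabinan (3-, 5-, 3,5-, 2,5-, 2,3,5-Araf), AG-I
   (4-, 4,6-, 3,4-Galp), AG-II (3-, 6-, 3,6-Galp, 2-Araf), RG-I
   (2-, 2,4-Rhap), HG (t-GalpA), xylan (4-Xylp), mannan/glucan
   (4-/4,6-Manp, 4-/4,6-Glcp).
3. **Terminal demands**, in order: AG-I branch points (4,6- + 3,4-Galp)
   consume t-Araf then t-Galp; AG-II branch points (3,6-Galp) consume
   t-Rhap, t-Arap, then t-Galp. Unsatisfied demand is recorded, never
   invented.
4. Remaining t-Araf caps the arabinan side chains; everything else
   (t-Glcp, GlcA, surplus terminals) goes to Others.

Every input mol% is allocated exactly once; the grand total is
conserved to 10⁻⁹ and all clamping events are recorded on the result.
Inputs are not renormalised to 100% (printed tables round). Published
per-column terminal splits are not mutually consistent across
fractions; the shipped priorities reproduce the high-molar-mass
fraction's column exactly, and only the deterministic cells (GalA
split, direct linkages, HG/XGA totals) are asserted in tests.

Per-domain DP = domain mole fraction × total DP, under the assumptions
that the domains of a fraction are covalently linked and the fraction
is effectively monodisperse (fractionated samples have D ≈ 1.1–1.3, so
this is a first-order approximation; for the parent extract with
D > 2 it is qualitative only).

The architectural classification ("RG-I-rich branched" when RG-I plus
side chains ≥ 60 mol%; "HG-rich linear" when HG ≥ 25 mol%; otherwise
"mixed/free-domain") is a configurable heuristic summary, not a
measured quantity.

## Synthetic data

The generators are the oracles for recovery testing and emulate the
study conditions:

* **Standards**: a pullulan kit of eight masses from 342 Da to 708 kDa
  placed on a known, strictly decreasing cubic truth calibration
  (coefficients 22.0, −1.8, −0.03, 0.002 over log₁₀ Vh ∈ [−1.5, 7]),
  with optional Gaussian jitter on the peak volumes.
* **Chromatograms**: molar-mass distributions are mixtures of
  log-normals (standard for polysaccharide extracts); the default
  high-molar-mass fraction emulation is a single log-normal with
  Mw = 59 000 Da and D = 1.3. Mass is deposited analytically per
  0.02 mL elution bin through the analyte Mark–Houwink law
  (K = 2×10⁻³ dL/g, a = 0.60, coil-like) and the truth curve, using the
  closed-form log-normal partial moments (no discretisation jitter),
  then convolved with Gaussian band broadening (default used in tests:
  σ = 0.1 mL). Detector signals follow: DRI ∝ c, and per-angle Rayleigh
  ratios from the Zimm relation with Rg = 0.03·M^0.55 nm. Noise is
  multiplicative Gaussian (1% in the recovery tests), matching detector
  behaviour and keeping signals positive. Injected mass defaults to
  0.5 mg (100 µL of a 5 mg/mL solution).
* **Linkage tables**: each domain emits its backbone, branch-point and
  terminal linkages with explicit branching frequencies (arabinan 0.30,
  RG-I Rha 0.65, AG-I 0.25, AG-II 0.20; HG DP 30); shared pools
  (t-Araf, 4-GalpA, t-Galp) are sized so the forward assignment returns
  the generating composition exactly at zero noise. Additive Gaussian
  noise per linkage (clipped at zero) models measurement scatter.

What the generators do **not** emulate: inter-detector delay volumes
and band-broadening mismatch between detectors (assumed pre-aligned),
solvent system peaks, baseline drift beyond linear, A₂ effects,
chemical degradation, and methanolysis losses. Passing recovery tests
therefore demonstrates correctness of the computational chain under
controlled conditions, not robustness to every instrumental artifact.

With 0.3 mol% additive noise per linkage, a single domain total sums
5–8 independent noise draws (sd up to ~0.9 mol%), so per-draw recovery
to 0.5 mol% is not statistically meaningful; the round-trip check is
therefore a Monte-Carlo unbiasedness test — the mean recovered
composition over 20 fixed seeds must match the generating composition
within 0.5 mol% per domain.

## Numerical choices and problem sizes

* Calibration inversion: bisection, xtol 10⁻¹²; monotonicity checked on
  a 512-point grid.
* Zimm fits: `np.polyfit` order 1; a slope below 10⁻⁹ of the intercept
  is treated as a flat line (no Rg).
* Distribution grids: ~200–350 slices per run at 0.02 mL slice width.
* Recovery statistics use 20 seeds (SEC chain and linkage round trip)
  and 200 replicates for the single-slice noise study; property suites
  run 200–1000 randomized cases. These sizes give stable medians while
  keeping the default test run fast.
* Ties and degenerate inputs: empty distributions, all-zero domains and
  infeasible branching raise informative errors rather than returning
  NaN.

## Known limitations

* Universal calibration accuracy inherits the Mark–Houwink parameters;
  for branched pectins the effective (K, a) differ from linear-coil
  values, shifting absolute Vh (not the relative comparisons).
* Per-slice Zimm Mw is the mass-weighted mean within a slice; strong
  band broadening mixes species and inflates Mn (deflating D). Keep
  broadening small or correct upstream.
* The domain rules assume the diagnostic linkages of classical pectin
  and softwood hemicellulose domains; RG-II is not modelled (its
  signature linkages are absent from the supported schema), nor is the
  degree of methyl-esterification.
* The per-domain DP model ignores dispersity within a fraction and
  inter-molecular heterogeneity; it distributes residues, not chains.
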