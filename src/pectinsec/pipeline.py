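"""End-to-end run configuration and orchestration.

A YAML run configuration names the input files and analysis parameters;
``run_pipeline`` executes calibrate -> distribute -> Zimm -> moments ->
compose -> assign -> report, writing each stage's artifact to the output
directory.  Runs with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as pio
from .calibration import MarkHouwink, PULLULAN_MH, fit_calibration
from .composition import anhydro_average_mass
from .light_scattering import DEFAULT_ANGLES, OpticalConfig
from .linkage_domains import AssignmentRules, assign_domains, default_rules
from .model_report import ClassThresholds, build_model, render_report
from .sec import DEFAULT_DRI_RESPONSE, SECMALLSModel

log = logging.getLogger("pectinsec")

__all__ = ["FractionInputs", "RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class FractionInputs:
    fraction: str
    chromatogram: str
    composition: str | None = None
    linkage: str | None = None
    injected_mass: float | None = None


@dataclass
class RunConfig:
    standards: str
    fractions: list[FractionInputs]
    calibration_order: int = 3
    standards_mh: MarkHouwink = field(default_factory=lambda: PULLULAN_MH)
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    dri_response_factor: float = DEFAULT_DRI_RESPONSE
    dri_threshold: float = 0.01
    min_r_squared: float = 0.2
    rh_exclude: tuple[float, float] | None = None
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    mws_mode: str = "number"
    rules: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def _resolve(p):
            return None if p is None else str((base / p) if not Path(p).is_absolute() else Path(p))

        mh_raw = raw.get("standards_mark_houwink")
        mh = PULLULAN_MH if mh_raw is None else MarkHouwink(k=float(mh_raw["k"]), a=float(mh_raw["a"]))
        opt_raw = raw.get("optics", {})
        optics = OpticalConfig(
            wavelength_nm=float(opt_raw.get("wavelength_nm", 660.0)),
            solvent_refractive_index=float(opt_raw.get("solvent_refractive_index", 1.333)),
            dndc=float(opt_raw.get("dndc", 0.146)),
            angles=tuple(opt_raw.get("angles", DEFAULT_ANGLES)),
        )
        th_raw = raw.get("thresholds", {})
        fractions = [
            FractionInputs(
                fraction=str(f["id"]),
                chromatogram=_resolve(f["chromatogram"]),
                composition=_resolve(f.get("composition")),
                linkage=_resolve(f.get("linkage")),
                injected_mass=None if f.get("injected_mass") is None else float(f["injected_mass"]),
            )
            for f in raw.get("fractions", [])
        ]
        rh_ex = raw.get("rh_exclude")
        return cls(
            standards=_resolve(raw["standards"]),
            fractions=fractions,
            calibration_order=int(raw.get("calibration_order", 3)),
            standards_mh=mh,
            optics=optics,
            dri_response_factor=float(raw.get("dri_response_factor", DEFAULT_DRI_RESPONSE)),
            dri_threshold=float(th_raw.get("dri_retention", 0.01)),
            min_r_squared=float(th_raw.get("min_r_squared", 0.2)),
            rh_exclude=None if rh_ex is None else (float(rh_ex[0]), float(rh_ex[1])),
            thresholds=ClassThresholds(
                rgi_branched=float(th_raw.get("rgi_branched", 60.0)),
                hg_linear=float(th_raw.get("hg_linear", 25.0)),
            ),
            mws_mode=str(raw.get("mws_mode", "number")),
            rules=_resolve(raw.get("rules")),
            seed=int(raw.get("seed", 0)),
        )


def run_pipeline(config: RunConfig, out_dir, skip_domains: bool = False) -> str:
    """Run the full analysis; returns the rendered report text.

    Artifacts written to ``out_dir``: ``calibration.json``, per-fraction
    ``<id>_slices.csv``, and ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    standards = stage("calibrate", lambda: pio.read_standards(config.standards))
    curve = stage(
        "calibrate",
        lambda: fit_calibration(standards, config.standards_mh, config.calibration_order),
    )
    pio.write_calibration(curve, out / "calibration.json")
    log.info(
        "calibration: order %d, rms residual %.4g mL, angles %s",
        config.calibration_order, curve.rms_residual, list(config.optics.angles),
    )

    rules: AssignmentRules | None = None
    if not skip_domains:
        rules = stage(
            "assign",
            lambda: AssignmentRules.from_yaml(config.rules) if config.rules else default_rules(),
        )

    models = []
    for frac in config.fractions:
        chrom = stage(
            f"analyze-sec[{frac.fraction}]",
            lambda f=frac: pio.read_chromatogram(f.chromatogram, injected_mass=f.injected_mass),
        )
        results = stage(
            f"analyze-sec[{frac.fraction}]",
            lambda c=chrom: SECMALLSModel(
                c,
                curve,
                config.optics,
                dri_response_factor=config.dri_response_factor,
                dri_threshold=config.dri_threshold,
                min_r_squared=config.min_r_squared,
                rh_exclude=config.rh_exclude,
            ).fit(),
        )
        results.to_frame().to_csv(out / f"{frac.fraction}_slices.csv", index=False)

        if frac.composition is None:
            log.info("%s: no composition file; SEC-only summary", frac.fraction)
            continue
        comp = stage(f"compose[{frac.fraction}]", lambda f=frac: pio.read_composition(f.composition))
        mws = anhydro_average_mass(comp, mode=config.mws_mode)

        if skip_domains or frac.linkage is None:
            log.info("%s: domain assignment skipped", frac.fraction)
            continue
        table = stage(
            f"assign[{frac.fraction}]",
            lambda f=frac: pio.read_linkage_table(f.linkage, fraction=f.fraction),
        )
        domains = stage(f"assign[{frac.fraction}]", lambda t=table: assign_domains(t, rules))
        model = stage(
            f"report[{frac.fraction}]",
            lambda: build_model(
                frac.fraction,
                results.moments,
                mws,
                domains,
                linkage_table=table,
                conformation_slope=results.conformation_slope,
                thresholds=config.thresholds,
            ),
        )
        models.append(model)

    if models:
        report = stage("report", lambda: render_report(models))
        (out / "report.json").write_text(report + "\n")
        return report
    return ""
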