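"""Delimited-text readers and writers for all pipeline file formats.

All files are plain delimited text (comma by default, tab accepted) with
unit-bearing headers that the readers validate.  Write-then-read is the
identity on the in-memory objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, Standard
from .composition import MonosaccharideComposition
from .distributions import Chromatogram
from .linkage_domains import LINKAGES, LinkageTable

__all__ = [
    "read_standards",
    "write_standards",
    "read_chromatogram",
    "write_chromatogram",
    "read_composition",
    "write_composition",
    "read_linkage_table",
    "write_linkage_table",
    "read_calibration",
    "write_calibration",
]


class FileFormatError(ValueError):
    """Malformed input file; message carries the file and line number."""


def _read_delimited(path, required: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FileFormatError(f"{path}: cannot parse delimited text: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FileFormatError(
                f"{path}, line 1: missing required column(s) {missing}; found {list(df.columns)}"
            )
    return df


# -- standards -----------------------------------------------------------


def read_standards(path) -> list[Standard]:
    """Read `molar_mass_da,peak_elution_ml` standards."""
    df = _read_delimited(path, ["molar_mass_da", "peak_elution_ml"])
    out = []
    for i, row in df.iterrows():
        try:
            out.append(Standard(float(row["molar_mass_da"]), float(row["peak_elution_ml"])))
        except (ValueError, TypeError) as exc:
            raise FileFormatError(f"{path}, line {i + 2}: {exc}") from exc
    return out


def write_standards(standards: list[Standard], path) -> None:
    pd.DataFrame(
        {
            "molar_mass_da": [s.molar_mass for s in standards],
            "peak_elution_ml": [s.peak_elution_volume for s in standards],
        }
    ).to_csv(path, index=False)


# -- chromatograms -------------------------------------------------------


def read_chromatogram(path, injected_mass: float | None = None) -> Chromatogram:
    """Read `elution_ml,dri[,R_theta_<angle>...]` multi-detector traces."""
    df = _read_delimited(path, ["elution_ml", "dri"])
    angle_cols = [c for c in df.columns if c.startswith("R_theta_")]
    angles = None
    rayleigh = None
    if angle_cols:
        try:
            angles = np.array([float(c.removeprefix("R_theta_")) for c in angle_cols])
        except ValueError as exc:
            raise FileFormatError(f"{path}, line 1: bad angle column name: {exc}") from exc
        rayleigh = df[angle_cols].to_numpy(float)
    try:
        return Chromatogram(
            elution_volume=df["elution_ml"].to_numpy(float),
            dri=df["dri"].to_numpy(float),
            rayleigh=rayleigh,
            angles=angles,
            injected_mass=injected_mass,
        )
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_chromatogram(chrom: Chromatogram, path) -> None:
    data = {"elution_ml": chrom.elution_volume, "dri": chrom.dri}
    if chrom.rayleigh is not None:
        for j, ang in enumerate(chrom.angles):
            data[f"R_theta_{ang:g}"] = chrom.rayleigh[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


# -- compositions --------------------------------------------------------


def read_composition(path) -> MonosaccharideComposition:
    """Read `sugar,weight_percent` monosaccharide compositions."""
    df = _read_delimited(path, ["sugar", "weight_percent"])
    values: dict[str, float] = {}
    for i, row in df.iterrows():
        sugar = str(row["sugar"]).strip()
        try:
            pct = float(row["weight_percent"])
            if pct < 0:
                raise ValueError(f"negative weight percent {pct} for {sugar}")
        except (ValueError, TypeError) as exc:
            raise FileFormatError(f"{path}, line {i + 2}: {exc}") from exc
        values[sugar] = values.get(sugar, 0.0) + pct
    try:
        return MonosaccharideComposition(values)
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_composition(comp: MonosaccharideComposition, path) -> None:
    pd.DataFrame(
        {"sugar": list(comp.weight_percent), "weight_percent": list(comp.weight_percent.values())}
    ).to_csv(path, index=False)


# -- linkage tables ------------------------------------------------------


def read_linkage_table(path, fraction: str | None = None) -> LinkageTable:
    """Read a linkage table, long (`sugar,linkage,mol_percent`) or wide.

    Wide files have a `linkage` column plus one column per fraction;
    ``fraction`` selects the column (required when several are present).
    """
    df = _read_delimited(path)
    if {"linkage", "mol_percent"}.issubset(df.columns):
        values: dict[str, float] = {}
        for i, row in df.iterrows():
            link = str(row["linkage"]).strip()
            try:
                pct = float(row["mol_percent"])
                if pct < 0:
                    raise ValueError(f"negative mol% {pct} for {link}")
            except (ValueError, TypeError) as exc:
                raise FileFormatError(f"{path}, line {i + 2}: {exc}") from exc
            if pct > 0:
                values[link] = values.get(link, 0.0) + pct
        try:
            return LinkageTable(values, fraction=fraction)
        except ValueError as exc:
            raise FileFormatError(f"{path}: {exc}") from exc
    if "linkage" in df.columns:
        frac_cols = [c for c in df.columns if c not in ("linkage", "sugar")]
        if not frac_cols:
            raise FileFormatError(f"{path}, line 1: no fraction columns in wide table")
        if fraction is None:
            if len(frac_cols) > 1:
                raise FileFormatError(
                    f"{path}: several fraction columns {frac_cols}; specify one"
                )
            fraction = frac_cols[0]
        if fraction not in frac_cols:
            raise FileFormatError(f"{path}: fraction {fraction!r} not among {frac_cols}")
        values = {}
        for i, row in df.iterrows():
            link = str(row["linkage"]).strip()
            try:
                pct = float(row[fraction])
            except (ValueError, TypeError) as exc:
                raise FileFormatError(f"{path}, line {i + 2}: {exc}") from exc
            if pct < 0:
                raise FileFormatError(f"{path}, line {i + 2}: negative mol% {pct} for {link}")
            if pct > 0:
                values[link] = values.get(link, 0.0) + pct
        try:
            return LinkageTable(values, fraction=fraction)
        except ValueError as exc:
            raise FileFormatError(f"{path}: {exc}") from exc
    raise FileFormatError(
        f"{path}, line 1: expected columns `sugar,linkage,mol_percent` (long) or "
        "`linkage,<fraction>...` (wide)"
    )


def write_linkage_table(table: LinkageTable, path, layout: str = "long") -> None:
    if layout == "long":
        rows = [
            {"sugar": _sugar(l), "linkage": l, "mol_percent": v}
            for l, v in table.mol_percent.items()
        ]
        pd.DataFrame(rows, columns=["sugar", "linkage", "mol_percent"]).to_csv(path, index=False)
    elif layout == "wide":
        name = table.fraction or "mol_percent"
        pd.DataFrame({"linkage": list(table.mol_percent), name: list(table.mol_percent.values())}).to_csv(
            path, index=False
        )
    else:
        raise ValueError("layout must be 'long' or 'wide'")


def _sugar(linkage: str) -> str:
    from .linkage_domains import LINKAGE_SUGAR

    return LINKAGE_SUGAR[linkage]


# -- calibration curves --------------------------------------------------


def read_calibration(path) -> CalibrationCurve:
    with open(path) as fh:
        return CalibrationCurve.from_dict(json.load(fh))


def write_calibration(curve: CalibrationCurve, path) -> None:
    with open(path, "w") as fh:
        json.dump(curve.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
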