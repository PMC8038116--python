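"""Monosaccharide composition, anhydro residue mass and degree of polymerization.

A residue incorporated in a polysaccharide chain contributes its monomer
mass minus one water (18.02 Da).  The composition-weighted average
anhydro residue mass Mws converts a molar mass into a residue count:
DP = Mw / Mws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "SUGARS",
    "ANHYDRO_MASS",
    "MonosaccharideComposition",
    "anhydro_average_mass",
    "degree_of_polymerization",
    "round_dp",
]

SUGARS = ("Ara", "Rha", "Gal", "Glc", "Man", "Xyl", "GalA", "GlcA")

#: Average anhydro residue masses (Da): pentoses 132.12, hexoses 162.14,
#: deoxyhexoses 146.14, uronic acids 176.13.
ANHYDRO_MASS: dict[str, float] = {
    "Ara": 132.12,
    "Xyl": 132.12,
    "Gal": 162.14,
    "Glc": 162.14,
    "Man": 162.14,
    "Rha": 146.14,
    "GalA": 176.13,
    "GlcA": 176.13,
}


@dataclass
class MonosaccharideComposition:
    """Weight-percent monosaccharide composition of a fraction.

    Compositions whose total falls outside [99, 101] (printed-rounding
    tolerance) are renormalised to 100 with a warning.
    """

    weight_percent: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weight_percent:
            raise ValueError("composition is empty")
        unknown = set(self.weight_percent) - set(SUGARS)
        if unknown:
            raise ValueError(f"unknown sugars: {sorted(unknown)}; expected {SUGARS}")
        if any(v < 0 for v in self.weight_percent.values()):
            raise ValueError("weight percentages must be non-negative")
        total = sum(self.weight_percent.values())
        if total <= 0:
            raise ValueError("composition sums to zero")
        if not 99.0 <= total <= 101.0:
            warnings.warn(
                f"composition sums to {total:.2f}%; renormalising to 100%", stacklevel=2
            )
            self.weight_percent = {k: 100.0 * v / total for k, v in self.weight_percent.items()}

    @property
    def weight_fractions(self) -> dict[str, float]:
        total = sum(self.weight_percent.values())
        return {k: v / total for k, v in self.weight_percent.items() if v > 0}


def anhydro_average_mass(
    comp: MonosaccharideComposition,
    table: dict[str, float] | None = None,
    mode: str = "number",
) -> float:
    """Average anhydro residue mass Mws (Da) of a composition.

    mode="number" (default): harmonic mean over weight fractions,
    1 / sum(w_i / M_i) — the number-average residue mass, appropriate for
    converting molar mass to a residue count.  mode="weight": arithmetic
    mean sum(w_i * M_i).
    """
    masses = ANHYDRO_MASS if table is None else table
    if any(m <= 0 for m in masses.values()):
        raise ValueError("anhydro masses must be positive")
    fracs = comp.weight_fractions
    missing = set(fracs) - set(masses)
    if missing:
        raise ValueError(f"no anhydro mass for: {sorted(missing)}")
    if mode == "number":
        return 1.0 / sum(w / masses[s] for s, w in fracs.items())
    if mode == "weight":
        return sum(w * masses[s] for s, w in fracs.items())
    raise ValueError(f"mode must be 'number' or 'weight', got {mode!r}")


def round_dp(dp: float, rounding: str = "ten") -> float:
    """Round a degree of polymerization for reporting.

    "ten": nearest ten (half away from zero); "unit": nearest integer;
    "none": unrounded.
    """
    if rounding == "none":
        return dp
    if rounding == "unit":
        return float(int(dp + 0.5))
    if rounding == "ten":
        return 10.0 * int(dp / 10.0 + 0.5)
    raise ValueError(f"rounding must be 'ten', 'unit' or 'none', got {rounding!r}")


def degree_of_polymerization(mw: float, mws: float, rounding: str = "ten") -> tuple[float, float]:
    """Degree of polymerization DP = Mw / Mws.

    Returns ``(raw, reported)`` where ``reported`` is rounded per
    ``rounding`` (default nearest ten).  Homogeneous of degree zero:
    scaling Mw and Mws together leaves DP unchanged.
    """
    if mw <= 0 or mws <= 0:
        raise ValueError("Mw and Mws must be positive")
    dp = mw / mws
    return dp, round_dp(dp, rounding)
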