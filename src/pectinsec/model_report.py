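"""Per-fraction macromolecular model: integrating SEC-MALLS and linkage data.

``build_model`` combines the molar-mass moments, the average anhydro
residue mass and the domain composition of one fraction into a
``FractionModel``: total and per-domain degrees of polymerization,
branching indicators and a coarse architectural class.  The class labels
summarise common pectin architectures — a hairy, heavily substituted
RG-I macromolecule; a smooth HG-dominated chain; or a mixture with free
domains — and their thresholds are configurable heuristics, not claims.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .composition import round_dp
from .distributions import Moments
from .linkage_domains import DomainComposition, LinkageTable, domain_dp

__all__ = ["ClassThresholds", "FractionModel", "build_model", "render_report"]

#: Domains counted as RG-I plus its side chains.
RGI_WITH_SIDECHAINS = ("RG-I", "Arabinan", "AG-I", "AG-II")


@dataclass(frozen=True)
class ClassThresholds:
    """mol% thresholds for the architectural classification."""

    rgi_branched: float = 60.0  # RG-I + side chains at or above -> branched
    hg_linear: float = 25.0  # HG at or above -> HG-rich linear


@dataclass
class FractionModel:
    """Integrated macromolecular description of one pectin fraction."""

    fraction: str
    moments: Moments
    mws: float
    domains: DomainComposition
    dp_total: float
    dp_by_domain: pd.Series
    architecture: str
    conformation_slope: float | None = None
    ara_branch_ratio: float | None = None
    rgi_substitution: float | None = None

    def to_dict(self) -> dict:
        d = {
            "fraction": self.fraction,
            "mn": self.moments.mn,
            "mw": self.moments.mw,
            "dispersity": self.moments.dispersity,
            "mws": self.mws,
            "dp": self.dp_total,
            "dp_reported": round_dp(self.dp_total, "ten"),
            "domains": {
                name: {
                    "mol_percent": float(self.domains.totals[name]),
                    "dp": float(self.dp_by_domain[name]),
                }
                for name in self.domains.totals.index
            },
            "class": self.architecture,
        }
        if self.conformation_slope is not None:
            d["conformation_slope"] = self.conformation_slope
        if self.ara_branch_ratio is not None:
            d["ara_branch_ratio"] = self.ara_branch_ratio
        if self.rgi_substitution is not None:
            d["rgi_substitution"] = self.rgi_substitution
        return d


def classify(domains: DomainComposition, thresholds: ClassThresholds) -> str:
    frac = domains.mole_fractions * 100.0
    rgi = sum(float(frac.get(d, 0.0)) for d in RGI_WITH_SIDECHAINS)
    if rgi >= thresholds.rgi_branched:
        return "RG-I-rich branched"
    if float(frac.get("HG", 0.0)) >= thresholds.hg_linear:
        return "HG-rich linear"
    return "mixed/free-domain"


def build_model(
    fraction: str,
    moments: Moments,
    mws: float,
    domains: DomainComposition,
    linkage_table: LinkageTable | None = None,
    conformation_slope: float | None = None,
    thresholds: ClassThresholds | None = None,
) -> FractionModel:
    """Assemble the per-fraction macromolecular model.

    Per-domain DP distributes the total DP = Mw/Mws over domains by mole
    fraction (covalently linked, effectively monodisperse chain).  When a
    linkage table is supplied, two branching indicators are computed:
    the ratio of branch-point to terminal arabinose linkages, and the
    RG-I substitution (side-chain mol% per backbone Rha mol%).
    """
    if moments is None:
        raise ValueError("missing input: molar-mass moments (SEC-MALLS stage)")
    if mws is None or mws <= 0:
        raise ValueError("missing input: average anhydro residue mass (composition stage)")
    if domains is None:
        raise ValueError("missing input: domain composition (linkage stage)")
    if domains.grand_total <= 0:
        raise ValueError("domain composition is all zero; nothing to model")
    thresholds = thresholds or ClassThresholds()

    dp_total = moments.mw / mws
    dp_domains = domain_dp(domains, dp_total)

    ara_branch = None
    rgi_subst = None
    if linkage_table is not None:
        t_ara = linkage_table.get("t-Araf")
        branch_pts = (
            linkage_table.get("3,5-Araf")
            + linkage_table.get("2,5-Araf")
            + 2.0 * linkage_table.get("2,3,5-Araf")
        )
        ara_branch = branch_pts / t_ara if t_ara > 0 else 0.0
        rha = linkage_table.get("2-Rhap") + linkage_table.get("2,4-Rhap")
        side = sum(
            float(domains.totals.get(d, 0.0)) for d in ("Arabinan", "AG-I", "AG-II")
        )
        rgi_subst = side / rha if rha > 0 else 0.0

    return FractionModel(
        fraction=fraction,
        moments=moments,
        mws=mws,
        domains=domains,
        dp_total=dp_total,
        dp_by_domain=dp_domains,
        architecture=classify(domains, thresholds),
        conformation_slope=conformation_slope,
        ara_branch_ratio=ara_branch,
        rgi_substitution=rgi_subst,
    )


def render_report(models: list[FractionModel]) -> str:
    """Deterministic JSON report, fractions ordered by id.

    Identical inputs produce byte-identical output.
    """
    if not models:
        raise ValueError("need at least one fraction model")
    ordered = sorted(models, key=lambda m: m.fraction)
    payload = {"fractions": [m.to_dict() for m in ordered]}
    return json.dumps(payload, indent=2, sort_keys=True)
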