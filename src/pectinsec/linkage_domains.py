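"""Glycosidic-linkage tables and pectic-domain assignment.

Methylation (PMAA) analysis yields the mol% of each glycosidic linkage
type in a fraction.  Linkages are diagnostic for the cell-wall
polysaccharide domains they come from — e.g. 4-GalpA for
homogalacturonan (HG) and rhamnogalacturonan-I (RG-I) backbones,
2-/2,4-Rhap for the RG-I backbone, 3,4-GalpA plus terminal Xylp for
xylogalacturonan (XGA), 5-/3,5-Araf for arabinans — so a table of
linkages can be apportioned into a domain composition.

The assignment rules are data (a shipped YAML file), not code: the
direct linkage-to-domain map, the branch-point terminal demands and the
galacturonic-acid backbone split are all editable, since Pettolino-style
assignments vary by tissue.

GalA apportionment
------------------
4-GalpA is shared by three backbones.  The split used here:

* XGA claims 3,4-GalpA up to the available terminal Xylp (each xylose
  branch sits on a 3-substituted backbone residue);
* remaining 3,4-GalpA belongs to RG-I;
* the RG-I backbone alternates Rha and GalA, so RG-I claims 4-GalpA
  equal to its Rha units (2- plus 2,4-Rhap) minus the 3,4-GalpA it
  already holds;
* the rest of 4-GalpA, plus terminal GalpA, is HG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LINKAGES",
    "LINKAGE_SUGAR",
    "DOMAINS",
    "LinkageTable",
    "AssignmentRules",
    "DomainComposition",
    "GalaSplit",
    "sugar_totals",
    "apportion_gala",
    "assign_domains",
    "domain_dp",
    "default_rules",
]

#: Canonical linkage schema: short name -> parent sugar.
LINKAGE_SUGAR: dict[str, str] = {
    "t-Araf": "Ara", "t-Arap": "Ara", "2-Araf": "Ara", "3-Araf": "Ara",
    "5-Araf": "Ara", "3,5-Araf": "Ara", "2,5-Araf": "Ara", "2,3,5-Araf": "Ara",
    "t-Galp": "Gal", "3-Galp": "Gal", "4-Galp": "Gal", "6-Galp": "Gal",
    "4,6-Galp": "Gal", "3,4-Galp": "Gal", "3,6-Galp": "Gal",
    "t-GalpA": "GalA", "4-GalpA": "GalA", "3,4-GalpA": "GalA",
    "t-Rhap": "Rha", "2-Rhap": "Rha", "2,4-Rhap": "Rha",
    "t-Glcp": "Glc", "4-Glcp": "Glc", "4,6-Glcp": "Glc",
    "t-Xylp": "Xyl", "4-Xylp": "Xyl",
    "4-Manp": "Man", "4,6-Manp": "Man",
    "t-GlcpA": "GlcA", "4-GlcpA": "GlcA",
}
LINKAGES = tuple(LINKAGE_SUGAR)

DOMAINS = ("Arabinan", "AG-I", "AG-II", "RG-I", "HG", "XGA", "HX", "HM", "Others")


@dataclass
class LinkageTable:
    """mol% per glycosidic linkage for one fraction.

    Values must be non-negative and belong to the canonical linkage
    schema.  A populated table whose grand total falls outside
    [95, 105] mol% (printed-rounding tolerance) raises; partial tables
    built programmatically may carry any subset of linkages.
    """

    mol_percent: dict[str, float]
    fraction: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.mol_percent) - set(LINKAGES)
        if unknown:
            raise ValueError(f"unknown linkages: {sorted(unknown)}")
        if any(v < 0 for v in self.mol_percent.values()):
            bad = {k: v for k, v in self.mol_percent.items() if v < 0}
            raise ValueError(f"negative mol% entries: {bad}")

    def validate_total(self, lo: float = 95.0, hi: float = 105.0) -> None:
        t = self.total
        if not lo <= t <= hi:
            raise ValueError(f"linkage grand total {t:.2f} mol% outside [{lo}, {hi}]")

    def get(self, linkage: str) -> float:
        return float(self.mol_percent.get(linkage, 0.0))

    @property
    def total(self) -> float:
        return float(sum(self.mol_percent.values()))

    def to_series(self) -> pd.Series:
        s = pd.Series({k: self.mol_percent.get(k, 0.0) for k in LINKAGES}, dtype=float)
        s.name = self.fraction
        return s


def sugar_totals(table: LinkageTable) -> pd.Series:
    """Sum of linkage mol% per parent sugar (the parenthesised table rows)."""
    totals: dict[str, float] = {}
    for link, value in table.mol_percent.items():
        sugar = LINKAGE_SUGAR[link]
        totals[sugar] = totals.get(sugar, 0.0) + value
    return pd.Series(totals, dtype=float).sort_index()


@dataclass(frozen=True)
class GalaSplit:
    """Apportionment of backbone GalA among XGA, RG-I and HG (mol%)."""

    xga_34: float
    rgi_34: float
    rgi_4: float
    hg_4: float
    warnings: tuple = ()


def apportion_gala(table: LinkageTable) -> GalaSplit:
    """Split 4-GalpA and 3,4-GalpA among the XGA, RG-I and HG backbones."""
    g4 = table.get("4-GalpA")
    g34 = table.get("3,4-GalpA")
    t_xyl = table.get("t-Xylp")
    rha = table.get("2-Rhap") + table.get("2,4-Rhap")

    notes: list[str] = []
    xga_34 = min(t_xyl, g34)
    rgi_34 = g34 - xga_34
    demand = max(0.0, rha - rgi_34)
    if demand > g4:
        notes.append(
            f"RG-I backbone demand {demand:.2f} mol% exceeds available 4-GalpA "
            f"{g4:.2f} mol%; clamping"
        )
        warnings.warn(notes[-1], stacklevel=2)
        demand = g4
    rgi_4 = demand
    hg_4 = g4 - rgi_4
    return GalaSplit(xga_34=xga_34, rgi_34=rgi_34, rgi_4=rgi_4, hg_4=hg_4, warnings=tuple(notes))


@dataclass
class AssignmentRules:
    """Ordered linkage-to-domain assignment rules.

    ``direct`` maps each domain to the linkages it claims outright;
    ``terminal_demands`` is an ordered list of branch-point demands, each
    drawing terminal residues from ``sources`` in priority order;
    ``terminal_remainders`` routes leftover terminals to a domain; any
    unclaimed residue goes to ``fallback``.
    """

    direct: dict[str, list[str]]
    terminal_demands: list[dict]
    terminal_remainders: dict[str, str] = field(default_factory=dict)
    fallback: str = "Others"
    gala_split: bool = True

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for domain, links in self.direct.items():
            for link in links:
                if link not in LINKAGE_SUGAR:
                    raise ValueError(f"rule for {domain} names unknown linkage {link!r}")
                if link in seen:
                    raise ValueError(
                        f"linkage {link!r} claimed directly by both {seen[link]} and {domain}"
                    )
                seen[link] = domain
        for rule in self.terminal_demands:
            for key in ("domain", "demand", "sources"):
                if key not in rule:
                    raise ValueError(f"terminal demand rule missing {key!r}: {rule}")

    @classmethod
    def from_yaml(cls, path) -> "AssignmentRules":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            direct=raw["direct"],
            terminal_demands=raw.get("terminal_demands", []),
            terminal_remainders=raw.get("terminal_remainders", {}),
            fallback=raw.get("fallback", "Others"),
            gala_split=raw.get("gala_split", True),
        )


def default_rules() -> AssignmentRules:
    """The shipped rule set for spruce-bark pectic fractions."""
    ref = resources.files("pectinsec.data") / "default_rules.yaml"
    with resources.as_file(ref) as path:
        return AssignmentRules.from_yaml(path)


@dataclass
class DomainComposition:
    """Itemised domain assignment: mol% per (domain, linkage)."""

    itemized: dict[str, dict[str, float]]
    fraction: str | None = None
    warnings: tuple = ()

    @property
    def totals(self) -> pd.Series:
        out = {d: float(sum(self.itemized.get(d, {}).values())) for d in DOMAINS}
        for d in self.itemized:
            if d not in out:
                out[d] = float(sum(self.itemized[d].values()))
        s = pd.Series(out, dtype=float)
        s.name = self.fraction
        return s

    @property
    def grand_total(self) -> float:
        return float(self.totals.sum())

    @property
    def mole_fractions(self) -> pd.Series:
        t = self.totals
        return t / t.sum()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"domain": d, "linkage": l, "mol_percent": v}
            for d in self.itemized
            for l, v in sorted(self.itemized[d].items())
            if v != 0.0
        ]
        return pd.DataFrame(rows, columns=["domain", "linkage", "mol_percent"])


def assign_domains(table: LinkageTable, rules: AssignmentRules | None = None) -> DomainComposition:
    """Apportion a linkage table into a pectic/hemicellulosic domain composition.

    Every input mol% is allocated exactly once: the GalA backbone split
    first, then direct assignments, then branch-point terminal demands in
    rule order, then terminal remainders; whatever is left flows to the
    fallback domain.  The grand total is conserved to numerical precision.
    """
    if rules is None:
        rules = default_rules()
    remaining = {k: float(v) for k, v in table.mol_percent.items()}
    itemized: dict[str, dict[str, float]] = {d: {} for d in DOMAINS}
    notes: list[str] = []

    def put(domain: str, linkage: str, amount: float) -> None:
        if amount <= 0:
            return
        bucket = itemized.setdefault(domain, {})
        bucket[linkage] = bucket.get(linkage, 0.0) + amount

    if rules.gala_split:
        split = apportion_gala(table)
        notes.extend(split.warnings)
        put("XGA", "3,4-GalpA", split.xga_34)
        put("XGA", "t-Xylp", split.xga_34)
        put("RG-I", "3,4-GalpA", split.rgi_34)
        put("RG-I", "4-GalpA", split.rgi_4)
        put("HG", "4-GalpA", split.hg_4)
        for link, used in (("3,4-GalpA", split.xga_34 + split.rgi_34),
                           ("4-GalpA", split.rgi_4 + split.hg_4),
                           ("t-Xylp", split.xga_34)):
            if link in remaining:
                remaining[link] = max(0.0, remaining[link] - used)

    for domain, links in rules.direct.items():
        for link in links:
            amount = remaining.pop(link, 0.0)
            put(domain, link, amount)

    for rule in rules.terminal_demands:
        demand = sum(table.get(link) for link in rule["demand"])
        for source in rule["sources"]:
            if demand <= 0:
                break
            take = min(demand, remaining.get(source, 0.0))
            if take > 0:
                put(rule["domain"], source, take)
                remaining[source] -= take
                demand -= take
        if demand > 1e-9:
            notes.append(
                f"{rule['domain']} branch-point demand short by {demand:.2f} mol% "
                f"(sources {rule['sources']} exhausted)"
            )

    for link, domain in rules.terminal_remainders.items():
        amount = remaining.pop(link, 0.0)
        put(domain, link, amount)

    for link, amount in remaining.items():
        put(rules.fallback, link, amount)

    dc = DomainComposition(itemized=itemized, fraction=table.fraction, warnings=tuple(notes))
    if abs(dc.grand_total - table.total) > 1e-9 * max(1.0, table.total):
        raise AssertionError(
            f"assignment lost mass: {dc.grand_total} vs input {table.total}"
        )
    return dc


def domain_dp(domains: DomainComposition, total_dp: float) -> pd.Series:
    """Per-domain degree of polymerization, DP_domain = mole fraction x DP.

    Assumes the domains of a fraction are covalently linked in a single,
    effectively monodisperse chain, so residues distribute across domains
    in proportion to their mole fractions.
    """
    if total_dp <= 0:
        raise ValueError("total DP must be positive")
    return domains.mole_fractions * total_dp
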