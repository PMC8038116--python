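"""Bundled reference datasets.

Published characterization values for pectic fractions isolated from
Norway spruce (*Picea abies*) inner bark by pressurized hot-water
extraction and preparative SEC: the parent extract P0 and size fractions
P2-P6.  They serve as worked-example inputs and as fixed points for the
domain-assignment rules.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .linkage_domains import LinkageTable

__all__ = ["load_spruce_bark_linkages", "spruce_bark_linkage_table", "load_spruce_bark_molar_mass"]


def _data_path(name: str):
    return resources.files("pectinsec.data") / name


def load_spruce_bark_linkages() -> pd.DataFrame:
    """Wide glycosidic-linkage table (mol%) for fractions P0, P3, P4, P5."""
    with resources.as_file(_data_path("spruce_bark_linkages.csv")) as p:
        return pd.read_csv(p, index_col="linkage")


def spruce_bark_linkage_table(fraction: str) -> LinkageTable:
    """One fraction's linkage table as a :class:`LinkageTable`."""
    df = load_spruce_bark_linkages()
    if fraction not in df.columns:
        raise KeyError(f"fraction {fraction!r} not in {list(df.columns)}")
    values = {k: float(v) for k, v in df[fraction].items() if v > 0}
    return LinkageTable(mol_percent=values, fraction=fraction)


def load_spruce_bark_molar_mass() -> pd.DataFrame:
    """Mn, Mw, average anhydro residue mass and yield per fraction."""
    with resources.as_file(_data_path("spruce_bark_molar_mass.csv")) as p:
        return pd.read_csv(p, index_col="fraction")
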