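"""Packaged reference tables from the published *P. hysterophorus* analysis.

The original study's inputs (GBIF occurrences, WorldClim/CMIP6 rasters)
are far beyond desk scale, so its printed result tables are shipped
verbatim as CSV data: the selected bioclimatic variables with their
averaged model contributions, the evaluation scores before/after spatial
rarefaction, the continental habitat-area changes, and the suitable-area
accounting for the 17 South Korean administrative divisions under the
current climate and the SSP2-4.5 / SSP5-8.5 scenario periods.  They serve
as arithmetic ground truth for the accounting machinery, not as model
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["ReferenceTables", "reference_tables"]


@dataclass(frozen=True)
class ReferenceTables:
    """The four published tables as DataFrames, values verbatim."""

    variable_contributions: pd.DataFrame  # code, description, unit, contribution %
    evaluation_scores: pd.DataFrame       # AUC/TSS/kappa before & after rarefying
    continent_area_change: pd.DataFrame   # current km2 + % change per scenario/period
    korea_ad_areas: pd.DataFrame          # 17 ADs x (total, current, 8 future areas)

    #: scenario/period column labels shared by the area tables
    SCENARIO_COLUMNS = (
        "ssp245_2021_2040", "ssp245_2041_2060", "ssp245_2061_2080", "ssp245_2081_2100",
        "ssp585_2021_2040", "ssp585_2041_2060", "ssp585_2061_2080", "ssp585_2081_2100",
    )


def _load(name: str) -> pd.DataFrame:
    with resources.files("maxniche.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def reference_tables() -> ReferenceTables:
    """Load the packaged reference tables."""
    return ReferenceTables(
        variable_contributions=_load("variable_contributions.csv"),
        evaluation_scores=_load("evaluation_scores.csv"),
        continent_area_change=_load("continent_area_change.csv"),
        korea_ad_areas=_load("korea_ad_areas.csv"),
    )
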