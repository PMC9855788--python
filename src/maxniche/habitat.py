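"""Binary habitat maps, area accounting, and zonal suitability summaries.

A suitability grid is binarised at the MTSS threshold into suitable /
unsuitable habitat; suitable cells are converted to area at a fixed
4.5 km² per cell (the 2.5-arcmin convention at the equator).  Zones — an
integer-labelled raster plus a lookup table — stand in for continents,
nations, or administrative divisions; per zone the suitable area, percent
change against the current climate, mean suitability, and a four-level
suitability category are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid

__all__ = [
    "BinaryMap",
    "ZoneSet",
    "NEW_COLONIZATION",
    "binarize",
    "suitable_area",
    "percent_change",
    "zonal_mean_suitability",
    "classify_suitability",
    "change_summary",
]

CELL_AREA_KM2 = 4.5

#: Sentinel for a zone gaining habitat where the current area is zero; a
#: percent change against zero is undefined.
NEW_COLONIZATION = "new_colonization"


@dataclass
class BinaryMap:
    """Suitable/unsuitable map with the threshold and scenario that made it."""

    values: Grid  # 1 suitable, 0 unsuitable, nodata preserved
    threshold_used: float
    scenario_tag: str = "current"

    @property
    def suitable(self) -> np.ndarray:
        return self.values.mask & (self.values.values > 0)

    @property
    def n_suitable(self) -> int:
        return int(self.suitable.sum())


@dataclass
class ZoneSet:
    """Integer zone raster (0 = outside every zone) plus a zone table."""

    zone_raster: Grid
    table: dict[int, tuple[str, float]] = field(default_factory=dict)  # id -> (name, km2)

    def __post_init__(self) -> None:
        labels = self.labels
        missing = [z for z in labels if z not in self.table]
        if missing:
            raise ValueError(f"zone raster label(s) {missing} absent from zone table")

    @property
    def labels(self) -> list[int]:
        vals = self.zone_raster.values[self.zone_raster.mask]
        return sorted(int(z) for z in np.unique(vals) if z != 0)

    def name(self, zone_id: int) -> str:
        return self.table[zone_id][0]

    def zone_mask(self, zone_id: int) -> np.ndarray:
        return self.zone_raster.mask & (self.zone_raster.values == zone_id)

    def to_csv(self, path: str) -> None:
        rows = [(z, n, a) for z, (n, a) in sorted(self.table.items())]
        pd.DataFrame(rows, columns=["id", "name", "total_area_km2"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, zone_raster: Grid, path: str) -> "ZoneSet":
        df = pd.read_csv(path)
        table = {int(r.id): (str(r.name), float(r.total_area_km2)) for r in df.itertuples()}
        return cls(zone_raster, table)


def binarize(suitability: Grid, t: float, scenario_tag: str = "current") -> BinaryMap:
    """Suitable where suitability >= t; nodata cells stay invalid."""
    if not 0.0 <= t <= 1.0 + 1e-12:
        raise ValueError("threshold must lie in [0, 1]")
    mask = suitability.mask
    vals = np.where(mask, (suitability.values >= t).astype(float), np.nan)
    out = Grid(vals, suitability.transform, nodata=np.nan, crs_tag=suitability.crs_tag)
    return BinaryMap(out, threshold_used=float(t), scenario_tag=scenario_tag)


def suitable_area(
    b: BinaryMap,
    cell_area_km2: float = CELL_AREA_KM2,
    zones: ZoneSet | None = None,
) -> float | dict[int, float]:
    """Suitable-cell count × cell area, in km², total or per zone."""
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    suit = b.suitable
    if zones is None:
        return float(suit.sum()) * cell_area_km2
    out: dict[int, float] = {}
    for z in zones.labels:
        out[z] = float((suit & zones.zone_mask(z)).sum()) * cell_area_km2
    return out


def percent_change(area_future: float, area_current: float):
    """100 × (future − current)/current; the new-colonization sentinel when
    the current area is zero and the future is not."""
    if area_current < 0 or area_future < 0:
        raise ValueError("areas must be non-negative")
    if area_current == 0:
        return 0.0 if area_future == 0 else NEW_COLONIZATION
    return 100.0 * (area_future - area_current) / area_current


def zonal_mean_suitability(suitability: Grid, zones: ZoneSet) -> dict[int, float]:
    """Arithmetic mean of suitability over all valid cells of each zone.

    Zones with no valid suitability cell get NaN (flagged undefined).
    """
    if not suitability.aligned_with(zones.zone_raster):
        raise ValueError("zone raster is not aligned with the suitability grid")
    valid = suitability.mask
    out: dict[int, float] = {}
    for z in zones.labels:
        m = zones.zone_mask(z) & valid
        out[z] = float(suitability.values[m].mean()) if m.any() else float("nan")
    return out


def classify_suitability(mean: float) -> str:
    """Four-level category of a zone-mean suitability in [0, 1].

    Boundaries are continuous half-open intervals at 0.25/0.50/0.75:
    low <= 0.25 < moderate <= 0.50 < high <= 0.75 < very_high.
    """
    if np.isnan(mean):
        return "undefined"
    if not 0.0 <= mean <= 1.0:
        raise ValueError("mean suitability must lie in [0, 1]")
    if mean <= 0.25:
        return "low"
    if mean <= 0.50:
        return "moderate"
    if mean <= 0.75:
        return "high"
    return "very_high"


GRAND_TOTAL = 0  # pseudo zone id for the all-zones row


def change_summary(
    suitability_by_scenario: dict[str, Grid],
    threshold: float,
    zones: ZoneSet,
    cell_area_km2: float = CELL_AREA_KM2,
    current_tag: str = "current",
) -> pd.DataFrame:
    """Zone × scenario accounting table (areas, change, mean, category).

    One row per zone and scenario plus a grand-total row per scenario
    (zone id 0, name "TOTAL").  Percent change is against the
    ``current_tag`` scenario of the same zone.
    """
    if current_tag not in suitability_by_scenario:
        raise ValueError(f"scenario {current_tag!r} required as the baseline")
    areas: dict[str, dict[int, float]] = {}
    means: dict[str, dict[int, float]] = {}
    totals: dict[str, float] = {}
    total_means: dict[str, float] = {}
    for tag, grid in suitability_by_scenario.items():
        bmap = binarize(grid, threshold, scenario_tag=tag)
        areas[tag] = suitable_area(bmap, cell_area_km2, zones)
        means[tag] = zonal_mean_suitability(grid, zones)
        totals[tag] = suitable_area(bmap, cell_area_km2)
        total_means[tag] = float(np.nanmean(np.where(grid.mask, grid.values, np.nan)))
    rows = []
    tags = list(suitability_by_scenario)
    for z in zones.labels:
        for tag in tags:
            rows.append(
                {
                    "zone_id": z,
                    "zone": zones.name(z),
                    "total_area_km2": zones.table[z][1],
                    "scenario_tag": tag,
                    "suitable_area_km2": areas[tag][z],
                    "percent_change_vs_current": percent_change(
                        areas[tag][z], areas[current_tag][z]
                    ),
                    "mean_suitability": means[tag][z],
                    "category": classify_suitability(means[tag][z]),
                }
            )
    for tag in tags:
        rows.append(
            {
                "zone_id": GRAND_TOTAL,
                "zone": "TOTAL",
                "total_area_km2": sum(a for _, a in zones.table.values()),
                "scenario_tag": tag,
                "suitable_area_km2": totals[tag],
                "percent_change_vs_current": percent_change(totals[tag], totals[current_tag]),
                "mean_suitability": total_means[tag],
                "category": classify_suitability(total_means[tag]),
            }
        )
    return pd.DataFrame(rows)
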