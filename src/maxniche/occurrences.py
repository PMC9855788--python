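"""Presence records: loading, spatial rarefaction, splitting, background.

Occurrence records arrive as CSV rows of (species, lon, lat).  Before
modelling they are spatially rarefied to at most one record per grid cell,
which curbs sampling bias and spatial autocorrelation in densely collected
regions.  Calibration/validation splits and uniform background samples are
drawn with explicit seeds so every pipeline stage is reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .grid import Grid

__all__ = [
    "OccurrenceSet",
    "CellSample",
    "LoadReport",
    "load_occurrences",
    "rarefy",
    "partition",
    "sample_background",
]


@dataclass
class OccurrenceSet:
    """Presence records in WGS84 decimal degrees."""

    records: list[tuple[float, float, str]]  # (lon, lat, source_id)
    species: str = ""

    def __post_init__(self) -> None:
        for lon, lat, _ in self.records:
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                raise ValueError(f"coordinate out of range: ({lon}, {lat})")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lonlat(self) -> np.ndarray:
        """Array (n, 2) of (lon, lat)."""
        if not self.records:
            return np.empty((0, 2))
        return np.array([(lon, lat) for lon, lat, _ in self.records])

    def cells_on(self, grid: Grid) -> list[tuple[int, int] | None]:
        """Containing cell per record (None when outside the grid)."""
        return [grid.cell_of(lon, lat) for lon, lat, _ in self.records]

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["species", "lon", "lat", "source_id"])
            for lon, lat, sid in self.records:
                w.writerow([self.species, repr(lon), repr(lat), sid])


@dataclass
class CellSample:
    """Distinct valid grid cells with the stack values observed there."""

    cells: np.ndarray  # (n, 2) int array of (row, col)
    feature_values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int).reshape(-1, 2)
        seen = {tuple(c) for c in self.cells}
        if len(seen) != len(self.cells):
            raise ValueError("cell sample contains duplicate cells")

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class LoadReport:
    """Counts from parsing an occurrence CSV."""

    n_read: int = 0
    n_kept: int = 0
    n_malformed: int = 0
    n_out_of_range: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def load_occurrences(path: str, species: str | None = None) -> tuple[OccurrenceSet, LoadReport]:
    """Load presence records from a CSV with columns species, lon, lat.

    Extra columns are ignored; rows with unparseable or out-of-range
    coordinates are dropped and counted in the returned :class:`LoadReport`.
    """
    report = LoadReport()
    records: list[tuple[float, float, str]] = []
    sp = species or ""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = {c.lower().strip(): c for c in (reader.fieldnames or [])}
        for required in ("species", "lon", "lat"):
            if required not in cols:
                raise ValueError(
                    f"occurrence CSV {path} lacks required column {required!r} "
                    f"(found {reader.fieldnames})"
                )
        for i, row in enumerate(reader):
            report.n_read += 1
            try:
                lon = float(row[cols["lon"]])
                lat = float(row[cols["lat"]])
            except (TypeError, ValueError):
                report.n_malformed += 1
                continue
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                report.n_out_of_range += 1
                continue
            if not sp:
                sp = row[cols["species"]]
            sid = row.get(cols.get("source_id", ""), "") or f"row{i}"
            records.append((lon, lat, sid))
    report.n_kept = len(records)
    return OccurrenceSet(records, species=sp), report


def rarefy(occ: OccurrenceSet, grid: Grid) -> OccurrenceSet:
    """Keep at most one record per grid cell (the first in input order).

    Records falling outside the grid or on nodata cells are dropped.  The
    operation is idempotent: rarefying an already-rarefied set is a no-op.
    """
    mask = grid.mask
    seen: set[tuple[int, int]] = set()
    kept: list[tuple[float, float, str]] = []
    for lon, lat, sid in occ.records:
        cell = grid.cell_of(lon, lat)
        if cell is None or not mask[cell]:
            continue
        if cell in seen:
            continue
        seen.add(cell)
        kept.append((lon, lat, sid))
    return OccurrenceSet(kept, species=occ.species)


def partition(
    occ: OccurrenceSet, train_frac: float = 0.75, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint calibration/validation split of the records.

    ``len(train) = round(train_frac * n)``; the union of the two parts is
    the input and the split is reproducible for a fixed seed.
    """
    n = len(occ)
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = np.sort(order[:n_train])
    test_idx = np.sort(order[n_train:])
    train = OccurrenceSet([occ.records[i] for i in train_idx], species=occ.species)
    test = OccurrenceSet([occ.records[i] for i in test_idx], species=occ.species)
    return train, test


def sample_background(
    mask: Grid,
    n: int = 10_000,
    seed: int = 0,
    exclude: set[tuple[int, int]] | None = None,
) -> CellSample:
    """Sample ``min(n, available)`` distinct valid cells uniformly.

    ``mask`` is a validity grid (nonzero = valid); cells in ``exclude`` are
    never drawn.  Raises if no valid cells remain.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    valid = np.argwhere(mask.mask & (mask.values != 0))
    if exclude:
        keep = [i for i, rc in enumerate(map(tuple, valid)) if rc not in exclude]
        valid = valid[keep]
    if len(valid) == 0:
        raise ValueError("no valid cells available for background sampling")
    rng = np.random.default_rng(seed)
    k = min(n, len(valid))
    idx = rng.choice(len(valid), size=k, replace=False)
    return CellSample(valid[np.sort(idx)])
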