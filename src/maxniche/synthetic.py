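"""Virtual-species generator: every pipeline stage testable without downloads.

The generator emulates the study conditions of a presence-only SDM run:

* mutually correlated, spatially smooth "climate" layers (Gaussian random
  fields mixed to a target correlation matrix), exercising the |r| < 0.75
  collinearity pruning;
* a true Gibbs-form suitability surface over a known subset of layers, so
  recovery can be scored against ground truth;
* presence samples drawn proportionally to the true raw density, with a
  controllable fraction of within-cell duplicates to exercise spatial
  rarefaction;
* "future scenario" stacks obtained by affine perturbation of layers;
* an integer zone raster (seeded Voronoi partition) standing in for
  continents or administrative divisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import Grid, GridStack, stack_layers, valid_mask
from .habitat import CELL_AREA_KM2, ZoneSet
from .occurrences import OccurrenceSet

__all__ = [
    "VirtualNiche",
    "simulate_bioclim_stack",
    "make_virtual_niche",
    "sample_presences",
    "perturb_scenario",
    "make_zones",
]

ARCMIN_2_5 = 2.5 / 60.0  # the 2.5-arcmin cell size in degrees


@dataclass
class VirtualNiche:
    """Known Gibbs niche over a layer stack.

    true_lambda are the weights on min-max-scaled layers; true_raw is the
    normalised Gibbs density over valid cells (a Grid summing to 1) and
    true_suitability its cloglog transform.
    """

    true_lambda: dict[str, float]
    true_raw: Grid
    true_suitability: Grid
    stack: GridStack
    entropy: float
    generator_config: dict = field(default_factory=dict)


def simulate_bioclim_stack(
    shape: tuple[int, int],
    n_layers: int = 6,
    corr_target: np.ndarray | None = None,
    smoothing: float = 5.0,
    seed: int = 0,
    codes: list[str] | None = None,
    origin: tuple[float, float] = (0.0, 45.0),
    cell_size: float = ARCMIN_2_5,
) -> GridStack:
    """Smooth correlated climate-like layers on a regular grid.

    Independent white-noise fields are smoothed with a Gaussian kernel of
    lengthscale ``smoothing`` cells, standardised, and mixed with a
    factor of ``corr_target`` (identity when omitted) so the empirical
    inter-layer correlation over cells approaches the target.  Layers are
    then shifted/scaled onto loosely climate-like ranges; the affine map
    leaves correlations untouched.  Deterministic per seed.
    """
    nrows, ncols = shape
    if corr_target is None:
        corr_target = np.eye(n_layers)
    corr_target = np.asarray(corr_target, dtype=float)
    if corr_target.shape != (n_layers, n_layers):
        raise ValueError(f"corr_target must be {n_layers}x{n_layers}")
    if not np.allclose(corr_target, corr_target.T, atol=1e-10):
        raise ValueError("corr_target must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(corr_target)
    if eigvals.min() < -1e-8:
        raise ValueError(
            f"corr_target is not positive semi-definite (min eigenvalue {eigvals.min():.3g})"
        )
    mixer = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))

    rng = np.random.default_rng(seed)
    fields = np.empty((n_layers, nrows, ncols))
    for i in range(n_layers):
        f = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=smoothing,
                            mode="reflect")
        fields[i] = (f - f.mean()) / f.std()
    mixed = np.einsum("ij,jrc->irc", mixer, fields)

    codes = codes or [f"Bio{i + 1}" for i in range(n_layers)]
    west, north = origin
    transform = (west, north, cell_size)
    grids = []
    for i, code in enumerate(codes):
        # temperature-like for the first half, precipitation-like after
        if i < (n_layers + 1) // 2:
            vals = 15.0 + 8.0 * mixed[i]
        else:
            vals = 1200.0 + 400.0 * mixed[i]
        grids.append((code, Grid(vals, transform)))
    return stack_layers(grids)


def make_virtual_niche(
    stack: GridStack, true_lambda: dict[str, float], generator_config: dict | None = None
) -> VirtualNiche:
    """Gibbs niche with known weights over min-max-scaled layers.

    raw ∝ exp(Σ λ_v · scaled layer v) over valid cells, normalised to sum
    to one; suitability is the cloglog transform with entropy computed
    over all valid cells.  All-zero weights give the uniform suitability
    1 − 1/e everywhere.
    """
    missing = [c for c in true_lambda if c not in stack]
    if missing:
        raise ValueError(f"niche variables not in stack: {missing}")
    mgrid = valid_mask(stack)
    valid = mgrid.values > 0
    eta = np.zeros(stack.shape)
    for code, lam in true_lambda.items():
        v = stack[code].values
        vv = v[valid]
        lo, hi = vv.min(), vv.max()
        scaled = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        eta += lam * scaled
    eta_valid = eta[valid]
    w = np.exp(eta_valid - eta_valid.max())
    q = w / w.sum()
    H = float(-np.sum(q * np.log(q)))
    raw = np.full(stack.shape, np.nan)
    raw[valid] = q
    suit = np.full(stack.shape, np.nan)
    suit[valid] = 1.0 - np.exp(-np.exp(H) * q)
    ref = next(iter(stack.layers.values()))
    return VirtualNiche(
        true_lambda=dict(true_lambda),
        true_raw=Grid(raw, ref.transform, nodata=np.nan),
        true_suitability=Grid(suit, ref.transform, nodata=np.nan),
        stack=stack,
        entropy=H,
        generator_config=dict(generator_config or {}),
    )


def sample_presences(
    niche: VirtualNiche,
    n: int = 500,
    dup_rate: float = 0.0,
    seed: int = 0,
    species: str = "virtual species",
) -> OccurrenceSet:
    """Presence records drawn proportionally to the true raw density.

    ``round(dup_rate * n)`` of the records are duplicates placed into
    cells already sampled (what spatial rarefaction later removes); the
    remaining records occupy distinct cells drawn without replacement
    with probability proportional to raw.  Each record is a uniform point
    inside its cell.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= dup_rate < 1.0:
        raise ValueError("dup_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    grid = niche.true_raw
    valid_cells = np.argwhere(grid.mask)
    p = grid.values[grid.mask]
    p = p / p.sum()
    n_dup = int(round(dup_rate * n))
    n_primary = n - n_dup
    n_available = int((p > 0).sum())
    if n_primary > n_available:
        raise ValueError(
            f"cannot place {n_primary} distinct presences on {n_available} cells "
            "with positive density"
        )
    primary_idx = rng.choice(len(valid_cells), size=n_primary, replace=False, p=p)
    dup_idx = rng.choice(primary_idx, size=n_dup, replace=True) if n_dup else np.empty(0, int)
    west, north, cs = grid.transform
    records = []
    for k, ci in enumerate(np.r_[primary_idx, dup_idx].astype(int)):
        r, c = valid_cells[ci]
        lon = west + (c + rng.uniform(0.0, 1.0)) * cs
        lat = north - (r + rng.uniform(0.0, 1.0)) * cs
        records.append((lon, lat, f"sim{k}"))
    return OccurrenceSet(records, species=species)


def perturb_scenario(
    stack: GridStack, deltas: dict[str, tuple[float, float]]
) -> GridStack:
    """Future-scenario stack: x -> shift + scale·x on the named layers.

    Untouched layers are copied; nodata masks are preserved.
    """
    missing = [c for c in deltas if c not in stack]
    if missing:
        raise ValueError(f"delta layers not in stack: {missing}")
    out = []
    for code, grid in stack.layers.items():
        if code in deltas:
            shift, scale = deltas[code]
            vals = np.where(grid.mask, shift + scale * grid.values, grid.values)
            out.append((code, grid.with_values(vals)))
        else:
            out.append((code, grid.with_values(grid.values.copy())))
    return stack_layers(out)


def make_zones(
    mask: Grid | tuple[int, int],
    k: int = 5,
    seed: int = 0,
    cell_area_km2: float = CELL_AREA_KM2,
) -> ZoneSet:
    """Partition the valid cells into k contiguous zones (seeded Voronoi).

    ``mask`` is a validity grid (or a plain shape, meaning all-valid).  k
    seed cells are drawn uniformly; every valid cell joins its nearest
    seed (ties to the lower zone id).  Zone ids run 1..k; the table holds
    name ``zone_i`` and total area = cells × cell area.
    """
    if isinstance(mask, tuple):
        mask = Grid(np.ones(mask), (0.0, 45.0, ARCMIN_2_5), nodata=-1.0)
    if k < 1:
        raise ValueError("k must be >= 1")
    valid = np.argwhere(mask.mask & (mask.values != 0))
    if k > len(valid):
        raise ValueError(f"k={k} exceeds the {len(valid)} valid cells")
    rng = np.random.default_rng(seed)
    seeds = valid[rng.choice(len(valid), size=k, replace=False)]
    d2 = ((valid[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assignment = np.argmin(d2, axis=1) + 1  # argmin takes the lowest id on ties
    raster = np.zeros(mask.shape)
    raster[valid[:, 0], valid[:, 1]] = assignment
    table = {}
    for z in range(1, k + 1):
        n_cells = int((assignment == z).sum())
        table[z] = (f"zone_{z}", n_cells * cell_area_km2)
    zgrid = Grid(raster, mask.transform, nodata=-1.0, crs_tag=mask.crs_tag)
    return ZoneSet(zgrid, table)
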