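"""End-to-end pipeline: rarefaction → variable selection → model → maps → tables.

A YAML config (or :class:`PipelineConfig`) names the inputs — occurrence
CSV and layer rasters, or a synthetic virtual-species specification — and
the run-level constants (correlation method and threshold, 75/25 split,
background size, replicate count, regularisation, cell area, scenarios,
master seed).  Every stage seed is derived from the master seed by a fixed
offset, the resolved config is written next to the outputs, and all
artifacts are re-readable by the modules that define their formats.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .grid import Grid, GridStack, read_grid, stack_layers, valid_mask, write_grid
from .habitat import ZoneSet, binarize, change_summary, suitable_area
from .model import (
    EnsembleResult,
    ensemble_replicates,
    fit_maxent,
    mtss_from_model,
    percent_contribution,
    permutation_importance,
    predict_cloglog,
)
from .occurrences import OccurrenceSet, load_occurrences, rarefy, sample_background
from .varselect import pairwise_correlation, prune_collinear

logger = logging.getLogger("maxniche")

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed offsets deriving stage seeds from the master seed
SEED_BACKGROUND = 11
SEED_REPLICATES = 1000
SEED_SYNTH_STACK = 21
SEED_SYNTH_PRESENCES = 31
SEED_ZONES = 41
SEED_PERMUTATION = 51


@dataclass
class PipelineConfig:
    """Run-level settings; defaults mirror the study conventions."""

    output_dir: str = "maxniche_run"
    occurrences: str | None = None
    layers: dict[str, str] = field(default_factory=dict)  # code -> raster path
    scenario_layers: dict[str, dict[str, str]] = field(default_factory=dict)
    zone_raster: str | None = None
    zone_table: str | None = None
    synthetic: dict | None = None
    correlation_method: str = "spearman"
    correlation_threshold: float = 0.75
    train_frac: float = 0.75
    n_background: int = 10_000
    n_replicates: int = 100
    reg_multiplier: float = 1.0
    cell_area_km2: float = 4.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _stage(name: str):
    """Wrap a stage so failures carry the stage name."""
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("inputs")
def _load_inputs(cfg: PipelineConfig):
    """Returns (stack, scenario stacks, occurrences, zones or None)."""
    if cfg.synthetic is not None:
        s = dict(cfg.synthetic)
        shape = tuple(s.get("shape", (100, 100)))
        n_layers = int(s.get("n_layers", 6))
        corr = np.asarray(s["corr_target"], dtype=float) if "corr_target" in s else None
        stack = synthetic.simulate_bioclim_stack(
            shape, n_layers=n_layers, corr_target=corr,
            smoothing=float(s.get("smoothing", 5.0)), seed=cfg.seed + SEED_SYNTH_STACK,
        )
        niche = synthetic.make_virtual_niche(stack, dict(s.get("true_lambda", {})))
        occ = synthetic.sample_presences(
            niche, n=int(s.get("n_presences", 500)),
            dup_rate=float(s.get("dup_rate", 0.2)), seed=cfg.seed + SEED_SYNTH_PRESENCES,
        )
        scenarios = {
            tag: synthetic.perturb_scenario(
                stack, {c: tuple(d) for c, d in deltas.items()}
            )
            for tag, deltas in dict(s.get("scenario_deltas", {})).items()
        }
        zones = None
        if s.get("zones_k"):
            zones = synthetic.make_zones(
                valid_mask(stack), k=int(s["zones_k"]), seed=cfg.seed + SEED_ZONES,
                cell_area_km2=cfg.cell_area_km2,
            )
        return stack, scenarios, occ, zones
    if not cfg.layers or not cfg.occurrences:
        raise ValueError("config needs either `synthetic` or both `layers` and `occurrences`")
    stack = stack_layers([(c, read_grid(p)) for c, p in cfg.layers.items()])
    scenarios = {
        tag: stack_layers([(c, read_grid(p)) for c, p in paths.items()])
        for tag, paths in cfg.scenario_layers.items()
    }
    occ, report = load_occurrences(cfg.occurrences)
    logger.info("loaded occurrences: %s", report.as_dict())
    zones = None
    if cfg.zone_raster and cfg.zone_table:
        zones = ZoneSet.from_csv(read_grid(cfg.zone_raster), cfg.zone_table)
    elif cfg.zone_raster or cfg.zone_table:
        logger.warning("zone raster/table incomplete; zonal outputs skipped")
    return stack, scenarios, occ, zones


def run_pipeline(cfg: PipelineConfig) -> str:
    """Run every stage and write all artifacts; returns the output dir."""
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    log: dict = {"seed": cfg.seed, "stage_seeds": {
        "background": cfg.seed + SEED_BACKGROUND,
        "replicates_base": cfg.seed + SEED_REPLICATES,
    }}

    stack, scenarios, occ_raw, zones = _load_inputs(cfg)
    mask = valid_mask(stack)
    log["n_occurrences_raw"] = len(occ_raw)

    occ = rarefy(occ_raw, mask)
    log["n_occurrences_rarefied"] = len(occ)
    logger.info("rarefaction: %d -> %d records", len(occ_raw), len(occ))
    occ.to_csv(os.path.join(out, "occurrences_rarefied.csv"))

    background = sample_background(mask, n=cfg.n_background, seed=cfg.seed + SEED_BACKGROUND)
    log["n_background"] = len(background)

    # variable selection on the background sample, priority by univariate gain
    corr = pairwise_correlation(stack, background, method=cfg.correlation_method)
    corr.to_csv(os.path.join(out, "correlation_matrix.csv"))
    B = pd.DataFrame(stack.values_at(background.cells), columns=stack.codes)
    pres_cells = np.asarray(
        [c for c in occ.cells_on(mask) if c is not None and mask.values[c] > 0]
    )
    P = pd.DataFrame(stack.values_at(pres_cells), columns=stack.codes)
    priority = {}
    for code in stack.codes:
        uni = fit_maxent(P[[code]], B[[code]], feature_classes={"L", "Q"},
                         reg_multiplier=cfg.reg_multiplier, tol=1e-5, max_iter=500)
        priority[code] = uni.gain_
    selected = prune_collinear(corr, threshold=cfg.correlation_threshold, priority=priority)
    log["variables_selected"] = selected
    log["variables_dropped"] = [c for c in stack.codes if c not in selected]
    with open(os.path.join(out, "variable_selection.json"), "w") as fh:
        json.dump({"method": cfg.correlation_method, "threshold": cfg.correlation_threshold,
                   "priority_gain": priority, "selected": selected,
                   "dropped": log["variables_dropped"]}, fh, indent=1)
    stack_sel = stack.subset(selected)
    scenarios_sel = {tag: s.subset(selected) for tag, s in scenarios.items()}

    ens = ensemble_replicates(
        occ, stack_sel, n_replicates=cfg.n_replicates, train_frac=cfg.train_frac,
        n_background=cfg.n_background, seed=cfg.seed + SEED_REPLICATES,
        model_params={"reg_multiplier": cfg.reg_multiplier},
    )
    ens.full_model.save(os.path.join(out, "model.json"))
    _write_evaluation(ens, out)
    log["mean_holdout_auc"] = float(np.mean([r.auc for r in ens.reports]))

    contrib = percent_contribution(ens.full_model)
    perm = permutation_importance(
        ens.full_model, P[selected], B[selected], seed=cfg.seed + SEED_PERMUTATION
    )
    pd.DataFrame(
        {"code": list(contrib), "percent_contribution": list(contrib.values()),
         "permutation_importance": [perm[c] for c in contrib]}
    ).to_csv(os.path.join(out, "variable_importance.csv"), index=False)

    threshold = mtss_from_model(ens.full_model)
    log["mtss_threshold"] = threshold

    suitability = {"current": ens.mean_grid}
    write_grid(ens.mean_grid, os.path.join(out, "suitability_current.tif"))
    for tag, sc_stack in scenarios_sel.items():
        g = predict_cloglog(ens.full_model, sc_stack)
        suitability[tag] = g
        write_grid(g, os.path.join(out, f"suitability_{_slug(tag)}.tif"))
    areas = {}
    for tag, g in suitability.items():
        bmap = binarize(g, threshold, scenario_tag=tag)
        write_grid(bmap.values, os.path.join(out, f"binary_{_slug(tag)}.tif"))
        areas[tag] = suitable_area(bmap, cfg.cell_area_km2)
    log["suitable_area_km2"] = areas

    if zones is not None:
        summary = change_summary(suitability, threshold, zones,
                                 cell_area_km2=cfg.cell_area_km2)
        summary.to_csv(os.path.join(out, "suitability_summary.csv"), index=False)
        zones.to_csv(os.path.join(out, "zones.csv"))
        write_grid(zones.zone_raster, os.path.join(out, "zones.tif"))
    else:
        logger.warning("no zones provided; zonal summary skipped")

    cfg.to_yaml(os.path.join(out, "config_resolved.yml"))
    with open(os.path.join(out, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=1)
    return out


def _write_evaluation(ens: EnsembleResult, out: str) -> None:
    rows = [r.as_dict() for r in ens.reports]
    with open(os.path.join(out, "evaluation.json"), "w") as fh:
        json.dump(rows, fh, indent=1)
    df = pd.DataFrame(
        [{k: r[k] for k in ("auc", "auc_train", "threshold", "tss", "kappa")} for r in rows]
    )
    df.index.name = "replicate"
    df.to_csv(os.path.join(out, "evaluation.csv"))


def _slug(tag: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in tag)
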