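"""A complete, self-contained virtual-species recovery study.

This is the package's reference experiment: a six-layer correlated climate
world with a known two-variable Gibbs niche and an engineered collinear
layer, sampled with within-cell duplicates, then pushed through the whole
pipeline — rarefaction, collinearity pruning, MaxEnt fitting, holdout
validation, truth recovery, and a warming-scenario area change.  It is
what the documentation's worked example runs and what desk-scale checks
of the method's behaviour are scored on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic
from .evaluation import mtss_threshold, roc_auc
from .grid import GridStack, valid_mask
from .habitat import binarize, suitable_area
from .model import fit_maxent, percent_contribution, permutation_importance, predict_cloglog
from .occurrences import partition, rarefy, sample_background
from .varselect import pairwise_correlation, prune_collinear

__all__ = ["virtual_species_study"]

# study conditions: informative niche axes, the engineered collinear pair,
# and the warming perturbation applied to the temperature-like driver
TRUE_LAMBDA = {"Bio1": 10.0, "Bio4": -8.0}
COLLINEAR_PAIR = ("Bio1", "Bio6")
COLLINEAR_R = 0.9
WARMING_SHIFT = 2.0  # degrees added to Bio1 in the "future" stack


def _presence_matrix(occ, stack: GridStack, mask) -> pd.DataFrame:
    cells = np.asarray(
        [c for c in occ.cells_on(mask) if c is not None and mask.values[c] > 0]
    )
    return pd.DataFrame(stack.values_at(cells), columns=stack.codes)


def virtual_species_study(
    seed: int = 1,
    shape: tuple[int, int] = (200, 200),
    n_layers: int = 6,
    n_presences: int = 500,
    dup_rate: float = 0.2,
    n_background: int = 10_000,
    train_frac: float = 0.75,
) -> dict:
    """Run the reference recovery experiment and return its metrics.

    Returns a dict with (among others): raw and rarefied presence counts,
    the selected/dropped variables, whether the engineered collinear layer
    was removed, holdout AUC against background, Spearman rho between the
    predicted and true suitability over all valid cells, the top
    permutation-importance variables, and the percent area change under
    the warming scenario at the fixed MTSS threshold.
    """
    corr = np.eye(n_layers)
    i, j = (int(c[3:]) - 1 for c in COLLINEAR_PAIR)
    corr[i, j] = corr[j, i] = COLLINEAR_R

    stack = synthetic.simulate_bioclim_stack(
        shape, n_layers=n_layers, corr_target=corr, smoothing=5.0, seed=seed + 21
    )
    niche = synthetic.make_virtual_niche(stack, TRUE_LAMBDA)
    occ_raw = synthetic.sample_presences(
        niche, n=n_presences, dup_rate=dup_rate, seed=seed + 31
    )
    mask = valid_mask(stack)
    occ = rarefy(occ_raw, mask)

    background = sample_background(mask, n=n_background, seed=seed + 11)
    B = pd.DataFrame(stack.values_at(background.cells), columns=stack.codes)

    corr_mat = pairwise_correlation(stack, background, method="spearman")
    P_all = _presence_matrix(occ, stack, mask)
    priority = {
        code: fit_maxent(
            P_all[[code]], B[[code]], feature_classes={"L", "Q"}, tol=1e-5, max_iter=500
        ).gain_
        for code in stack.codes
    }
    selected = prune_collinear(corr_mat, threshold=0.75, priority=priority)

    train, test = partition(occ, train_frac=train_frac, seed=seed + 41)
    stack_sel = stack.subset(selected)
    P_train = _presence_matrix(train, stack_sel, mask)
    P_test = _presence_matrix(test, stack_sel, mask)
    B_sel = B[selected]
    model = fit_maxent(P_train, B_sel)

    bg_scores = model.predict(B_sel)
    holdout_auc = roc_auc(model.predict(P_test), bg_scores)
    predicted = predict_cloglog(model, stack_sel)
    truth_mask = niche.true_suitability.mask & predicted.mask
    rho = stats.spearmanr(
        predicted.values[truth_mask], niche.true_suitability.values[truth_mask]
    ).statistic

    importance = permutation_importance(model, P_train, B_sel, seed=seed + 51)
    contribution = percent_contribution(model)
    top2 = sorted(importance, key=importance.get, reverse=True)[:2]

    threshold = mtss_threshold(model.predict(P_train), bg_scores)
    current_area = suitable_area(binarize(predicted, threshold, "current"))
    future_stack = synthetic.perturb_scenario(stack_sel, {"Bio1": (WARMING_SHIFT, 1.0)})
    future = predict_cloglog(model, future_stack)
    future_area = suitable_area(binarize(future, threshold, "warming"))

    return {
        "n_presences_raw": len(occ_raw),
        "n_presences_rarefied": len(occ),
        "selected": selected,
        "dropped": [c for c in stack.codes if c not in selected],
        "collinear_layer_removed": COLLINEAR_PAIR[1] not in selected,
        "holdout_auc": float(holdout_auc),
        "suitability_spearman_rho": float(rho),
        "permutation_importance": importance,
        "percent_contribution": contribution,
        "top2_importance": top2,
        "informative_in_top2": set(top2) == set(TRUE_LAMBDA),
        "mtss_threshold": float(threshold),
        "current_area_km2": float(current_area),
        "warming_area_km2": float(future_area),
        "warming_area_change_pct": float(
            100.0 * (future_area - current_area) / current_area
        ) if current_area > 0 else None,
        "model": model,
    }
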