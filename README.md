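# maxniche

Presence-only maximum-entropy species distribution modelling (SDM), built
for habitat-suitability studies of the kind used to forecast the spread of
invasive plants such as *Parthenium hysterophorus* under climate change:
occurrence records plus bioclimatic raster layers in, suitability maps,
validation scores, and habitat-change tables out.

The pipeline mirrors standard SDM practice:

1. **Spatial rarefaction** — occurrence records are thinned to one per
   grid cell (2.5-arcmin convention, ~4.5 km² per cell) to curb sampling
   bias and spatial autocorrelation.
2. **Variable selection** — candidate layers (e.g. the Bio1–Bio19
   bioclimatic variables) are correlated pairwise over a background
   sample (Spearman by default) and greedily pruned until every retained
   pair satisfies |r| < 0.75.
3. **MaxEnt niche model** — a Gibbs distribution q(x) ∝ exp(λ·f(x)) over
   background cells, with linear/quadratic/product/hinge/threshold
   features and an L1 penalty, fitted by minimising

   J(λ) = −mean_presence[λ·f] + log mean_background[exp(λ·f)] + Σⱼ βⱼ|λⱼ|.

   Suitability maps use the cloglog output
   c(x) = 1 − exp(−e^H·q̃(x)) ∈ [0, 1], with H the entropy of q.
4. **Validation** — ROC-AUC (exact rank formulation), the true skill
   statistic TSS = sensitivity + specificity − 1, and Cohen's kappa at
   the maximum-training-sensitivity-plus-specificity (MTSS) threshold,
   with replicated 75/25 calibration/validation splits.
5. **Habitat change** — binary suitable/unsuitable maps at the MTSS
   threshold, suitable area at 4.5 km²/cell, percent change against the
   current climate, and per-zone mean suitability classified as low
   (≤0.25), moderate (≤0.50), high (≤0.75), or very high (>0.75).

A virtual-species generator (correlated Gaussian random-field "climate"
layers, a known Gibbs-form truth, duplicate-laden presence sampling,
perturbed future scenarios, Voronoi zones) makes every stage testable at
desk scale with no downloads.

The MaxEnt model is a scikit-learn-style estimator (`MaxEnt().fit(X, y)`
with y = 1 for presences, 0 for background; `predict` returns cloglog
suitability) and the collinearity pruner a sklearn transformer, so both
compose with sklearn pipelines and model selection.

## Worked example

The package's reference experiment builds a 200×200-cell world with six
correlated climate layers (one engineered to correlate at r = 0.9 with an
informative layer), defines a true niche from two layers (weights +10 on
Bio1, −8 on Bio4), samples 500 presence records with 20% within-cell
duplicates, and runs the full pipeline:

```python
from maxniche.experiment import virtual_species_study

r = virtual_species_study(seed=1)
print(r["n_presences_raw"], "->", r["n_presences_rarefied"])  # rarefaction
print(r["selected"], "dropped:", r["dropped"])
print("holdout AUC", round(r["holdout_auc"], 3))
print("rank recovery rho", round(r["suitability_spearman_rho"], 3))
print("MTSS threshold", round(r["mtss_threshold"], 3))
print("area now", r["current_area_km2"], "km2,",
      "warming:", round(r["warming_area_change_pct"], 1), "% change")
```

prints

```
500 -> 400
['Bio1', 'Bio2', 'Bio3', 'Bio4', 'Bio5'] dropped: ['Bio6']
holdout AUC 0.857
rank recovery rho 0.966
MTSS threshold 0.21
area now 31689.0 km2, warming: 37.0 % change
```

Reading: rarefaction removed exactly the 100 duplicated records; the
pruner dropped the engineered collinear layer and kept the informative
ones; the fitted model separates holdout presences from background well
(AUC 0.86) and ranks cells almost exactly as the true suitability does
(Spearman ρ 0.97); a uniform +2° warming shift on the temperature-like
driver enlarges the suitable area by ~37% at the fixed MTSS threshold —
the qualitative behaviour expected for a warmth-limited invader.

There is also a CLI (`maxniche --help`) with subcommands `simulate`,
`rarefy`, `select-vars`, `fit`, `evaluate`, `project`, `threshold`,
`change`, and `run` (full pipeline from a YAML config).

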