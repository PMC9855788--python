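# Methods

## The model

maxniche estimates a presence-only species distribution as a maximum-entropy
(Gibbs) distribution over the background cells of a study region. Given
feature transforms f(x) ∈ [0,1]^m of the environmental variables at a cell
x, the model is

    q(x) = exp(λ·f(x)) / Σ_background exp(λ·f(x'))    (the "raw" output),

and λ is chosen to minimise the L1-regularised negative log-likelihood of
the presence sample,

    J(λ) = −mean_presence[λ·f] + log mean_background[exp(λ·f)] + Σ_j β_j |λ_j|.

J is convex; its unpenalised negative is the *training gain* (zero for the
uniform model). The assumptions are the usual ones for presence-background
SDMs: presences are an (approximately) independent sample proportional to
q over the landscape, the background sample represents availability, and
the environmental layers capture the axes that limit the species.

Suitability maps use the cloglog transform

    c(x) = 1 − exp(−e^H · q̃(x)),

where q̃ is the raw-scale density evaluated at arbitrary cells and H is the
entropy of q over the training background. c lies in [0,1], is monotone in
λ·f, and equals 1 − 1/e ≈ 0.632 everywhere for the uninformative model —
useful as a mental reference point when reading maps.

### Features and regularisation

Variables are expanded into linear, quadratic, product, hinge and
threshold features, each min–max scaled into [0,1] over the training
background. Hinge/threshold knots sit at interior background quantiles
(10 per variable by default). Feature classes default by presence count:
fewer than 10 presences uses linear only; 10–79 adds quadratic and hinge;
80+ adds products and thresholds. Each feature's penalty is

    β_j = reg_multiplier × β_class(n_presence) × sd_j(background) / √n_presence,

with class bases 1.0 (linear/quadratic/product/threshold) and 0.5 (hinge),
eased down log-linearly to half between 10 and 100 presences and capped at
the base below 10. These defaults are declared here, not inferred from any
particular MaxEnt implementation; bit-compatibility with other tools is a
non-goal.

### Optimisation

Cyclic coordinate descent with soft-thresholding handles the L1 term: each
coordinate takes a Newton step on the smooth part (gradient E_q[f_j] −
mean_presence[f_j], curvature Var_q(f_j)), soft-thresholds at β_j, and
backtracks until the objective actually decreases, so J is non-increasing
across updates. Convergence is a relative objective change below 1e-6 over
a full cycle (cap 5000 cycles; non-convergence returns the model with a
flag and a warning). Each accepted update's objective decrease is credited
to the updated feature's variable(s) — split equally for products — which
is exactly the bookkeeping that percent-contribution reporting needs.
Negative credits are floored at zero and the vector normalised to 100.

### Projection and clamping

When projecting onto other rasters (including future scenarios), variable
values are clipped to the training background range of each variable by
default, so the model never extrapolates feature responses beyond observed
conditions. Clamping can be disabled per model.

## Pipeline conventions

* **Rarefaction** keeps the first record (file order) in each occupied
  grid cell — deterministic, and idempotent by construction. Records on
  nodata cells or outside the grid are dropped.
* **Point-in-cell** uses half-open intervals [west, east) × (south,
  north], so boundary points belong to exactly one cell.
* **Splits** are seeded random 75/25 partitions of the rarefied records;
  replicate r derives its seed as base + r. The replicate ambiguity
  (re-splits vs bootstrap vs cross-validation) is resolved as re-splits.
* **Background** defaults to 10,000 cells drawn uniformly without
  replacement from the valid mask; presences are not excluded (the usual
  presence-background convention).
* **Correlation** defaults to Spearman (Pearson available; the method is
  recorded in every report). Correlations are computed on the background
  sample. Pruning is greedy: while any pair violates |r| < threshold
  (strict), resolve the strongest-correlated violating pair by dropping
  its lower-priority member (priority = univariate model gain in the
  pipeline; ties break toward the member with larger mean |r| against the
  remainder, then later input order). Resolving the strongest pair first
  makes the selected set monotone non-shrinking in the threshold.
* **Evaluation** treats background points as pseudo-absences. AUC is the
  exact rank-based pair statistic. TSS and kappa are reported at the MTSS
  threshold — the smallest candidate score (observed scores plus 0)
  maximising training sensitivity + specificity — because that is the
  operational threshold used for mapping.
* **Areas** use a constant 4.5 km² per cell (the 2.5-arcmin convention at
  the equator), deliberately ignoring the cosine(latitude) distortion so
  the arithmetic matches the reporting convention of published tables; a
  latitude-corrected mode would be a straightforward extension but is off
  scope here. Percent change against a zero current area is reported as a
  `new_colonization` sentinel rather than a number.
* **Zone means** average cloglog suitability over *all* valid cells of a
  zone (not only suitable ones), so divisions with zero suitable area
  still get a defined category. Category boundaries are continuous
  half-open intervals at 0.25 / 0.50 / 0.75 (printed two-decimal bounds
  like "0.26–0.50" are read as the rounding of those).
* **Ensembles** average cloglog grids cellwise over replicates and
  threshold the averaged map with the MTSS threshold of the full-data
  calibration model.

## The virtual-species generator

The generator emulates the inputs of a desk-scale SDM study: layers are
white noise smoothed with a Gaussian kernel (lengthscale in cells),
standardised, and mixed through a factor of a target correlation matrix,
giving smooth, mutually correlated fields with controllable collinearity;
a known niche is a Gibbs model over min–max-scaled layers; presences are
distinct cells drawn without replacement proportionally to the true raw
density, plus a chosen fraction of within-cell duplicates (what
rarefaction should remove); future scenarios are affine perturbations of
layers; zones are a seeded Voronoi partition of the valid cells.

What it does *not* emulate: spatially biased sampling (roadside effects,
uneven collection effort beyond duplication), non-stationary or
anisotropic spatial structure, realistic climate physics or downscaling,
land-use covariates, and observation error in coordinates. Passing the
recovery checks therefore demonstrates the statistical machinery is
correct under the stated sampling model — not that any real-data analysis
is free of the biases above.

### Reference experiment conditions

The packaged study (`maxniche.experiment.virtual_species_study`) uses a
200×200 grid, six layers at smoothing lengthscale 5 cells, an engineered
r = 0.9 collinear pair (Bio1–Bio6), 500 presences at 20% duplication,
10,000 background cells, and a two-variable truth with weights +10 (Bio1)
and −8 (Bio4). The effect size was set by analysing the data-generating
process itself: with these weights the *ideal* model (scoring cells by the
true suitability) separates presences from background at AUC ≈ 0.88, i.e.
the virtual species is strongly climate-limited, the regime these methods
are designed for; substantially weaker niches make even a perfect fit
hover near AUC 0.8 and tell you nothing about estimation quality. The
warming scenario shifts the temperature-like driver by +2 units with the
threshold held fixed. These sizes keep the full study near ten seconds on
one CPU while leaving the recovery metrics stable across seeds.

## Numerical choices and degenerate inputs

* Constant variables are dropped from features (with a warning); constant
  layers correlate as r = 0 (flagged) rather than NaN.
* Curvature in coordinate steps is floored at 1e-12; raw probabilities are
  clipped at 1e-300 before the entropy log.
* ESRI ASCII is written with 6 significant digits; GeoTIFF as float32
  single band with explicit nodata, pixel-scale/tiepoint and a minimal
  geographic-WGS84 geokey directory. Round-trips preserve values to those
  precisions, and masks and transforms exactly.
* The MTSS tie-break (smallest maximising threshold) uses a 1e-12
  tolerance so ties computed along different floating-point paths resolve
  identically.
* Empty occurrence sets rarefy to empty; splits require at least two
  records; background sampling requires at least one valid cell; zones
  with no valid cells get NaN means flagged "undefined".

## Known limitations

* Raw output is defined only on the training background (by
  construction); asking for it elsewhere raises.
* Serialised models keep weights, features, scaling and metadata but not
  the training matrices, so threshold re-derivation needs the training
  data or a stored threshold.
* Collinearity pruning is greedy, not globally optimal; with adversarial
  priorities it may keep fewer variables than the best feasible subset.
* The constant-cell-area convention overstates areas away from the
  equator, exactly as the reporting convention it reproduces does.
* Percent-contribution is path-dependent (a property of the optimisation
  trace, as in the tool family this follows), so it should be read
  comparatively, not as a variance decomposition.
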