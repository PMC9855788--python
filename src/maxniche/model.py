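"""Presence-only maximum-entropy (MaxEnt) niche model.

The model estimates a Gibbs distribution q(x) ∝ exp(λ·f(x)) over the
background cells of the study region, choosing the feature weights λ to
minimise the L1-regularised negative log-likelihood of the presences

    J(λ) = −mean_presence[λ·f] + log mean_background[exp(λ·f)] + Σ_j β_j |λ_j|.

J is convex; it is minimised by cyclic coordinate descent with
soft-thresholding, which also yields the per-update gain trace used for
percent-contribution accounting.  The fitted raw distribution q over the
training background sums to one; suitability maps use the cloglog
transform c(x) = 1 − exp(−e^H · q̃(x)) with H the entropy of q, which is
bounded in [0, 1] and equals 1 − 1/e for an uninformative model.

The estimator follows the scikit-learn protocol: ``fit(X, y)`` with y = 1
for presences and y = 0 for background rows, ``predict(X)`` returning
cloglog suitability, and trailing-underscore fitted attributes.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .evaluation import roc_auc
from .features import FeatureSet, auto_feature_classes
from .grid import Grid, GridStack, valid_mask
from .occurrences import CellSample, OccurrenceSet, partition, sample_background

__all__ = [
    "MaxEnt",
    "fit_maxent",
    "predict_raw",
    "predict_cloglog",
    "mtss_from_model",
    "percent_contribution",
    "permutation_importance",
    "jackknife_gains",
    "ensemble_replicates",
    "EnsembleResult",
]

# base L1 strength by feature class; scaled by sd/sqrt(n) in _betas
_CLASS_BETA = {"linear": 1.0, "quadratic": 1.0, "hinge": 0.5, "product": 1.0, "threshold": 1.0}


def _default_beta(kind: str, n_presence: int) -> float:
    """Class base regularisation, eased down as presences accumulate."""
    base = _CLASS_BETA[kind]
    if n_presence <= 10:
        return base  # capped: tiny samples never get weaker regularisation
    # halve smoothly between 10 and 100 presences (log-linear), flat beyond
    frac = min(np.log10(n_presence / 10.0) / 1.0, 1.0)
    return base * (1.0 - 0.5 * frac)


class MaxEnt(BaseEstimator):
    """L1-regularised maximum-entropy presence/background model.

    Parameters
    ----------
    feature_classes : "auto" or iterable of {"L","Q","P","H","T"}
        "auto" picks classes by presence count (<10: L; <80: L,Q,H;
        otherwise all five).
    hinge_knots : int, default 10
        Knots per variable for hinge/threshold features, at background
        quantiles.
    reg_multiplier : float, default 1.0
        Global multiplier on every feature's L1 penalty.
    tol : float, default 1e-6
        Convergence: relative objective change per full coordinate cycle.
    max_iter : int, default 5000
        Maximum coordinate-descent cycles.
    clamp : bool, default True
        Clip projection inputs to the training background range of each
        variable (no extrapolation beyond observed conditions).

    Attributes
    ----------
    lambda_ : ndarray of feature weights
    beta_ : ndarray of per-feature L1 strengths
    log_z_ : float, log mean_background exp(λ·f)
    entropy_ : float, entropy H of the raw distribution over background
    raw_ : ndarray, the fitted q over the training background (sums to 1)
    gain_ : float, unpenalised training gain
    features_ : FeatureSet
    converged_ : bool;  n_iter_ : int
    contribution_trace_ : dict variable code -> accumulated gain credit
    """

    def __init__(
        self,
        feature_classes="auto",
        hinge_knots: int = 10,
        reg_multiplier: float = 1.0,
        tol: float = 1e-6,
        max_iter: int = 5000,
        clamp: bool = True,
    ):
        self.feature_classes = feature_classes
        self.hinge_knots = hinge_knots
        self.reg_multiplier = reg_multiplier
        self.tol = tol
        self.max_iter = max_iter
        self.clamp = clamp

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        """Fit on raw variable values; y = 1 marks presence rows, 0 background."""
        if isinstance(X, pd.DataFrame):
            codes = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            codes = [f"x{j}" for j in range(Xv.shape[1])]
        y = np.asarray(y)
        if Xv.ndim != 2 or len(y) != len(Xv):
            raise ValueError("X must be 2-D with one y entry per row")
        if not np.all(np.isfinite(Xv)):
            raise ValueError("X contains non-finite values")
        pres, bg = Xv[y == 1], Xv[y == 0]
        if len(pres) < 1 or len(bg) < 2:
            raise ValueError(
                f"need >=1 presence and >=2 background rows, got {len(pres)}/{len(bg)}"
            )
        classes = (
            auto_feature_classes(len(pres))
            if isinstance(self.feature_classes, str) and self.feature_classes == "auto"
            else set(self.feature_classes)
        )
        self.features_ = FeatureSet.from_background(
            bg, codes=codes, classes=classes, hinge_knots=self.hinge_knots
        )
        Fp = self.features_.transform(pres)
        Fb = self.features_.transform(bg)
        self._fit_features(Fp, Fb)
        self.background_X_ = bg
        self.presence_X_ = pres
        self.codes_ = codes
        self.n_features_in_ = Xv.shape[1]
        return self

    def _fit_features(self, Fp: np.ndarray, Fb: np.ndarray) -> None:
        """Coordinate descent on pre-built presence/background feature matrices."""
        n_pres, m = Fp.shape
        n_bg = Fb.shape[0]
        beta = np.array(
            [
                self.reg_multiplier
                * _default_beta(f.kind, n_pres)
                * Fb[:, j].std()
                / np.sqrt(n_pres)
                for j, f in enumerate(self.features_.definitions)
            ]
        )
        mean_fp = Fp.mean(axis=0)
        lam = np.zeros(m)
        eta = np.zeros(n_bg)  # Fb @ lam, maintained incrementally

        def objective(eta_b: np.ndarray, lam_v: np.ndarray) -> float:
            return float(
                -mean_fp @ lam_v + logsumexp(eta_b) - np.log(n_bg) + beta @ np.abs(lam_v)
            )

        J = objective(eta, lam)
        credit: dict[str, float] = {c: 0.0 for c in self.features_.codes}
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            J_cycle_start = J
            for j in range(m):
                fj = Fb[:, j]
                w = np.exp(eta - eta.max())
                w /= w.sum()
                Eq = float(w @ fj)
                g = Eq - mean_fp[j]
                h = float(w @ (fj * fj)) - Eq * Eq
                if h < 1e-12:
                    h = 1e-12
                z = lam[j] - g / h
                new = np.sign(z) * max(abs(z) - beta[j] / h, 0.0)
                d = new - lam[j]
                if d == 0.0:
                    continue
                # backtrack until the convex objective actually decreases
                accepted = False
                for _ in range(30):
                    lam_try = lam.copy()
                    lam_try[j] = lam[j] + d
                    eta_try = eta + d * fj
                    J_try = objective(eta_try, lam_try)
                    if J_try <= J + 1e-15:
                        accepted = True
                        break
                    d *= 0.5
                if not accepted:
                    continue
                delta = J - J_try  # increase in penalised gain
                for code in self.features_.definitions[j].variables:
                    credit[code] += delta / len(self.features_.definitions[j].variables)
                lam, eta, J = lam_try, eta_try, J_try
            denom = max(abs(J_cycle_start), 1e-12)
            if abs(J_cycle_start - J) / denom < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"coordinate descent did not converge in {self.max_iter} cycles",
                stacklevel=2,
            )
        self.lambda_ = lam
        self.beta_ = beta
        self.log_z_ = float(logsumexp(eta) - np.log(n_bg))  # log mean exp
        q = np.exp(eta - self.log_z_) / n_bg
        self.raw_ = q
        self.entropy_ = float(-np.sum(q * np.log(np.clip(q, 1e-300, None))))
        self.gain_ = float(mean_fp @ lam - self.log_z_)
        self.converged_ = converged
        self.n_iter_ = it
        self.contribution_trace_ = credit
        self.n_presence_ = n_pres
        self.n_background_ = n_bg

    # -- prediction ---------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """λ·f(x) (clamped to the training range when ``clamp`` is set)."""
        check_is_fitted(self, "lambda_")
        F = self.features_.transform(self._coerce(X), clamp=self.clamp)
        return F @ self.lambda_

    def predict_qtilde(self, X) -> np.ndarray:
        """Raw-scale density q̃(x) = exp(λ·f − logZ)/n_bg at arbitrary points."""
        return np.exp(self.decision_function(X) - self.log_z_) / self.n_background_

    def predict(self, X) -> np.ndarray:
        """Cloglog suitability c(x) = 1 − exp(−e^H · q̃(x)) in [0, 1]."""
        return 1.0 - np.exp(-np.exp(self.entropy_) * self.predict_qtilde(X))

    def _coerce(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.codes_ if c not in X.columns]
            if missing:
                raise ValueError(f"missing variable column(s) {missing}")
            return X[self.codes_].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "lambda_")
        params = self.get_params()
        if isinstance(params.get("feature_classes"), (set, frozenset)):
            params["feature_classes"] = sorted(params["feature_classes"])
        return {
            "params": params,
            "codes": self.codes_,
            "features": self.features_.to_dict(),
            "lambda": self.lambda_.tolist(),
            "beta": self.beta_.tolist(),
            "log_z": self.log_z_,
            "entropy": self.entropy_,
            "gain": self.gain_,
            "converged": self.converged_,
            "n_iter": self.n_iter_,
            "n_presence": self.n_presence_,
            "n_background": self.n_background_,
            "contribution_trace": self.contribution_trace_,
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "MaxEnt":
        with open(path) as fh:
            d = json.load(fh)
        params = d["params"]
        if isinstance(params.get("feature_classes"), list):
            params["feature_classes"] = set(params["feature_classes"])
        model = cls(**params)
        model.features_ = FeatureSet.from_dict(d["features"])
        model.codes_ = list(d["codes"])
        model.lambda_ = np.asarray(d["lambda"])
        model.beta_ = np.asarray(d["beta"])
        model.log_z_ = d["log_z"]
        model.entropy_ = d["entropy"]
        model.gain_ = d["gain"]
        model.converged_ = d["converged"]
        model.n_iter_ = d["n_iter"]
        model.n_presence_ = d["n_presence"]
        model.n_background_ = d["n_background"]
        model.contribution_trace_ = d["contribution_trace"]
        model.raw_ = None
        model.background_X_ = None
        model.presence_X_ = None
        return model


# -- module-level operation surface ---------------------------------------

def fit_maxent(
    presences: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
    reg_multiplier: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 5000,
    **kwargs,
) -> MaxEnt:
    """Fit from separate presence and background raw-variable matrices."""
    if isinstance(presences, pd.DataFrame) and isinstance(background, pd.DataFrame):
        X = pd.concat([presences, background], axis=0, ignore_index=True)
    else:
        X = np.vstack([np.asarray(presences, float), np.asarray(background, float)])
    y = np.r_[np.ones(len(presences)), np.zeros(len(background))]
    return MaxEnt(reg_multiplier=reg_multiplier, tol=tol, max_iter=max_iter, **kwargs).fit(X, y)


def predict_raw(model: MaxEnt, cells) -> np.ndarray:
    """The normalised Gibbs probabilities q over the training background.

    Raw output is only defined on the training background; passing any
    other matrix raises.
    """
    check_is_fitted(model, "lambda_")
    cells = model._coerce(cells)
    if model.background_X_ is None or cells.shape != model.background_X_.shape or not np.allclose(
        cells, model.background_X_
    ):
        raise ValueError("raw output is defined only on the training background cells")
    return model.raw_


def predict_cloglog(model: MaxEnt, stack: GridStack) -> Grid:
    """Project the model over a layer stack as a cloglog suitability grid."""
    check_is_fitted(model, "lambda_")
    missing = [c for c in model.codes_ if c not in stack]
    if missing:
        raise ValueError(f"stack lacks model variable layer(s): {missing}")
    sub = stack.subset(model.codes_)
    mgrid = valid_mask(sub)
    cells = np.argwhere(mgrid.values > 0)
    out = np.full(sub.shape, np.nan)
    if len(cells):
        X = sub.values_at(cells)
        out[cells[:, 0], cells[:, 1]] = model.predict(X)
    ref = sub.layers[model.codes_[0]]
    return Grid(out, ref.transform, nodata=np.nan, crs_tag=ref.crs_tag)


def mtss_from_model(model: MaxEnt) -> float:
    """MTSS threshold from the model's own training scores.

    Maximises training sensitivity + specificity over the cloglog scores
    of the fitted presences against the training background.
    """
    from .evaluation import mtss_threshold

    check_is_fitted(model, "lambda_")
    if model.presence_X_ is None or model.background_X_ is None:
        raise ValueError("model was deserialised without its training data")
    return mtss_threshold(model.predict(model.presence_X_), model.predict(model.background_X_))


def percent_contribution(model: MaxEnt) -> dict[str, float]:
    """Share (%) of the training gain credited to each variable.

    Each accepted coordinate update's increase in penalised gain is
    credited to the updated feature's variable(s), split equally for
    products; negatives are floored at zero and the vector normalised to
    sum to 100.
    """
    check_is_fitted(model, "contribution_trace_")
    credit = {c: max(v, 0.0) for c, v in model.contribution_trace_.items()}
    total = sum(credit.values())
    if total <= 0:
        return {c: 0.0 for c in credit}
    return {c: 100.0 * v / total for c, v in credit.items()}


def permutation_importance(
    model: MaxEnt,
    presences: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
    seed: int = 0,
) -> dict[str, float]:
    """AUC drop (%) when each variable is permuted across all rows.

    The variable's values are shuffled jointly over presence and
    background rows, scores recomputed, and the training-AUC drop
    recorded; drops are floored at 0 and normalised to sum to 100.
    """
    check_is_fitted(model, "lambda_")
    P = model._coerce(presences)
    B = model._coerce(background)
    base = roc_auc(model.predict(P), model.predict(B))
    rng = np.random.default_rng(seed)
    drops: dict[str, float] = {}
    for j, code in enumerate(model.codes_):
        allv = np.r_[P[:, j], B[:, j]]
        perm = rng.permutation(allv)
        Pp, Bp = P.copy(), B.copy()
        Pp[:, j] = perm[: len(P)]
        Bp[:, j] = perm[len(P):]
        drops[code] = max(base - roc_auc(model.predict(Pp), model.predict(Bp)), 0.0)
    total = sum(drops.values())
    if total <= 0:
        return {c: 0.0 for c in drops}
    return {c: 100.0 * v / total for c, v in drops.items()}


def jackknife_gains(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    variables: list[str] | None = None,
    **fit_kwargs,
) -> dict[str, tuple[float, float]]:
    """Training gain with each variable alone and with it withheld.

    Returns code -> (gain_only, gain_without).  A variable whose
    single-variable model carries most of the full gain is the dominant
    niche axis; a large drop in gain_without marks unique information.
    """
    if not isinstance(presences, pd.DataFrame) or not isinstance(background, pd.DataFrame):
        raise TypeError("jackknife_gains requires DataFrames with variable columns")
    variables = variables or [str(c) for c in presences.columns]
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    out: dict[str, tuple[float, float]] = {}
    for v in variables:
        rest = [c for c in variables if c != v]
        only = fit_maxent(presences[[v]], background[[v]], **fit_kwargs)
        without = fit_maxent(presences[rest], background[rest], **fit_kwargs)
        out[v] = (only.gain_, without.gain_)
    return out


class EnsembleResult:
    """Replicated-split ensemble: mean cloglog grid plus per-replicate reports."""

    def __init__(self, mean_grid: Grid, reports: list, thresholds: list[float],
                 full_model: MaxEnt, background: CellSample):
        self.mean_grid = mean_grid
        self.reports = reports
        self.thresholds = thresholds
        self.full_model = full_model
        self.background = background


def ensemble_replicates(
    occ: OccurrenceSet,
    stack: GridStack,
    n_replicates: int = 100,
    train_frac: float = 0.75,
    n_background: int = 10_000,
    seed: int = 0,
    model_params: dict | None = None,
) -> EnsembleResult:
    """Replicate the 75/25 split, fit, and average the suitability maps.

    Replicate r splits with ``seed + r``, fits on the calibration
    presences against a shared background sample, projects a cloglog grid
    and evaluates on the holdout.  The ensemble map is the cellwise mean.
    A full-data model (all rarefied presences) supplies the operational
    MTSS threshold.
    """
    from .evaluation import evaluate  # local import to avoid cycle at module load

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    params = dict(model_params or {})
    mask = valid_mask(stack)
    background = sample_background(mask, n=n_background, seed=seed + 90_001)
    B = pd.DataFrame(stack.values_at(background.cells), columns=stack.codes)

    def presence_matrix(o: OccurrenceSet) -> pd.DataFrame:
        cells = [c for c in o.cells_on(mask) if c is not None and mask.values[c] > 0]
        if not cells:
            raise ValueError("no presence records fall on valid cells")
        arr = stack.values_at(np.asarray(cells))
        return pd.DataFrame(arr, columns=stack.codes)

    full_model = fit_maxent(presence_matrix(occ), B, **params)

    grids = []
    reports = []
    thresholds = []
    for r in range(n_replicates):
        try:
            train, test = partition(occ, train_frac=train_frac, seed=seed + r)
            model = fit_maxent(presence_matrix(train), B, **params)
            grid = predict_cloglog(model, stack)
            bg_scores = model.predict(B)
            rep = evaluate(
                model.predict(presence_matrix(test)),
                bg_scores,
                train_presence_scores=model.predict(presence_matrix(train)),
            )
        except Exception as exc:
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc
        grids.append(grid.values)
        reports.append(rep)
        thresholds.append(rep.threshold)
    mean_vals = np.nanmean(np.stack(grids), axis=0)
    mean_grid = Grid(mean_vals, stack.transform, nodata=np.nan)
    return EnsembleResult(mean_grid, reports, thresholds, full_model, background)
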