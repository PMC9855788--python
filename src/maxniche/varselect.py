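"""Collinearity screening of candidate environmental layers.

Bioclimatic predictors are strongly inter-correlated (temperature summaries
with each other, precipitation summaries with each other).  Before fitting,
layer values over a background cell sample are correlated pairwise
(Spearman by default, Pearson optionally) and a greedy rule prunes the set
until every retained pair satisfies ``|r| < threshold`` (default 0.75):
while a violating pair exists, drop its lower-priority member, where the
priority is typically each variable's univariate model gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .grid import GridStack
from .occurrences import CellSample

__all__ = [
    "CorrelationMatrix",
    "pairwise_correlation",
    "prune_collinear",
    "CollinearityPruner",
]


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise correlation of layer values over a cell sample."""

    codes: list[str]
    r: np.ndarray
    method: str = "spearman"
    constant: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.codes)
        if self.r.shape != (k, k):
            raise ValueError(f"r must be {k}x{k}, got {self.r.shape}")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.codes, columns=self.codes)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path)


def _corr_from_matrix(X: np.ndarray, codes: list[str], method: str) -> CorrelationMatrix:
    k = X.shape[1]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 sample cells for a robust coefficient")
    if method not in {"spearman", "pearson"}:
        raise ValueError(f"unknown correlation method {method!r}")
    sd = X.std(axis=0)
    constant = [codes[j] for j in range(k) if sd[j] == 0]
    if constant:
        warnings.warn(
            f"constant layer(s) {constant}: correlations against them set to 0",
            stacklevel=3,
        )
    if method == "spearman":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-input warnings handled above
            r, _ = stats.spearmanr(X)
        if np.ndim(r) == 0:  # scipy collapses the 2-column case to a scalar
            r = np.array([[1.0, float(r)], [float(r), 1.0]])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return CorrelationMatrix(list(codes), np.clip(r, -1, 1), method=method, constant=constant)


def pairwise_correlation(
    stack: GridStack, sample: CellSample, method: str = "spearman"
) -> CorrelationMatrix:
    """Correlate every pair of stack layers over the sampled cells."""
    if len(sample) == 0:
        raise ValueError("empty cell sample")
    if len(stack) < 2:
        raise ValueError("need at least 2 layers to correlate")
    X = stack.values_at(sample.cells)
    return _corr_from_matrix(X, stack.codes, method)


def prune_collinear(
    corr: CorrelationMatrix,
    threshold: float = 0.75,
    priority: dict[str, float] | None = None,
) -> list[str]:
    """Greedy pruning until every retained pair has ``|r| < threshold``.

    While any pair violates the threshold, the member with the lower
    priority score is dropped (ties: larger mean ``|r|`` against the
    remaining variables goes first, then later input order).  With no
    priority given, input order is the priority (earlier = higher).
    Re-running on the output is the identity, and the result is
    deterministic.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    codes = list(corr.codes)
    k = len(codes)
    if priority is None:
        prio = {c: float(k - i) for i, c in enumerate(codes)}
    else:
        prio = {c: float(priority.get(c, -np.inf)) for c in codes}
    absr = np.abs(corr.r)
    alive = dict.fromkeys(codes, True)
    idx = {c: i for i, c in enumerate(codes)}

    def violations() -> list[tuple[str, str]]:
        live = [c for c in codes if alive[c]]
        return [
            (a, b)
            for i, a in enumerate(live)
            for b in live[i + 1:]
            if absr[idx[a], idx[b]] >= threshold
        ]

    dropped: dict[str, tuple[str, str]] = {}
    while True:
        viol = violations()
        if not viol:
            break
        live = [c for c in codes if alive[c]]

        def drop_key(c: str) -> tuple[float, float, float]:
            others = [o for o in live if o != c]
            mean_r = float(np.mean([absr[idx[c], idx[o]] for o in others])) if others else 0.0
            # lowest priority first; tie -> larger mean |r|; tie -> later input order
            return (prio[c], -mean_r, -idx[c])

        # resolve the strongest collinearity first; this also makes the
        # selected set monotone non-shrinking in the threshold
        pair = max(viol, key=lambda ab: (absr[idx[ab[0]], idx[ab[1]]], -idx[ab[0]], -idx[ab[1]]))
        loser = min(pair, key=drop_key)
        alive[loser] = False
        dropped[loser] = pair
    return [c for c in codes if alive[c]]


class CollinearityPruner(TransformerMixin, BaseEstimator):
    """Drop collinear columns of a layer-value matrix (sklearn transformer).

    Parameters
    ----------
    threshold : float, default 0.75
        Retained pairs must satisfy ``|r| < threshold`` (strict).
    method : {"spearman", "pearson"}, default "spearman"
    priority : dict or None
        Column name -> score; higher-scoring columns survive conflicts.

    Attributes
    ----------
    correlation_ : CorrelationMatrix
    selected_codes_ : list of retained column names
    dropped_codes_ : list of eliminated column names
    """

    def __init__(
        self,
        threshold: float = 0.75,
        method: str = "spearman",
        priority: dict[str, float] | None = None,
    ):
        self.threshold = threshold
        self.method = method
        self.priority = priority

    def fit(self, X, y=None):
        X, codes = self._coerce(X)
        self.correlation_ = _corr_from_matrix(X, codes, self.method)
        self.selected_codes_ = prune_collinear(
            self.correlation_, threshold=self.threshold, priority=self.priority
        )
        self.dropped_codes_ = [c for c in codes if c not in self.selected_codes_]
        self.n_features_in_ = len(codes)
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_codes_")
        if isinstance(X, pd.DataFrame):
            return X[self.selected_codes_]
        X = np.asarray(X, dtype=float)
        keep = [self.correlation_.codes.index(c) for c in self.selected_codes_]
        return X[:, keep]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "selected_codes_")
        return np.asarray(self.selected_codes_, dtype=object)

    @staticmethod
    def _coerce(X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        return X, [f"x{j}" for j in range(X.shape[1])]
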