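"""MaxEnt feature construction.

Environmental variables are expanded into bounded feature transforms —
linear, quadratic, product, hinge, and threshold — each scaled into [0, 1]
over the training background.  Hinge and threshold knots sit at background
quantiles.  At projection time inputs may be clamped to the training range
of each variable so the model never extrapolates beyond conditions it saw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .grid import GridStack
from .occurrences import CellSample

__all__ = ["Feature", "FeatureSet", "build_features", "auto_feature_classes"]

CLASS_CODES = {"L": "linear", "Q": "quadratic", "P": "product", "H": "hinge", "T": "threshold"}


@dataclass(frozen=True)
class Feature:
    """One feature transform of one or two variables.

    kind : linear | quadratic | product | hinge | threshold
    variables : tuple of variable codes (two only for product)
    knot : hinge/threshold location on the raw variable scale
    direction : +1 forward hinge (rises above the knot), -1 reverse
    """

    kind: str
    variables: tuple[str, ...]
    knot: float | None = None
    direction: int = 0

    @property
    def label(self) -> str:
        v = "*".join(self.variables)
        if self.kind == "linear":
            return v
        if self.kind == "quadratic":
            return f"{v}^2"
        if self.kind == "product":
            return v
        if self.kind == "hinge":
            arrow = "fwd" if self.direction > 0 else "rev"
            return f"hinge_{arrow}({v};{self.knot:.6g})"
        return f"thr({v};{self.knot:.6g})"


def auto_feature_classes(n_presence: int) -> set[str]:
    """Default feature classes by presence count (few points, simple model)."""
    if n_presence < 10:
        return {"L"}
    if n_presence < 80:
        return {"L", "Q", "H"}
    return {"L", "Q", "H", "P", "T"}


class FeatureSet:
    """Feature definitions plus the background scaling that bounds them.

    Construct with :meth:`from_background`, then map any raw-variable
    matrix to the feature space with :meth:`transform`.

    Attributes
    ----------
    definitions : list of Feature
    clamp_ranges : dict code -> (min, max) of the training background
    scaling : dict feature index -> (min, max) applied after the raw
        transform so every feature lies in [0, 1] on the background
    """

    def __init__(
        self,
        definitions: list[Feature],
        clamp_ranges: dict[str, tuple[float, float]],
        scaling: list[tuple[float, float]],
        codes: list[str],
    ):
        self.definitions = definitions
        self.clamp_ranges = clamp_ranges
        self.scaling = scaling
        self.codes = codes

    def __len__(self) -> int:
        return len(self.definitions)

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.definitions]

    # -- construction -------------------------------------------------------

    @classmethod
    def from_background(
        cls,
        background: pd.DataFrame | np.ndarray,
        codes: list[str] | None = None,
        classes: set[str] = frozenset({"L", "Q", "H"}),
        hinge_knots: int = 10,
    ) -> "FeatureSet":
        """Define features and their [0, 1] scaling from background values."""
        if isinstance(background, pd.DataFrame):
            codes = [str(c) for c in background.columns]
            B = background.to_numpy(dtype=float)
        else:
            B = np.asarray(background, dtype=float)
            if codes is None:
                codes = [f"x{j}" for j in range(B.shape[1])]
        if not classes:
            raise ValueError("at least one feature class required")
        unknown = set(classes) - set(CLASS_CODES)
        if unknown:
            raise ValueError(f"unknown feature class(es) {sorted(unknown)}")
        if ({"H", "T"} & set(classes)) and hinge_knots < 2:
            raise ValueError("hinge/threshold features need hinge_knots >= 2")
        if not np.all(np.isfinite(B)):
            raise ValueError("background contains non-finite values")

        clamp = {c: (float(B[:, j].min()), float(B[:, j].max())) for j, c in enumerate(codes)}
        usable = [c for c in codes if clamp[c][1] > clamp[c][0]]
        dropped = [c for c in codes if c not in usable]
        if dropped:
            warnings.warn(f"constant variable(s) dropped from features: {dropped}", stacklevel=2)

        defs: list[Feature] = []
        if "L" in classes:
            defs += [Feature("linear", (c,)) for c in usable]
        if "Q" in classes:
            defs += [Feature("quadratic", (c,)) for c in usable]
        if "P" in classes:
            defs += [Feature("product", (a, b)) for a, b in combinations(usable, 2)]
        # interior quantile knots; endpoints excluded so every knot lies
        # strictly inside the variable's training range
        qs = np.linspace(0, 1, hinge_knots + 2)[1:-1]
        for c in usable:
            j = codes.index(c)
            knots = np.unique(np.quantile(B[:, j], qs))
            lo, hi = clamp[c]
            knots = knots[(knots > lo) & (knots < hi)]
            if "H" in classes:
                for k in knots:
                    defs.append(Feature("hinge", (c,), knot=float(k), direction=+1))
                    defs.append(Feature("hinge", (c,), knot=float(k), direction=-1))
            if "T" in classes:
                defs += [Feature("threshold", (c,), knot=float(k)) for k in knots]

        fs = cls(defs, clamp, scaling=[(0.0, 1.0)] * len(defs), codes=codes)
        raw = fs._raw_transform(B)
        scaling = []
        for j in range(raw.shape[1]):
            lo, hi = float(raw[:, j].min()), float(raw[:, j].max())
            scaling.append((lo, hi if hi > lo else lo + 1.0))
        fs.scaling = scaling
        return fs

    # -- evaluation ---------------------------------------------------------

    def _raw_transform(self, X: np.ndarray) -> np.ndarray:
        col = {c: X[:, self.codes.index(c)] for c in self.codes}
        out = np.empty((X.shape[0], len(self.definitions)))
        for j, f in enumerate(self.definitions):
            if f.kind == "linear":
                out[:, j] = col[f.variables[0]]
            elif f.kind == "quadratic":
                out[:, j] = col[f.variables[0]] ** 2
            elif f.kind == "product":
                out[:, j] = col[f.variables[0]] * col[f.variables[1]]
            elif f.kind == "hinge":
                x = col[f.variables[0]]
                lo, hi = self.clamp_ranges[f.variables[0]]
                k = f.knot
                if f.direction > 0:
                    out[:, j] = np.clip((x - k) / (hi - k), 0.0, None)
                else:
                    out[:, j] = np.clip((k - x) / (k - lo), 0.0, None)
            elif f.kind == "threshold":
                out[:, j] = (col[f.variables[0]] > f.knot).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {f.kind!r}")
        return out

    def transform(self, X: pd.DataFrame | np.ndarray, clamp: bool = False) -> np.ndarray:
        """Feature matrix for raw variable values (columns in ``codes`` order)."""
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.codes if c not in X.columns]
            if missing:
                raise ValueError(f"missing variable column(s) {missing}")
            X = X[self.codes].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.codes):
            raise ValueError(f"expected {len(self.codes)} variable columns, got {X.shape}")
        if clamp:
            X = X.copy()
            for j, c in enumerate(self.codes):
                lo, hi = self.clamp_ranges[c]
                X[:, j] = np.clip(X[:, j], lo, hi)
        raw = self._raw_transform(X)
        lo = np.array([s[0] for s in self.scaling])
        hi = np.array([s[1] for s in self.scaling])
        return (raw - lo) / (hi - lo)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "codes": self.codes,
            "definitions": [
                {"kind": f.kind, "variables": list(f.variables), "knot": f.knot,
                 "direction": f.direction}
                for f in self.definitions
            ],
            "clamp_ranges": {c: list(v) for c, v in self.clamp_ranges.items()},
            "scaling": [list(s) for s in self.scaling],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        defs = [
            Feature(e["kind"], tuple(e["variables"]), e["knot"], e["direction"])
            for e in d["definitions"]
        ]
        clamp = {c: (v[0], v[1]) for c, v in d["clamp_ranges"].items()}
        scaling = [(s[0], s[1]) for s in d["scaling"]]
        return cls(defs, clamp, scaling, list(d["codes"]))


def build_features(
    stack: GridStack,
    background: CellSample,
    classes: set[str] = frozenset({"L", "Q", "H"}),
    hinge_knots: int = 10,
) -> FeatureSet:
    """Feature set scaled over the stack values at the background cells."""
    B = stack.values_at(background.cells)
    return FeatureSet.from_background(B, codes=stack.codes, classes=set(classes),
                                      hinge_knots=hinge_knots)
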