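"""Model validation: ROC-AUC, confusion counts, TSS, kappa, MTSS threshold.

Presence-only models are validated against the background sample acting as
pseudo-absences.  AUC is threshold-free; the true skill statistic (TSS =
sensitivity + specificity − 1) and Cohen's kappa are computed at the
threshold that maximises training sensitivity + specificity (MTSS), the
same threshold later used to binarise suitability maps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "roc_auc",
    "confusion_at",
    "tss",
    "kappa",
    "mtss_threshold",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 table: presences scored >= t are TP, background < t are TN."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_presence(self) -> int:
        return self.TP + self.FN

    @property
    def n_background(self) -> int:
        return self.TN + self.FP

    @property
    def sensitivity(self) -> float:
        return self.TP / self.n_presence

    @property
    def specificity(self) -> float:
        return self.TN / self.n_background


def _scores(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("score list must be non-empty")
    return a


def roc_auc(presence_scores, background_scores) -> float:
    """P(presence score > background score) + half the tie probability.

    Computed exactly over all pairs via the rank (Mann-Whitney)
    formulation, so it scales to large samples.
    """
    p, b = _scores(presence_scores), _scores(background_scores)
    ranks = stats.rankdata(np.r_[p, b])  # average ranks handle ties
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2.0
    return float(u / (len(p) * len(b)))


def confusion_at(presence_scores, background_scores, t: float) -> ConfusionCounts:
    """Confusion counts with >= t predicted suitable."""
    p, b = _scores(presence_scores), _scores(background_scores)
    tp = int((p >= t).sum())
    fp = int((b >= t).sum())
    return ConfusionCounts(TP=tp, FN=len(p) - tp, TN=len(b) - fp, FP=fp)


def tss(c: ConfusionCounts) -> float:
    """True skill statistic: sensitivity + specificity − 1, in [−1, 1]."""
    if c.n_presence == 0 or c.n_background == 0:
        raise ValueError("TSS undefined without both presences and background")
    return c.sensitivity + c.specificity - 1.0


def kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa: agreement beyond chance for the 2x2 table."""
    n = c.n_presence + c.n_background
    if n == 0:
        raise ValueError("kappa undefined on an empty table")
    po = (c.TP + c.TN) / n
    pe = ((c.TP + c.FN) * (c.TP + c.FP) + (c.TN + c.FP) * (c.TN + c.FN)) / (n * n)
    if pe == 1.0:
        raise ValueError("kappa undefined when chance agreement is 1")
    return (po - pe) / (1.0 - pe)


def mtss_threshold(presence_scores, background_scores) -> float:
    """Threshold maximising sensitivity + specificity.

    Candidates are the distinct observed scores plus 0; among maximisers
    the smallest is returned, so perfectly separated scores yield the
    minimum presence score.
    """
    p, b = _scores(presence_scores), _scores(background_scores)
    candidates = np.unique(np.r_[0.0, p, b])
    best_t, best_v = 0.0, -np.inf
    for t in candidates:
        c = confusion_at(p, b, float(t))
        v = c.sensitivity + c.specificity
        if v > best_v + 1e-12:
            best_t, best_v = float(t), v
    return best_t


@dataclass
class EvaluationReport:
    """Holdout AUC plus threshold-dependent skill at the MTSS threshold."""

    auc: float
    threshold: float
    tss: float
    kappa: float
    counts: ConfusionCounts
    n_presence: int
    n_background: int
    auc_train: float | None = None

    def as_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)


def evaluate(
    presence_scores,
    background_scores,
    train_presence_scores=None,
) -> EvaluationReport:
    """Full report for one model run.

    AUC compares ``presence_scores`` (typically the 25% holdout) with the
    background.  The MTSS threshold is chosen on the calibration scores
    when ``train_presence_scores`` is given (training
    sensitivity+specificity), otherwise on the scored presences
    themselves; TSS and kappa are evaluated at that threshold on the
    scored presences.
    """
    p, b = _scores(presence_scores), _scores(background_scores)
    thr_presences = (
        _scores(train_presence_scores) if train_presence_scores is not None else p
    )
    t = mtss_threshold(thr_presences, b)
    c = confusion_at(p, b, t)
    report = EvaluationReport(
        auc=roc_auc(p, b),
        threshold=t,
        tss=tss(c),
        kappa=kappa(c),
        counts=c,
        n_presence=len(p),
        n_background=len(b),
    )
    if train_presence_scores is not None:
        report.auc_train = roc_auc(thr_presences, b)
    return report
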