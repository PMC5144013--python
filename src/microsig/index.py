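"""The signature microbiome index and its validation.

The index of a sample is the sum of relative abundances of the taxa in
a signature panel; because the panel is a subset of the composition the
index always lies in [0, 1].  Validation follows the biomarker
playbook: a two-sided Mann-Whitney U comparison between groups, a ROC
curve swept over the observed index values (whose trapezoid AUC equals
U / (n1 * n2) with half-credit for ties), and leave-one-out
cross-validation in which the optimal classification cutoff is re-fit
on each training fold and applied to the held-out sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import RelAbundanceTable
from .screen import SignaturePanel


def compute_index(rel: RelAbundanceTable, panel: SignaturePanel,
                  strict: bool = True) -> pd.Series:
    """Per-sample sum of relative abundances over the panel taxa."""
    if len(panel) == 0:
        raise ValueError("signature panel is empty")
    present = [t for t in panel.taxa if t in rel.fractions.columns]
    missing = [t for t in panel.taxa if t not in rel.fractions.columns]
    if missing:
        if strict:
            raise ValueError(f"panel taxa missing from table: {missing}")
        warnings.warn(f"panel taxa missing from table contribute 0: {missing}")
    values = rel.fractions[present].sum(axis=1) if present \
        else pd.Series(0.0, index=rel.fractions.index)
    return values.rename("index")


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (pairs a > b plus half-ties) and p-value.

    The p-value is exact (full enumeration of the U distribution) when
    n_a * n_b <= 400 and the data are tie-free, otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _binary_labels(labels, positive: str) -> np.ndarray:
    y = np.asarray(pd.Series(labels) == positive)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y


def roc_auc(index, labels, positive: str) -> tuple[pd.DataFrame, float]:
    """ROC curve over the observed index values and its trapezoid AUC.

    Cutoffs sweep the sorted unique values (predict positive when
    index >= cutoff); tied values produce diagonal segments, so the AUC
    equals the normalised Mann-Whitney U including half-credit ties.
    """
    x = np.asarray(index, dtype=float)
    y = _binary_labels(labels, positive)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    cutoffs = np.concatenate([[np.inf], np.unique(x)[::-1]])
    tpr = [(x[y] >= c).sum() / n_pos for c in cutoffs]
    fpr = [(x[~y] >= c).sum() / n_neg for c in cutoffs]
    points = pd.DataFrame({"cutoff": cutoffs, "fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(points["tpr"], points["fpr"]))
    return points, auc


def _candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Increasing cutoff grid: one candidate per distinct decision rule.

    Midpoints between adjacent distinct values, plus an all-positive
    candidate below the minimum and an all-negative candidate above the
    maximum (offset by half the adjacent gap, so the grid is equivariant
    under affine maps of the index).
    """
    d = np.unique(values)
    if d.size == 1:
        return np.array([d[0] - 0.5, d[0] + 0.5])
    mids = (d[:-1] + d[1:]) / 2.0
    low = d[0] - (d[1] - d[0]) / 2.0
    high = d[-1] + (d[-1] - d[-2]) / 2.0
    return np.concatenate([[low], mids, [high]])


def _best_cutoff(values: np.ndarray, y: np.ndarray,
                 objective: str = "accuracy") -> float:
    """Cutoff maximising the training objective; ties -> smallest cutoff."""
    candidates = _candidate_cutoffs(values)
    n_pos, n_neg = y.sum(), (~y).sum()
    best_c, best_score = None, -np.inf
    for c in candidates:  # increasing, so strict > keeps the smallest optimum
        pred = values >= c
        tp = (pred & y).sum()
        tn = (~pred & ~y).sum()
        if objective == "accuracy":
            score = (tp + tn) / y.size
        elif objective == "youden":
            score = tp / n_pos + tn / n_neg - 1.0
        else:
            raise ValueError(f"unknown objective {objective!r}")
        if score > best_score:
            best_score, best_c = score, c
    return float(best_c)


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out cutoff cross-validation outcome."""

    sample_ids: tuple[str, ...]
    cutoffs: np.ndarray          # per-fold training-optimal cutoff
    predictions: np.ndarray      # per-fold predicted positive (bool)
    truth: np.ndarray            # per-fold true positive (bool)
    accuracy: float
    sensitivity: float
    specificity: float


def loo_cutoff_cv(index, labels, positive: str,
                  objective: str = "accuracy") -> LooResult:
    """Hold out each sample, refit the optimal cutoff, classify it.

    The held-out sample is predicted positive when its index is >= the
    training-fold cutoff; overall accuracy, sensitivity (positive class
    recall) and specificity aggregate the per-fold predictions.
    """
    ids = index.index if isinstance(index, pd.Series) else None
    series = pd.Series(np.asarray(index, dtype=float), index=ids)
    x = series.to_numpy()
    y = _binary_labels(labels, positive)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("leave-one-out needs >= 2 samples per class")
    cutoffs = np.empty(x.size)
    preds = np.empty(x.size, dtype=bool)
    for i in range(x.size):
        mask = np.ones(x.size, dtype=bool)
        mask[i] = False
        cutoffs[i] = _best_cutoff(x[mask], y[mask], objective=objective)
        preds[i] = x[i] >= cutoffs[i]
    tp = (preds & y).sum()
    tn = (~preds & ~y).sum()
    return LooResult(
        sample_ids=tuple(str(s) for s in series.index),
        cutoffs=cutoffs, predictions=preds, truth=y,
        accuracy=float((tp + tn) / x.size),
        sensitivity=float(tp / y.sum()),
        specificity=float(tn / (~y).sum()),
    )


@dataclass(frozen=True)
class IndexReport:
    """Everything the index analysis produces for one cohort."""

    index: pd.Series
    positive_group: str
    group_stats: pd.DataFrame    # median and IQR per group
    u_statistic: float
    p_value: float
    roc_points: pd.DataFrame
    auc: float
    loo: LooResult

    def to_dict(self) -> dict:
        return {
            "positive_group": self.positive_group,
            "group_stats": {g: {"median": float(r["median"]), "iqr": float(r["iqr"])}
                            for g, r in self.group_stats.iterrows()},
            "mann_whitney_u": self.u_statistic,
            "mann_whitney_p": self.p_value,
            "auc": self.auc,
            "loo_accuracy": self.loo.accuracy,
            "loo_sensitivity": self.loo.sensitivity,
            "loo_specificity": self.loo.specificity,
        }


def index_report(rel: RelAbundanceTable, panel: SignaturePanel, groups,
                 positive_group: str | None = None, strict: bool = True,
                 objective: str = "accuracy") -> IndexReport:
    """Compute the index and its full validation report.

    The positive class defaults to the panel's enriched group: the ROC
    and LOO ask how well a high index predicts membership in the group
    the signature taxa were gained in.
    """
    if isinstance(groups, pd.DataFrame):
        groups = groups["group"]
    labels = pd.Series(groups).loc[rel.sample_ids]
    positive = positive_group or panel.enriched_group
    if positive not in set(labels):
        raise ValueError(f"positive group {positive!r} absent from metadata")
    values = compute_index(rel, panel, strict=strict)
    stats_rows = {}
    for g in pd.unique(labels):
        v = values[labels == g]
        q1, q3 = np.percentile(v, [25, 75])  # linear-interpolation quantiles
        stats_rows[g] = {"median": float(np.median(v)), "iqr": float(q3 - q1)}
    pos_vals = values[labels == positive]
    neg_vals = values[labels != positive]
    u, p = mann_whitney(pos_vals, neg_vals)
    points, auc = roc_auc(values, labels, positive)
    loo = loo_cutoff_cv(values, labels, positive, objective=objective)
    return IndexReport(index=values, positive_group=positive,
                       group_stats=pd.DataFrame(stats_rows).T,
                       u_statistic=u, p_value=p, roc_points=points, auc=auc,
                       loo=loo)
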