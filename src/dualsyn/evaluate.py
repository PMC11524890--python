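"""Metric panel, cross-validation harness, and all-pairs score matrices.

Regression is summarized by Pearson correlation (PCC), R², MSE and
RMSE; classification by Cohen's kappa, F1, ROC AUC, PR AUC, balanced
accuracy, precision and recall. Cross-validation repeats the 5-fold
loop with fresh seeds and reports per-fold values with the mean and a
normal-approximation 95% confidence interval per metric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm
from sklearn.base import clone, is_classifier

from .data import SplitPlan, SplitStrategy, TripletRecord, make_splits

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    """Per-fold metric values with mean and 95% CI summaries."""

    task: str
    values: dict[str, list[float]] = field(default_factory=dict)

    def add(self, fold_metrics: dict[str, float]) -> None:
        for k, v in fold_metrics.items():
            self.values.setdefault(k, []).append(float(v))

    @property
    def mean(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.values.items()}

    @property
    def ci95(self) -> dict[str, tuple[float, float]]:
        """mean ± 1.96·sd/√n over the fold values."""
        out = {}
        for k, v in self.values.items():
            v = np.asarray(v)
            half = 1.96 * v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
            out[k] = (float(v.mean() - half), float(v.mean() + half))
        return out

    def summary(self) -> pd.DataFrame:
        rows = [
            {"metric": k, "mean": np.mean(v), "ci_low": self.ci95[k][0],
             "ci_high": self.ci95[k][1], "n_folds": len(v)}
            for k, v in self.values.items()
        ]
        return pd.DataFrame(rows)


def _safe_pcc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        warnings.warn("zero-variance input to PCC; reporting 0")
        return 0.0
    return float(stats.pearsonr(y_true, y_pred).statistic)


def compute_metrics(y_true, y_pred, task: str = "regression",
                    y_proba=None) -> dict[str, float]:
    """Standard metric panel for one evaluation set.

    For classification ``y_pred`` holds hard labels and ``y_proba`` the
    positive-class probability (needed for the AUC metrics; they are
    omitted when absent). Binary labels may be strings; the
    lexicographically larger label is treated as positive, matching the
    synergistic-vs-antagonistic convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if task == "regression":
        mse = float(np.mean((y_true - y_pred) ** 2))
        return {
            "pcc": _safe_pcc(y_true.astype(float), y_pred.astype(float)),
            "r2": float(skm.r2_score(y_true, y_pred)),
            "mse": mse,
            "rmse": float(np.sqrt(mse)),
        }
    classes = np.unique(y_true)
    pos = classes[-1]  # np.unique sorts, so the last label is positive
    out = {
        "kappa": float(skm.cohen_kappa_score(y_true, y_pred)),
        "f1": float(skm.f1_score(y_true, y_pred, pos_label=pos)),
        "bacc": float(skm.balanced_accuracy_score(y_true, y_pred)),
        "precision": float(skm.precision_score(y_true, y_pred, pos_label=pos,
                                               zero_division=0)),
        "recall": float(skm.recall_score(y_true, y_pred, pos_label=pos,
                                         zero_division=0)),
    }
    if y_proba is not None and len(classes) == 2:
        y_bin = (y_true == pos).astype(int)
        out["roc_auc"] = float(skm.roc_auc_score(y_bin, y_proba))
        out["pr_auc"] = float(skm.average_precision_score(y_bin, y_proba))
    return out


def _assert_no_leakage(plan: SplitPlan, fold: int, train_mask, test_mask) -> None:
    """Enforce the split strategy's disjointness contract inside the loop."""
    tr = [r for r, m in zip(plan.records, train_mask) if m]
    te = [r for r, m in zip(plan.records, test_mask) if m]
    if plan.strategy is SplitStrategy.PAIR_OUT:
        assert not ({r.pair for r in tr} & {r.pair for r in te})
    elif plan.strategy is SplitStrategy.CELL_OUT:
        assert not ({r.cell for r in tr} & {r.cell for r in te})
    elif plan.strategy is SplitStrategy.DRUG_OUT:
        held_out = {d for d, f in plan.drug_folds.items() if f == fold}
        tr_drugs = {d for r in tr for d in (r.drug1, r.drug2)}
        assert not (held_out & tr_drugs)


def cross_validate(estimator, records: list[TripletRecord],
                   strategy: SplitStrategy | str = SplitStrategy.RANDOM,
                   repeats: int = 10, n_folds: int = 5,
                   seeds: list[int] | None = None) -> MetricReport:
    """Repeated stratified-by-strategy k-fold cross-validation.

    A fresh clone of ``estimator`` is fitted per fold; per-fold metrics
    are pooled into a :class:`MetricReport` (repeats × n_folds values
    per metric). ``seeds`` overrides the per-repeat split seeds.
    """
    seeds = list(range(repeats)) if seeds is None else list(seeds)
    task = "classification" if is_classifier(estimator) else "regression"
    report = MetricReport(task=task)
    X_all = pd.DataFrame([(r.drug1, r.drug2, r.cell) for r in records],
                         columns=["drug1", "drug2", "cell"])
    y_all = (np.array([r.label for r in records]) if task == "classification"
             else np.array([r.score for r in records]))
    for seed in seeds[:repeats]:
        plan = make_splits(records, strategy, n_folds=n_folds, seed=seed)
        for fold, train_mask, test_mask in plan.iter_folds():
            _assert_no_leakage(plan, fold, train_mask, test_mask)
            est = clone(estimator)
            est.set_params(seed=seed * n_folds + fold)
            est.fit(X_all[train_mask], y_all[train_mask])
            X_te, y_te = X_all[test_mask], y_all[test_mask]
            pred = est.predict(X_te)
            if task == "classification":
                proba = est.predict_proba(X_te)[:, np.argmax(est.classes_)]
                report.add(compute_metrics(y_te, pred, task, y_proba=proba))
            else:
                report.add(compute_metrics(y_te, pred, task))
    return report


def predict_matrix(estimator, pairs: list[tuple[str, str]], cells: list[str],
                   batch_cells: int = 8) -> pd.DataFrame:
    """Dense pairs × cells prediction matrix.

    Every entry is the symmetrized triplet prediction; rows are labeled
    ``"drug1+drug2"`` and columns by cell id. Predictions stream over
    blocks of cells so memory stays bounded for large panels.
    """
    labels = [f"{a}+{b}" for a, b in pairs]
    out = np.empty((len(pairs), len(cells)))
    for lo in range(0, len(cells), batch_cells):
        block = cells[lo:lo + batch_cells]
        X = pd.DataFrame(
            [(a, b, c) for a, b in pairs for c in block],
            columns=["drug1", "drug2", "cell"],
        )
        pred = estimator.predict(X)
        out[:, lo:lo + len(block)] = np.asarray(pred).reshape(len(pairs), len(block))
    return pd.DataFrame(out, index=labels, columns=cells)


def synergistic_ratio(matrix: pd.DataFrame, pos_thr: float = 10.0) -> pd.Series:
    """Per-pair fraction of cell lines predicted above the synergy threshold."""
    return (matrix > pos_thr).mean(axis=1)
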