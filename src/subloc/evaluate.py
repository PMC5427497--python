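"""Classifier evaluation: confusion matrices, Cohen's kappa, and
stratified bootstrap confidence intervals.

Precision/recall uncertainty is quantified by resampling the test cells
with replacement *within each true class*, so every bootstrap replicate
preserves the original class counts; the 2.5th and 97.5th percentiles of
the per-replicate statistics form the 95% confidence interval (plain
percentile method).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class EvalReport:
    """Confusion matrix (rows = true, columns = predicted) and summary
    statistics, with optional per-class bootstrap CIs."""

    class_order: tuple[str, ...]
    confusion: np.ndarray
    accuracy: float
    kappa: float
    per_class: pd.DataFrame  # precision, recall (+ CI bounds when computed)
    n_boot: int = 0

    def confusion_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.class_order, columns=self.class_order)


def confusion_matrix(
    true_labels: Sequence[str], pred_labels: Sequence[str], class_order: Sequence[str]
) -> np.ndarray:
    lut = {c: i for i, c in enumerate(class_order)}
    K = len(class_order)
    cm = np.zeros((K, K), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        cm[lut[t], lut[p]] += 1
    return cm


def cohens_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement: ``(p_o - p_e) / (1 - p_e)`` with the
    expected agreement from the row/column marginals."""
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def confusion_and_metrics(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    class_order: Sequence[str],
) -> EvalReport:
    """Accuracy, Cohen's kappa, and per-class precision/recall.

    Precision is column-wise, recall row-wise on the confusion matrix. A
    class absent from the truth has undefined recall (reported as NaN, not
    zero); a class never predicted has undefined precision.
    """
    true_labels, pred_labels = list(true_labels), list(pred_labels)
    if len(true_labels) == 0:
        raise ValueError("empty label vectors")
    if len(true_labels) != len(pred_labels):
        raise ValueError("label vectors differ in length")
    extra = (set(true_labels) | set(pred_labels)) - set(class_order)
    if extra:
        raise ValueError(f"labels outside class_order: {sorted(extra)}")
    cm = confusion_matrix(true_labels, pred_labels, class_order)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    diag = np.diag(cm).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, diag / support, np.nan)
        precision = np.where(predicted > 0, diag / predicted, np.nan)
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "support": support},
        index=list(class_order),
    )
    return EvalReport(
        class_order=tuple(class_order),
        confusion=cm,
        accuracy=float(diag.sum() / cm.sum()),
        kappa=cohens_kappa(cm),
        per_class=per_class,
    )


def stratified_bootstrap_ci(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    class_order: Sequence[str],
    n_boot: int = 20000,
    level: float = 0.95,
    seed: int = 0,
    return_replicates: bool = False,
):
    """95% bootstrap CIs for per-class precision and recall.

    Complete (true, predicted) pairs are resampled with replacement within
    each true class, so the class-label counts of every replicate equal the
    original counts exactly. Precision replicates in which a class receives
    zero predictions contribute a missing value and are dropped before the
    percentiles. A class with zero support gets a missing CI.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    true_arr = np.asarray(true_labels)
    lut = {c: i for i, c in enumerate(class_order)}
    pred_idx = np.array([lut[p] for p in pred_labels])
    K = len(class_order)

    # per-replicate predicted-class counts per true class
    diag_counts = np.zeros((n_boot, K))
    col_counts = np.zeros((n_boot, K))
    class_counts = np.zeros((n_boot, K), dtype=int)  # resampled true-class sizes
    support = np.zeros(K, dtype=int)
    for k, cls in enumerate(class_order):
        members = pred_idx[true_arr == cls]
        support[k] = len(members)
        if support[k] == 0:
            continue
        # chunk over replicates to bound memory
        chunk = max(1, int(2_000_000 // max(support[k], 1)))
        for start in range(0, n_boot, chunk):
            stop = min(start + chunk, n_boot)
            draws = members[rng.integers(0, support[k], size=(stop - start, support[k]))]
            rows_n = stop - start
            flat = draws + K * np.arange(rows_n)[:, None]
            counts = np.bincount(flat.ravel(), minlength=rows_n * K).reshape(rows_n, K)
            col_counts[start:stop] += counts
            diag_counts[start:stop, k] = counts[:, k]
            class_counts[start:stop, k] = counts.sum(axis=1)

    alpha = (1.0 - level) / 2.0
    rows = []
    rec_reps = np.full((n_boot, K), np.nan)
    prec_reps = np.full((n_boot, K), np.nan)
    for k, cls in enumerate(class_order):
        if support[k] == 0:
            rows.append(dict(precision_lo=np.nan, precision_hi=np.nan,
                             recall_lo=np.nan, recall_hi=np.nan))
            continue
        rec = diag_counts[:, k] / support[k]
        rec_reps[:, k] = rec
        denom = col_counts[:, k]
        prec = np.where(denom > 0, diag_counts[:, k] / np.maximum(denom, 1), np.nan)
        prec_reps[:, k] = prec
        prec_valid = prec[~np.isnan(prec)]
        rows.append(dict(
            precision_lo=float(np.percentile(prec_valid, 100 * alpha)) if len(prec_valid) else np.nan,
            precision_hi=float(np.percentile(prec_valid, 100 * (1 - alpha))) if len(prec_valid) else np.nan,
            recall_lo=float(np.percentile(rec, 100 * alpha)),
            recall_hi=float(np.percentile(rec, 100 * (1 - alpha))),
        ))
    ci = pd.DataFrame(rows, index=list(class_order))
    if return_replicates:
        return ci, dict(recall=rec_reps, precision=prec_reps, support=support,
                        class_counts=class_counts)
    return ci


def evaluate(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    class_order: Sequence[str],
    n_boot: int = 20000,
    seed: int = 0,
) -> EvalReport:
    """Full report: metrics plus stratified bootstrap CIs."""
    report = confusion_and_metrics(true_labels, pred_labels, class_order)
    ci = stratified_bootstrap_ci(true_labels, pred_labels, class_order, n_boot=n_boot, seed=seed)
    report.per_class = report.per_class.join(ci)
    report.n_boot = n_boot
    return report


@dataclass
class ProteinReport:
    accuracy_all: float
    correct_all: int
    total_all: int
    accuracy_filtered: float
    correct_filtered: int
    total_filtered: int
    min_cells: int


def protein_level_report(
    protein_calls: Mapping[str, str],
    true_protein_labels: Mapping[str, str],
    n_cells_per_protein: Mapping[str, int],
    min_cells: int = 10,
) -> ProteinReport:
    """Protein-level accuracy with and without the minimum-cell filter.

    Counts are reported as correct/total fractions both over all called
    proteins and over the subset with at least ``min_cells`` cells.
    """
    unknown = set(protein_calls) - set(true_protein_labels)
    if unknown:
        raise ValueError(f"called proteins missing from truth: {sorted(unknown)[:5]}")
    pids = list(protein_calls)
    correct = np.array([protein_calls[p] == true_protein_labels[p] for p in pids])
    keep = np.array([n_cells_per_protein.get(p, 0) >= min_cells for p in pids])
    total_f = int(keep.sum())
    return ProteinReport(
        accuracy_all=float(correct.mean()) if len(pids) else float("nan"),
        correct_all=int(correct.sum()),
        total_all=len(pids),
        accuracy_filtered=float(correct[keep].mean()) if total_f else float("nan"),
        correct_filtered=int(correct[keep].sum()),
        total_filtered=total_f,
        min_cells=min_cells,
    )
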