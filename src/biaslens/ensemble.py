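"""Exhaustive ensemble enumeration and best-ensemble selection.

An ensemble prediction is the unweighted arithmetic mean of its members'
softmax rows — every member contributes equally.  Given n candidate
models, all 2^n - 1 nonempty subsets are scored on cached per-model
validation probability tables (re-inference is unnecessary because the
classifier contract is pure), and the best subset is chosen by maximal
validation accuracy, breaking ties by fewest members and then by
lexicographically smallest member-id tuple.  Test metrics, when
supplied, are reporting-only and never influence selection.

The lexicographic third-level tie-break is this package's addition: with
thousands of subsets, equal-accuracy equal-size ties do occur, and a
deterministic rule is preferred over picking one at random.
"""
from __future__ import annotations

import itertools
import json
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .contracts import ClassifierContract, SplitMetrics


@dataclass
class EnsembleRecord:
    member_ids: tuple[str, ...]
    size: int
    val_metrics: SplitMetrics
    test_metrics: SplitMetrics | None = None

    def __post_init__(self) -> None:
        if self.size != len(self.member_ids) or self.size < 1:
            raise ValueError("size must equal the number of member ids (>= 1)")
        if len(set(self.member_ids)) != self.size:
            raise ValueError("member ids must be unique")


class EnsembleClassifier(ClassifierContract):
    """Simple-average ensemble satisfying the black-box contract only."""

    def __init__(self, members: list[ClassifierContract]):
        if not members:
            raise ValueError("an ensemble needs at least one member")
        n_classes = {m.n_classes for m in members}
        if len(n_classes) != 1:
            raise ValueError("ensemble members disagree on n_classes")
        self.members = list(members)
        self.n_classes = n_classes.pop()

    def predict(self, images: np.ndarray) -> np.ndarray:
        return ensemble_predict(self, images)


def ensemble_predict(ensemble: EnsembleClassifier,
                     images: np.ndarray) -> np.ndarray:
    """Unweighted mean of member probability rows; rows still sum to 1."""
    preds = [m.predict(images) for m in ensemble.members]
    return np.mean(preds, axis=0)


def _fast_metrics(probs: np.ndarray, labels: np.ndarray,
                  ranks: np.ndarray | None = None) -> SplitMetrics:
    """Vectorized accuracy / binary F1 / rank AUC for the enumeration loop.

    Identical to ``contracts.metrics_from_probabilities`` (asserted in
    tests) but avoids per-call scikit-learn overhead across 2^n subsets.
    """
    p1 = probs[:, 1]
    pred = (probs[:, 1] >= probs[:, 0]).astype(int)
    acc = float((pred == labels).mean())
    tp = float(np.sum((pred == 1) & (labels == 1)))
    fp = float(np.sum((pred == 1) & (labels == 0)))
    fn = float(np.sum((pred == 0) & (labels == 1)))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        auc = None
    else:
        r = rankdata(p1) if ranks is None else ranks
        auc = float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))
    return SplitMetrics(accuracy=acc, f1=f1, auc=auc)


def enumerate_ensembles(model_ids: list[str],
                        cached_val_predictions: np.ndarray,
                        labels: np.ndarray,
                        cached_test_predictions: np.ndarray | None = None,
                        test_labels: np.ndarray | None = None
                        ) -> list[EnsembleRecord]:
    """Score every nonempty subset of models: 2^n - 1 records.

    ``cached_val_predictions`` is a ``(n_models, n_images, 2)`` table of
    per-model softmax rows; each subset's metrics come from averaging the
    cached rows, which the purity contract makes bit-identical to
    re-inference.  Test tables, if given, fill ``test_metrics`` for
    reporting only.
    """
    preds = np.asarray(cached_val_predictions, dtype=float)
    labels = np.asarray(labels)
    if len(model_ids) < 1:
        raise ValueError("need at least one model")
    if preds.shape[0] != len(model_ids) or preds.shape[1] != len(labels):
        raise ValueError("prediction table shape does not match "
                         "model ids / labels")
    records = []
    indices = range(len(model_ids))
    for r in range(1, len(model_ids) + 1):
        for subset in itertools.combinations(indices, r):
            avg = preds[list(subset)].mean(axis=0)
            val = _fast_metrics(avg, labels)
            test = None
            if cached_test_predictions is not None:
                tavg = np.asarray(cached_test_predictions)[list(subset)].mean(axis=0)
                test = _fast_metrics(tavg, np.asarray(test_labels))
            records.append(EnsembleRecord(
                member_ids=tuple(model_ids[i] for i in subset),
                size=r, val_metrics=val, test_metrics=test))
    return records


def select_best(records: list[EnsembleRecord]) -> EnsembleRecord:
    """Maximal validation accuracy; ties -> fewest members -> smallest ids.

    Selection never consults test metrics.
    """
    if not records:
        raise ValueError("no ensemble records to select from")
    return min(records, key=lambda rec: (-rec.val_metrics.accuracy,
                                         rec.size, rec.member_ids))


def records_to_frame(records: list[EnsembleRecord]) -> pd.DataFrame:
    """Tabular view of all records ('+'-joined member ids), e.g. for the
    accuracy-vs-size scatter."""
    rows = []
    for rec in records:
        row = {"members": "+".join(rec.member_ids), "size": rec.size,
               "val_accuracy": rec.val_metrics.accuracy,
               "val_f1": rec.val_metrics.f1, "val_auc": rec.val_metrics.auc}
        if rec.test_metrics is not None:
            row.update({"test_accuracy": rec.test_metrics.accuracy,
                        "test_f1": rec.test_metrics.f1,
                        "test_auc": rec.test_metrics.auc})
        rows.append(row)
    return pd.DataFrame(rows)


def run_ensemble_search(prob_csv: str | pathlib.Path,
                        label_csv: str | pathlib.Path,
                        out_dir: str | pathlib.Path) -> EnsembleRecord:
    """File-level driver: CSV of per-model validation probabilities
    (rows = images, one column per model id, values = class-1
    probability) plus a label CSV -> records CSV + selected-record JSON.
    """
    probs = pd.read_csv(prob_csv)
    labels = pd.read_csv(label_csv)["label"].to_numpy()
    ids = list(probs.columns)
    p1 = probs.to_numpy().T                      # (n_models, n_images)
    table = np.stack([1.0 - p1, p1], axis=2)
    records = enumerate_ensembles(ids, table, labels)
    best = select_best(records)
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(out / "ensemble_records.csv", index=False)
    (out / "best_ensemble.json").write_text(json.dumps({
        "member_ids": list(best.member_ids), "size": best.size,
        "val_metrics": best.val_metrics.as_dict()}, indent=2))
    return best
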