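"""Supervised barcode classification and its evaluation metrics.

A per-experiment classifier is trained on cytological profiles from
single-clone control wells (at least 200 labeled cells per class), using a
stratified 70/30 train/validation split and a boosted-tree model with a
fixed budget of boosting stages (default 50).  Performance is reported per
barcode as the false detection rate (per predicted class: fraction of calls
that belong to another clone) and the miss rate (per true class: fraction of
a clone's cells not called as it), plus macro-averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import train_test_split

MIN_CELLS_PER_CLASS = 200
DEFAULT_SPLIT = 0.7
DEFAULT_BUDGET = 50


@dataclass
class ConfusionSummary:
    """Confusion matrix (true x predicted counts) with per-barcode rates."""

    matrix: pd.DataFrame
    fdr: pd.Series  # per predicted class; NaN if the class was never predicted
    miss: pd.Series  # per true class; NaN if the class has no true examples
    macro_fdr: float
    macro_miss: float


@dataclass
class BarcodeModel:
    """A fitted per-experiment barcode classifier with its training metadata."""

    estimator: HistGradientBoostingClassifier
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    n_per_class: dict[str, int]
    split: float
    budget: int
    seed: int
    confidence_floor: float = 0.0  # 5th pct of validation confidence


def confusion_metrics(true_labels, predicted_labels) -> ConfusionSummary:
    """Per-barcode FDR and miss rate from paired label vectors.

    FDR(class c) = FP / (FP + TP) over cells *predicted* as c; miss(c) =
    FN / (FN + TP) over cells *truly* c.  Macro averages ignore undefined
    (NaN) entries.  Macro miss equals 1 - macro recall by construction.
    """
    true = pd.Series(list(true_labels), dtype=object)
    pred = pd.Series(list(predicted_labels), dtype=object)
    if len(true) != len(pred):
        raise ValueError("label vectors must have equal length")
    if len(true) == 0:
        raise ValueError("empty label vectors")
    classes = sorted(set(true) | set(pred))
    matrix = pd.crosstab(true, pred).reindex(
        index=classes, columns=classes, fill_value=0
    )
    matrix.index.name = "true"
    matrix.columns.name = "predicted"
    tp = pd.Series(np.diag(matrix), index=classes, dtype=float)
    predicted_totals = matrix.sum(axis=0).astype(float)
    true_totals = matrix.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = (predicted_totals - tp) / predicted_totals
        miss = (true_totals - tp) / true_totals
    fdr[predicted_totals == 0] = np.nan
    miss[true_totals == 0] = np.nan
    return ConfusionSummary(
        matrix=matrix,
        fdr=fdr.rename("fdr"),
        miss=miss.rename("miss"),
        macro_fdr=float(fdr.mean(skipna=True)),
        macro_miss=float(miss.mean(skipna=True)),
    )


def train_barcode_classifier(
    features: pd.DataFrame,
    labels,
    split: float = DEFAULT_SPLIT,
    budget: int = DEFAULT_BUDGET,
    seed: int = 0,
    min_cells: int = MIN_CELLS_PER_CLASS,
) -> tuple[BarcodeModel, ConfusionSummary]:
    """Train on single-clone control cells; evaluate on the held-out split.

    Every class must contribute at least ``min_cells`` cells; the split is
    stratified with ``split`` (default 70%) used for training.
    """
    labels = pd.Series(list(labels), index=features.index, dtype=object)
    counts = labels.value_counts()
    short = counts[counts < min_cells]
    if len(short):
        raise ValueError(
            "classes under the %d-cell training minimum: %s"
            % (min_cells, ", ".join(f"{c} ({n})" for c, n in short.items()))
        )
    x_train, x_val, y_train, y_val = train_test_split(
        features,
        labels,
        train_size=split,
        stratify=labels,
        random_state=seed,
    )
    estimator = HistGradientBoostingClassifier(max_iter=budget, random_state=seed)
    estimator.fit(x_train.to_numpy(dtype=float), y_train.to_numpy())
    proba = estimator.predict_proba(x_val.to_numpy(dtype=float))
    y_pred = estimator.classes_[np.argmax(proba, axis=1)]
    summary = confusion_metrics(y_val, y_pred)
    model = BarcodeModel(
        estimator=estimator,
        classes=tuple(estimator.classes_),
        feature_names=tuple(features.columns),
        n_per_class=counts.to_dict(),
        split=split,
        budget=budget,
        seed=seed,
        confidence_floor=float(np.percentile(proba.max(axis=1), 5)),
    )
    return model, summary


def call_barcodes(model: BarcodeModel, features: pd.DataFrame) -> pd.DataFrame:
    """Assign a barcode and a confidence to every cell.

    The feature schema is name-keyed: columns are aligned to the training
    schema regardless of order, and missing columns raise.  Cells whose
    confidence falls below the model's validation floor are flagged
    ``low_confidence`` (e.g. clones absent at training time).
    """
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns: {missing}")
    aligned = features[list(model.feature_names)].to_numpy(dtype=float)
    proba = model.estimator.predict_proba(aligned)
    idx = np.argmax(proba, axis=1)
    return pd.DataFrame(
        {
            "barcode": np.asarray(model.estimator.classes_)[idx],
            "confidence": proba[np.arange(len(idx)), idx],
            "low_confidence": proba[np.arange(len(idx)), idx] < model.confidence_floor,
        },
        index=features.index,
    )
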