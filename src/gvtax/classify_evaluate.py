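"""Prediction and evaluation for the two-level taxonomy classifiers.

A query genome receives an order-level and a family-level call, each with a
class-membership probability (the fraction of forest trees voting for the
class).  Wrong calls empirically concentrate at low probability, so calls
below a cutoff (default 0.5) are flagged low-confidence.  Family classes are
either named families (e.g. ``IM_01``) or, for families with too few
sequenced representatives to learn, order-level aggregate bins (``AF``,
``AG``, ``IM``, ``PM``, ``PV``); non-giant-virus material (Mirusviricota,
jumbo phage, virophage) is the ``Not_GV`` class.

Evaluation follows the standard multiclass classification report:
accuracy = (TP+TN)/(TP+TN+FP+FN), per-class precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R), support-weighted averages, and a
confusion matrix (rows = truth, columns = predicted) optionally normalized
by row sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.metrics import precision_recall_fscore_support

from .io_features import FeatureMatrix
from .training import TrainedClassifier

LOW_CONFIDENCE_CUTOFF = 0.5
DEFAULT_MIN_FAMILY_MEMBERS = 30

#: Order -> aggregate family-bin prefix for rare families.
DEFAULT_ORDER_BINS = {
    "Asfuvirales": "AF",
    "Algavirales": "AG",
    "Imitervirales": "IM",
    "Pimascovirales": "PM",
    "Pandoravirales": "PV",
    "Chitovirales": "CH",
    "Not_GV": "Not_GV",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """One genome's call at one taxonomic level."""

    genome_id: str
    level: str
    predicted_class: str
    probability: float
    probability_vector: dict[str, float]
    low_confidence: bool


@dataclass
class TaxonLabelSet:
    """Per-genome (order, family_class) labels."""

    labels: dict[str, tuple[str, str]]  # genome_id -> (order, family_class)

    def orders(self) -> dict[str, str]:
        return {g: o for g, (o, _) in self.labels.items()}

    def families(self) -> dict[str, str]:
        return {g: f for g, (_, f) in self.labels.items()}

    def level(self, level: str) -> dict[str, str]:
        if level == "order":
            return self.orders()
        if level == "family":
            return self.families()
        raise ValueError(f"level must be 'order' or 'family', got {level!r}")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonLabelSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"genome_id", "order", "family"}
        if not required.issubset(df.columns):
            raise ValueError(f"label table must have columns {sorted(required)}")
        return cls(
            labels={
                r.genome_id: (r.order, r.family) for r in df.itertuples(index=False)
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"genome_id": g, "order": o, "family": f}
                for g, (o, f) in self.labels.items()
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class EvaluationReport:
    """Accuracy, per-class metrics and confusion matrices for one level."""

    accuracy: float
    per_class: pd.DataFrame  # index=class; precision, recall, f1, support
    weighted: dict[str, float]  # precision, recall, f1
    confusion: pd.DataFrame  # raw counts, rows=truth, cols=predicted
    confusion_normalized: pd.DataFrame  # rows normalized by class size

    @property
    def misclassification_percent(self) -> float:
        return 100.0 * (1.0 - self.accuracy)

    def to_table(self, decimals: int = 2) -> pd.DataFrame:
        """Classification-report table (rounded), one row per class plus
        accuracy and weighted-average rows."""
        tbl = self.per_class.round(decimals)
        tbl.loc["Accuracy"] = ["", "", round(self.accuracy, decimals), int(self.per_class["support"].sum())]
        tbl.loc["Weighted avg"] = [
            round(self.weighted["precision"], decimals),
            round(self.weighted["recall"], decimals),
            round(self.weighted["f1"], decimals),
            int(self.per_class["support"].sum()),
        ]
        return tbl


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _align_features(model: TrainedClassifier, features: FeatureMatrix) -> FeatureMatrix:
    missing = [f for f in model.feature_names if f not in features.feature_names]
    extra = [f for f in features.feature_names if f not in model.feature_names]
    if missing:
        raise ValueError(
            f"query matrix is missing model feature(s): {missing[:10]}"
            + (f"; extra feature(s): {extra[:10]}" if extra else "")
        )
    if extra:
        warnings.warn(
            f"dropping {len(extra)} feature(s) unknown to the model", stacklevel=3
        )
    return features.subset_features(model.feature_names)


def predict(
    model: TrainedClassifier,
    features: FeatureMatrix,
    low_confidence_cutoff: float = LOW_CONFIDENCE_CUTOFF,
) -> list[PredictionResult]:
    """Apply a trained classifier to query feature rows.

    Query columns are aligned to the model's frozen feature order by name;
    a missing feature is an error, never silently imputed.  The reported
    probability is the forest's vote fraction for the winning class; ties
    are broken lexicographically (the class-list order).
    """
    aligned = _align_features(model, features)
    proba = model.model.predict_proba(aligned.to_frame())
    classes = list(model.model.classes_)
    results = []
    for gid, row in zip(aligned.genome_ids, proba):
        best = int(np.argmax(row))  # classes_ is sorted, so ties fall lexicographically
        p = float(row[best])
        results.append(
            PredictionResult(
                genome_id=gid,
                level=model.level,
                predicted_class=str(classes[best]),
                probability=p,
                probability_vector={str(c): float(v) for c, v in zip(classes, row)},
                low_confidence=p < low_confidence_cutoff,
            )
        )
    return results


def predictions_to_frame(results: Sequence[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "level": r.level,
                "predicted_class": r.predicted_class,
                "probability": r.probability,
                "low_confidence": r.low_confidence,
            }
            for r in results
        ]
    )


def order_bin(order: str, order_bins: Mapping[str, str] | None = None) -> str:
    bins = dict(DEFAULT_ORDER_BINS)
    if order_bins:
        bins.update(order_bins)
    if order in bins:
        return bins[order]
    return order[:2].upper()


def flag_level_disagreement(
    order_class: str,
    family_class: str,
    order_bins: Mapping[str, str] | None = None,
) -> bool:
    """True when a family call's order prefix contradicts the order call.

    Family classes carry their order's bin as a prefix (``IM_01`` / ``IM``);
    the two levels are predicted independently, so disagreement is reported,
    not repaired.
    """
    expected = order_bin(order_class, order_bins)
    return not (family_class == expected or family_class.startswith(expected + "_"))


# ---------------------------------------------------------------------------
# Rare-family aggregation
# ---------------------------------------------------------------------------

def aggregate_rare_families(
    labels: TaxonLabelSet,
    min_members: int = DEFAULT_MIN_FAMILY_MEMBERS,
    order_bins: Mapping[str, str] | None = None,
) -> TaxonLabelSet:
    """Relabel families with < ``min_members`` genomes to their order's bin.

    Families too small to learn a boundary for are collapsed into an
    order-level aggregate class (e.g. three Imitervirales families of a
    handful of genomes each all become ``IM``); families at or above the
    threshold keep their name.
    """
    counts = pd.Series([f for _, f in labels.labels.values()]).value_counts()
    out = {}
    for gid, (order, family) in labels.labels.items():
        if counts[family] < min_members:
            out[gid] = (order, order_bin(order, order_bins))
        else:
            out[gid] = (order, family)
    return TaxonLabelSet(labels=out)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from confusion counts.

    Zero denominators yield 0 by convention (a class that is never predicted
    has precision 0; one with no true members has recall 0).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, f1_from_precision_recall(precision, recall)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate(
    predictions: Sequence[PredictionResult] | Mapping[str, str],
    truth: Mapping[str, str] | TaxonLabelSet,
    level: str | None = None,
) -> EvaluationReport:
    """Compare predictions to truth labels: accuracy, per-class P/R/F1, confusion.

    ``predictions`` is either a list of :class:`PredictionResult` or a plain
    genome_id -> class mapping.  Every prediction must have a truth label.
    The normalized confusion matrix divides each row by its class size, so
    diagonal entries are per-class recall.
    """
    if isinstance(truth, TaxonLabelSet):
        if level is None:
            raise ValueError("level required when truth is a TaxonLabelSet")
        truth = truth.level(level)
    if isinstance(predictions, Mapping):
        pred_map = dict(predictions)
    else:
        pred_map = {r.genome_id: r.predicted_class for r in predictions}

    missing = [g for g in pred_map if g not in truth]
    if missing:
        raise ValueError(f"predictions without truth labels: {missing[:10]}")

    gids = list(pred_map)
    y_true = np.asarray([truth[g] for g in gids])
    y_pred = np.asarray([pred_map[g] for g in gids])
    classes = sorted(set(y_true) | set(y_pred))

    accuracy = float(np.mean(y_true == y_pred))
    precision, recall, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support.astype(int),
        },
        index=classes,
    )
    w = support / support.sum()
    weighted = {
        "precision": float(np.sum(precision * w)),
        "recall": float(np.sum(recall * w)),
        "f1": float(np.sum(f1 * w)),
    }
    cm = _sk_confusion_matrix(y_true, y_pred, labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, cm / row_sums, 0.0)
    confusion_normalized = pd.DataFrame(norm, index=classes, columns=classes)
    return EvaluationReport(
        accuracy=accuracy,
        per_class=per_class,
        weighted=weighted,
        confusion=confusion,
        confusion_normalized=confusion_normalized,
    )
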