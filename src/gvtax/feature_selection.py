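"""Feature screening and reduction for the GVOG presence/absence classifiers.

Profile-HMM searches against thousands of protein-family models dominate the
cost of classifying a new genome, so the feature set is reduced in stages:

1. *Prevalence screening*: keep GVOGs found in at least a minimum fraction
   (default 25%) of the genomes of an order, so only broadly represented
   families enter training.
2. *RFE curves*: recursive feature elimination (dropping the
   lowest-impurity-importance features) scored by cross-validation at a
   ladder of feature-set sizes, to locate the accuracy plateau.
3. *Collinearity clustering*: GVOG presence patterns are strongly correlated
   within lineages; permuting one of two correlated features barely moves
   accuracy, masking their importance.  Features are therefore grouped by
   hierarchical clustering (Ward linkage on 1 - Spearman rho) and one
   representative per cluster is kept before permutation testing.
4. *Importance ranking*: permutation importance on a held-out set, and
   impurity importance (MDI) from the fitted forest, each yielding a final
   top-k feature set.  GC content is always retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_is_fitted

from .io_features import FeatureMatrix

DEFAULT_MIN_PREVALENCE = 0.25
#: Default final feature-set sizes, at the cross-validation accuracy plateau.
DEFAULT_FINAL_K = {"order": 150, "family": 200}
#: Fraction of remaining features eliminated per RFE step.
DEFAULT_RFE_STEP = 0.1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImportanceRanking:
    """Per-feature importance (mean, sd) under one method."""

    method: str  # "permutation" | "impurity"
    importances: dict[str, tuple[float, float]]

    def ranked(self) -> list[str]:
        """Feature names by decreasing mean importance; ties broken lexicographically."""
        return sorted(self.importances, key=lambda f: (-self.importances[f][0], f))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"feature": f, "mean_importance": m, "sd_importance": s}
            for f, (m, s) in self.importances.items()
        ]
        return pd.DataFrame(rows).sort_values(
            ["mean_importance", "feature"], ascending=[False, True], ignore_index=True
        )


@dataclass
class FeatureClusterSet:
    """A partition of feature names into correlation clusters, one representative each."""

    clusters: list[list[str]]
    representatives: list[str]
    linkage_method: str
    distance_threshold: float

    def __post_init__(self) -> None:
        flat = [f for c in self.clusters for f in c]
        if len(flat) != len(set(flat)):
            raise ValueError("clusters overlap")
        if len(self.representatives) != len(self.clusters):
            raise ValueError("need exactly one representative per cluster")

    @property
    def features(self) -> set[str]:
        return {f for c in self.clusters for f in c}


# ---------------------------------------------------------------------------
# Prevalence screening
# ---------------------------------------------------------------------------

def prevalence_table(
    matrix: FeatureMatrix, orders: Mapping[str, str]
) -> pd.DataFrame:
    """Per-(GVOG, order) prevalence: fraction of the order's genomes with presence."""
    missing = [g for g in matrix.genome_ids if g not in orders]
    if missing:
        raise ValueError(f"genomes without an order label: {missing[:10]}")
    df = matrix.to_frame().drop(columns="gc_content")
    order_series = pd.Series({g: orders[g] for g in matrix.genome_ids})
    counts = order_series.value_counts()
    if (counts == 0).any():
        raise ValueError("order with zero genomes")
    return df.groupby(order_series).mean().T  # GVOG x order


def prevalence_screen(
    matrix: FeatureMatrix,
    orders: Mapping[str, str],
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    mode: str = "any-order",
) -> list[str]:
    """Keep GVOGs found in >= ``min_prevalence`` of the genomes of an order.

    ``mode="any-order"`` keeps a GVOG if its prevalence reaches the threshold
    in at least one order (union); ``"every-order"`` requires it in all
    orders.  GC content is always retained, as the first returned feature.
    """
    if mode not in ("any-order", "every-order"):
        raise ValueError(f"mode must be 'any-order' or 'every-order', got {mode!r}")
    prev = prevalence_table(matrix, orders)
    stat = prev.max(axis=1) if mode == "any-order" else prev.min(axis=1)
    kept = [g for g in prev.index if stat[g] >= min_prevalence]
    return ["gc_content"] + kept


# ---------------------------------------------------------------------------
# Collinearity clustering
# ---------------------------------------------------------------------------

def spearman_cluster(
    matrix: FeatureMatrix,
    distance_threshold: float = 0.5,
    ranking: ImportanceRanking | None = None,
) -> FeatureClusterSet:
    """Group features by hierarchical clustering on Spearman rank correlations.

    Distance between two features is 1 - rho; a constant column has rho
    defined as 0 against every other column.  The dendrogram (Ward linkage)
    is cut at ``distance_threshold``; each cluster's representative is its
    highest-ranked feature when a ``ranking`` is supplied, else the first in
    column order.  A threshold of 0 leaves every feature in its own cluster.
    """
    names = list(matrix.feature_names)
    if len(names) < 2:
        raise ValueError("need at least 2 features to cluster")

    if distance_threshold <= 0:
        clusters = [[n] for n in names]
    else:
        X = matrix.values
        # Spearman rho as Pearson correlation of column ranks; this stays
        # well-defined elementwise when some columns are constant (scipy's
        # spearmanr degenerates to a scalar NaN in that case).
        ranks = np.apply_along_axis(rankdata, 0, X)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(ranks, rowvar=False)
        rho = np.asarray(rho, dtype=float)
        rho[np.isnan(rho)] = 0.0  # constant columns: undefined rank correlation -> 0
        np.fill_diagonal(rho, 1.0)
        dist = 1.0 - rho
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="ward")
        assignments = fcluster(Z, t=distance_threshold, criterion="distance")
        by_cluster: dict[int, list[str]] = {}
        for name, c in zip(names, assignments):
            by_cluster.setdefault(int(c), []).append(name)
        clusters = [by_cluster[c] for c in sorted(by_cluster)]

    if ranking is not None:
        order = {f: i for i, f in enumerate(ranking.ranked())}
        reps = [min(c, key=lambda f: (order.get(f, len(order)), f)) for c in clusters]
    else:
        col = {f: i for i, f in enumerate(names)}
        reps = [min(c, key=lambda f: col[f]) for c in clusters]
    return FeatureClusterSet(
        clusters=clusters,
        representatives=reps,
        linkage_method="ward",
        distance_threshold=distance_threshold,
    )


# ---------------------------------------------------------------------------
# RFE accuracy curve
# ---------------------------------------------------------------------------

def default_forest(seed: int | None = 0, n_estimators: int = 100, **kw) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, **kw
    )


def rfe_curve(
    matrix: FeatureMatrix,
    labels: Sequence[str],
    sizes: Sequence[int],
    cv_folds: int = 10,
    seed: int = 0,
    estimator: RandomForestClassifier | None = None,
    step: float = DEFAULT_RFE_STEP,
) -> list[tuple[int, float, float]]:
    """Cross-validated accuracy of the best feature subset at each size.

    For each requested size, recursive feature elimination repeatedly drops
    the lowest-impurity-importance features (10% of the remainder per step)
    down to that size; the surviving subset is scored by stratified k-fold
    cross-validation.  Returns (n_features, mean accuracy, sd) per size.
    """
    sizes = list(sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("feature-set sizes must be >= 1")
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    n_total = len(matrix.feature_names)
    if any(s > n_total for s in sizes):
        raise ValueError(f"sizes must be <= {n_total} total features")

    est = estimator if estimator is not None else default_forest(seed)
    X = matrix.to_frame()
    y = np.asarray(labels)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    out = []
    for size in sizes:
        if size == n_total:
            cols = list(X.columns)
        else:
            selector = RFE(clone(est), n_features_to_select=size, step=step)
            selector.fit(X, y)
            cols = [c for c, keep in zip(X.columns, selector.support_) if keep]
        scores = cross_val_score(clone(est), X[cols], y, cv=cv, scoring="accuracy")
        out.append((size, float(scores.mean()), float(scores.std())))
    return out


# ---------------------------------------------------------------------------
# Importance measures
# ---------------------------------------------------------------------------

def permutation_importance_ranking(
    model,
    heldout: FeatureMatrix,
    heldout_labels: Sequence[str],
    n_repeats: int = 10,
    seed: int = 0,
    pre_cluster: FeatureClusterSet | None = None,
) -> ImportanceRanking:
    """Mean decrease in held-out accuracy when one feature column is shuffled.

    With ``pre_cluster`` given, only cluster representatives are permuted and
    reported — the remedy for correlated features sharing (and so hiding)
    their importance.
    """
    check_is_fitted(model)
    model_features = list(getattr(model, "feature_names_in_", []))
    if model_features and model_features != list(heldout.feature_names):
        raise ValueError(
            "feature mismatch between model and matrix; model expects "
            f"{model_features[:5]}..., matrix has {heldout.feature_names[:5]}..."
        )
    X = heldout.to_frame()
    y = np.asarray(heldout_labels)
    result = _sk_permutation_importance(
        model, X, y, scoring="accuracy", n_repeats=n_repeats, random_state=seed,
        n_jobs=1,
    )
    keep = (
        set(pre_cluster.representatives)
        if pre_cluster is not None
        else set(heldout.feature_names)
    )
    importances = {
        f: (float(m), float(s))
        for f, m, s in zip(
            heldout.feature_names, result.importances_mean, result.importances_std
        )
        if f in keep
    }
    return ImportanceRanking(method="permutation", importances=importances)


def impurity_importance(model, feature_names: Sequence[str] | None = None) -> ImportanceRanking:
    """Mean decrease in impurity per feature, normalised to sum to 1.

    The sd is taken across the forest's trees.
    """
    check_is_fitted(model)
    names = (
        list(feature_names)
        if feature_names is not None
        else list(getattr(model, "feature_names_in_", []))
    )
    means = np.asarray(model.feature_importances_, dtype=float)
    if not names:
        names = [f"f{i}" for i in range(means.size)]
    if len(names) != means.size:
        raise ValueError("feature_names length does not match the fitted model")
    per_tree = np.array([t.feature_importances_ for t in model.estimators_])
    sds = per_tree.std(axis=0)
    return ImportanceRanking(
        method="impurity",
        importances={f: (float(m), float(s)) for f, m, s in zip(names, means, sds)},
    )


def select_final_features(ranking: ImportanceRanking, k: int) -> list[str]:
    """Top-k features by mean importance; ties lexicographic; GC always kept."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(ranking.importances)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} ranked features")
    ranked = ranking.ranked()
    if "gc_content" in ranking.importances:
        rest = [f for f in ranked if f != "gc_content"]
        selected = ["gc_content"] + rest[: k - 1]
    else:
        selected = ranked[:k]
    return selected
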