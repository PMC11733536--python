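"""TF-fingerprint classification of neuron clusters by progenitor domain.

A small panel of telencephalon patterning transcription factors (FOXG1, the
dorsal markers PAX6/EMX1/EMX2/TBR1/EOMES, and the ventral markers
GSX2/NKX2-1/LHX6/DLX1/2/5/6) yields two features per TF per cluster: the mean
log-normalized expression, min-max scaled to [0, 1] within each dataset, and
the detection rate, which is already a proportion. A linear-margin (SVM)
classifier over these features predicts a cluster's progenitor domain of
origin (MGE-derived, CGE/LGE-derived, or excitatory) and is evaluated by
class-stratified k-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import LinearSVC

from .sc_core import ClusterProfile

logger = logging.getLogger(__name__)

__all__ = [
    "TFPanel",
    "DEFAULT_PANEL",
    "FingerprintFeatures",
    "CVReport",
    "build_features",
    "train_classifier",
    "cross_validate",
]

DEFAULT_PANEL = (
    "FOXG1", "PAX6", "EMX1", "EMX2", "TBR1", "EOMES",
    "GSX2", "NKX2-1", "LHX6", "DLX1", "DLX2", "DLX5", "DLX6",
)

DEFAULT_HYPER_GRID = {
    "estimator__C": [0.01, 0.1, 1, 10],
    "estimator__loss": ["hinge", "squared_hinge"],
}


@dataclass
class TFPanel:
    tf_list: tuple[str, ...] = DEFAULT_PANEL

    def __post_init__(self):
        if not self.tf_list:
            raise ValueError("empty TF panel")
        if len(set(self.tf_list)) != len(self.tf_list):
            raise ValueError("duplicate TFs in panel")


@dataclass
class FingerprintFeatures:
    """Clusters x (2 * |panel|) feature matrix with per-cluster metadata.

    Columns are ``<TF>__mean`` (min-max scaled within dataset) and
    ``<TF>__det`` (detection rate); all values lie in [0, 1].
    """

    features: pd.DataFrame  # clusters x features
    meta: pd.DataFrame  # per cluster: dataset, class

    def __post_init__(self):
        x = self.features.to_numpy()
        if x.size and (x.min() < -1e-12 or x.max() > 1 + 1e-12):
            raise ValueError("fingerprint features must lie in [0, 1]")

    @property
    def classes(self) -> pd.Series:
        return self.meta["class"]


@dataclass
class CVReport:
    """Per-fold, per-class precision and recall of the cross-validated
    fingerprint classifier, with the fold assignment of every cluster."""

    metrics: pd.DataFrame  # columns: fold, class, precision, recall
    fold_of: pd.Series  # cluster -> fold
    hyperparameters: list  # chosen per fold

    def median_recall_per_class(self) -> pd.Series:
        """Median across folds of per-class recall."""
        return self.metrics.groupby("class")["recall"].median()

    def pooled_metrics(self) -> pd.DataFrame:
        """Mean across folds, per class (the alternative aggregation)."""
        return self.metrics.groupby("class")[["precision", "recall"]].mean()


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.zeros_like(col, dtype=float)
    return (col - lo) / (hi - lo)


def build_features(
    profiles: dict[str, ClusterProfile],
    panel: TFPanel | None = None,
    class_of: dict | None = None,
) -> FingerprintFeatures:
    """Build the two-feature-per-TF representation of clusters.

    ``profiles`` maps dataset id -> :class:`ClusterProfile`; ``class_of`` maps
    cluster id -> class label (clusters without a label are excluded). Mean
    expression is min-max scaled per TF *within each dataset*, since datasets
    need not share comparable expression ranges; detection rate passes through
    unscaled. Panel TFs absent from a dataset yield zero features (warned).
    """
    panel = panel or TFPanel()
    class_of = class_of or {}
    rows, meta = [], []
    for ds, prof in profiles.items():
        keep = [cl for cl in prof.clusters if class_of.get(cl) is not None]
        if not keep:
            continue
        mean_block = np.zeros((len(keep), len(panel.tf_list)))
        det_block = np.zeros((len(keep), len(panel.tf_list)))
        for j, tf in enumerate(panel.tf_list):
            if tf not in prof.mean_expr.columns:
                logger.warning("dataset %s lacks panel TF %s; features set to 0", ds, tf)
                continue
            mean_block[:, j] = _minmax(prof.mean_expr.loc[keep, tf].to_numpy())
            det_block[:, j] = prof.detection_rate.loc[keep, tf].to_numpy()
        rows.append(np.hstack([mean_block, det_block]))
        for cl in keep:
            meta.append({"cluster": cl, "dataset": ds, "class": class_of[cl]})
    if not rows:
        raise ValueError("no cluster has a valid class label")
    meta = pd.DataFrame(meta).set_index("cluster")
    cols = [f"{tf}__mean" for tf in panel.tf_list] + [f"{tf}__det" for tf in panel.tf_list]
    feats = pd.DataFrame(np.vstack(rows), index=meta.index, columns=cols)
    return FingerprintFeatures(features=feats, meta=meta)


def _make_svm(seed: int | None = 0):
    return OneVsRestClassifier(LinearSVC(random_state=seed, max_iter=20_000, dual=True))


def train_classifier(
    feat: FingerprintFeatures,
    hyper_grid: dict | None = None,
    seed: int = 0,
    inner_cv: int = 3,
):
    """Fit a one-vs-rest linear SVM on the fingerprint features, choosing the
    regularization strength and loss by inner cross-validated accuracy."""
    y = feat.classes
    if y.nunique() < 2:
        raise ValueError("need at least two classes to train")
    if (y.value_counts() < 2).any():
        raise ValueError("need at least two clusters per class")
    grid = hyper_grid or DEFAULT_HYPER_GRID
    cv = StratifiedKFold(
        n_splits=min(inner_cv, int(y.value_counts().min())),
        shuffle=True, random_state=seed,
    )
    search = GridSearchCV(_make_svm(seed), grid, cv=cv, scoring="accuracy")
    search.fit(feat.features.to_numpy(), y.to_numpy())
    return search.best_estimator_


def stratified_folds(classes: pd.Series, k: int, seed: int = 0) -> pd.Series:
    """Class-stratified fold assignment: per class, seeded shuffle then
    round-robin, so each class is balanced across folds."""
    counts = classes.value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise ValueError(
            f"classes {list(small.index)} have fewer than k={k} clusters; use a smaller k"
        )
    rng = np.random.default_rng(seed)
    fold = pd.Series(-1, index=classes.index, dtype=int)
    for cls in sorted(classes.unique()):
        members = classes.index[classes == cls].to_numpy()
        members = members[rng.permutation(len(members))]
        for i, m in enumerate(members):
            fold[m] = i % k
    return fold


def cross_validate(
    feat: FingerprintFeatures,
    k: int = 4,
    seed: int = 0,
    hyper_grid: dict | None = None,
) -> CVReport:
    """Class-stratified k-fold cross-validation of the fingerprint classifier.

    Per fold, hyperparameters are re-selected on the training clusters and
    precision/recall are computed across held-out clusters within each class.
    """
    y = feat.classes
    fold_of = stratified_folds(y, k, seed)
    labels = sorted(y.unique())
    records, chosen = [], []
    X = feat.features
    for f in range(k):
        test_idx = fold_of.index[fold_of == f]
        train_idx = fold_of.index[fold_of != f]
        sub = FingerprintFeatures(X.loc[train_idx], feat.meta.loc[train_idx])
        model = train_classifier(sub, hyper_grid=hyper_grid, seed=seed)
        chosen.append(model.get_params()["estimator__C"])
        pred = model.predict(X.loc[test_idx].to_numpy())
        truth = y.loc[test_idx].to_numpy()
        prec = precision_score(truth, pred, labels=labels, average=None, zero_division=0)
        rec = recall_score(truth, pred, labels=labels, average=None, zero_division=0)
        for cls, p, r in zip(labels, prec, rec):
            records.append({"fold": f, "class": cls, "precision": p, "recall": r})
    return CVReport(
        metrics=pd.DataFrame(records), fold_of=fold_of, hyperparameters=chosen
    )
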