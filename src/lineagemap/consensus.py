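"""Reference-based consensus cell-type annotation.

A reference atlas is filtered (cell types under a floor removed) and
subsampled (cap per type), predictors are trained on the gene space shared
between reference and query, per-cell labels from every method are aggregated
through an ontology to broad labels, and a consensus is assigned when at
least two methods agree (unique plurality with support >= 2; ties give "no
consensus"). For high-resolution annotation, cells called neurons against a
developmental reference are re-annotated against an adult reference, and
cells landing in non-neuronal categories on the second pass — labels
discrepant between the two references — are set to "no consensus".

Two predictors ship built-in (Spearman-correlation argmax and a per-cell
linear SVM); external tools plug in through the same ``fit``/``predict``
interface or as precomputed label tables.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC

from .sc_core import CellMatrix, ClusterProfile, NormalizedMatrix, cluster_profiles, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "Reference",
    "VoteResult",
    "NO_CONSENSUS",
    "UNASSIGNED",
    "prepare_reference",
    "correlation_classify",
    "CorrelationClassifier",
    "SVMClassifier",
    "vote",
    "two_step_annotate",
]

NO_CONSENSUS = "no consensus"
UNASSIGNED = "unassigned"


@dataclass
class Reference:
    """Prepared training reference: subsampled cells, their fine labels,
    per-type mean profiles, the fine->broad ontology and the broad->category
    (neuron / glia / other) map."""

    matrix: CellMatrix
    labels: pd.Series  # per retained cell, fine type
    profiles: ClusterProfile  # per fine type
    ontology: dict  # fine -> broad
    category: dict = field(default_factory=dict)  # broad -> neuron/glia/other


@dataclass
class VoteResult:
    """Per-cell labels from each method (broad, post-ontology) and the
    consensus call."""

    method_labels: pd.DataFrame  # cells x methods, broad labels
    consensus: pd.Series  # per cell


def prepare_reference(
    m: CellMatrix,
    type_of: dict | pd.Series,
    ontology: dict,
    category: dict | None = None,
    min_cells: int = 100,
    max_cells: int = 500,
    seed: int = 0,
) -> Reference:
    """Filter and subsample a labeled atlas into a training reference.

    Cell types with fewer than ``min_cells`` cells are removed; each
    remaining type is subsampled without replacement to at most ``max_cells``
    (seeded). Every fine label must have an ontology image.
    """
    labels = pd.Series({c: type_of[c] for c in m.cells})
    missing = sorted(set(labels.unique()) - set(ontology))
    if missing:
        raise KeyError(f"fine labels without ontology mapping: {missing}")
    rng = np.random.default_rng(seed)
    keep_cells: list = []
    for t, members in labels.groupby(labels).groups.items():
        members = pd.Index(members)
        if len(members) < min_cells:
            logger.info("cell type %s has %d cells (< %d); removed", t, len(members), min_cells)
            continue
        if len(members) > max_cells:
            sel = rng.choice(len(members), size=max_cells, replace=False)
            members = members[np.sort(sel)]
        keep_cells.extend(members)
    if not keep_cells:
        raise ValueError(f"no cell type has at least {min_cells} cells")
    sub = m.subset_cells(keep_cells)
    sub_labels = labels.loc[keep_cells]
    nm = normalize(sub)
    profiles = cluster_profiles(nm, sub, sub_labels, min_cells=1)
    return Reference(matrix=sub, labels=sub_labels, profiles=profiles,
                     ontology=dict(ontology), category=dict(category or {}))


def _shared_genes(query: NormalizedMatrix, ref: Reference) -> pd.Index:
    """Training gene space: genes detected in both reference and query."""
    q_detected = query.genes[np.asarray((query.values > 0).sum(axis=1)).ravel() > 0]
    r_detected = ref.matrix.genes[
        np.asarray((ref.matrix.counts > 0).sum(axis=1)).ravel() > 0
    ]
    shared = q_detected.intersection(r_detected)
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared between query and reference")
    return shared


class CorrelationClassifier:
    """Argmax Spearman correlation against per-type mean reference profiles.

    Ties are broken by the first type in reference order (logged); cells with
    zero expression variance over the shared genes are labeled "unassigned".
    """

    name = "correlation"

    def __init__(self):
        self._profiles = None
        self._types = None
        self._genes = None

    def fit(self, ref: Reference, shared: pd.Index):
        self._genes = shared
        self._types = list(ref.profiles.clusters)
        self._profiles = ref.profiles.mean_expr[shared].to_numpy()  # types x genes
        return self

    def predict(self, query: NormalizedMatrix) -> pd.Series:
        labels, _ = self.predict_with_correlation(query)
        return labels

    def predict_with_correlation(self, query: NormalizedMatrix):
        q = query.to_frame().loc[self._genes].to_numpy().T  # cells x genes
        ref_ranks = stats.rankdata(self._profiles, axis=1)
        ref_ranks = ref_ranks - ref_ranks.mean(axis=1, keepdims=True)
        ref_norm = np.linalg.norm(ref_ranks, axis=1)
        labels, corrs = [], []
        n_ties = 0
        for row in q:
            if np.ptp(row) == 0:
                labels.append(UNASSIGNED)
                corrs.append(np.nan)
                continue
            r = stats.rankdata(row)
            r = r - r.mean()
            denom = np.linalg.norm(r) * ref_norm
            with np.errstate(invalid="ignore"):
                rho = (ref_ranks @ r) / denom
            rho = np.where(np.isfinite(rho), rho, -np.inf)
            best = float(np.max(rho))
            hits = np.flatnonzero(rho == best)
            if len(hits) > 1:
                n_ties += 1
            labels.append(self._types[hits[0]])
            corrs.append(best)
        if n_ties:
            logger.info("%d cells had tied best correlations; first reference type used", n_ties)
        idx = query.cells
        return pd.Series(labels, index=idx), pd.Series(corrs, index=idx)


class SVMClassifier:
    """Per-cell linear SVM trained on the subsampled reference cells."""

    name = "svm"

    def __init__(self, C: float = 1.0, seed: int = 0):
        self._model = LinearSVC(C=C, random_state=seed, max_iter=20_000)
        self._genes = None

    def fit(self, ref: Reference, shared: pd.Index):
        self._genes = shared
        nm = normalize(ref.matrix)
        X = nm.to_frame().loc[shared].to_numpy().T
        self._model.fit(X, ref.labels.to_numpy())
        return self

    def predict(self, query: NormalizedMatrix) -> pd.Series:
        X = query.to_frame().loc[self._genes].to_numpy().T
        return pd.Series(self._model.predict(X), index=query.cells)


def correlation_classify(query: NormalizedMatrix, ref: Reference):
    """Convenience wrapper: fit the correlation classifier on the shared gene
    space and return (labels, correlations)."""
    shared = _shared_genes(query, ref)
    clf = CorrelationClassifier().fit(ref, shared)
    return clf.predict_with_correlation(query)


# ---------------------------------------------------------------------------
# Voting


def _aggregate(labels: pd.Series, ontology: dict) -> pd.Series:
    def up(v):
        if v in (NO_CONSENSUS, UNASSIGNED):
            return v
        if v not in ontology:
            raise KeyError(f"label {v!r} has no ontology mapping")
        return ontology[v]

    return labels.map(up)


def vote(
    method_labels: pd.DataFrame,
    ontology: dict,
    min_support: int = 2,
    strict_majority: bool = False,
) -> VoteResult:
    """Consensus over per-cell labels from M >= 2 methods.

    Labels are first aggregated through the ontology to broad labels. The
    consensus is the unique plurality label with support >= ``min_support``
    ("at least two methods agreed"); ties for the plurality, or a maximum
    support below the threshold, give "no consensus". "unassigned" votes are
    excluded from the counts. With ``strict_majority`` the winner must exceed
    M/2 instead.
    """
    if method_labels.shape[1] < 2:
        raise ValueError("need labels from at least two methods")
    broad = method_labels.apply(lambda col: _aggregate(col, ontology))
    m = method_labels.shape[1]
    out = []
    for _, row in broad.iterrows():
        votes = Counter(v for v in row if v not in (UNASSIGNED, NO_CONSENSUS))
        if not votes:
            out.append(NO_CONSENSUS)
            continue
        top = votes.most_common()
        best_label, best_n = top[0]
        tied = sum(1 for _, n in top if n == best_n) > 1
        threshold = (m // 2 + 1) if strict_majority else min_support
        if tied or best_n < threshold:
            out.append(NO_CONSENSUS)
        else:
            out.append(best_label)
    return VoteResult(method_labels=broad,
                      consensus=pd.Series(out, index=method_labels.index))


def two_step_annotate(
    query: NormalizedMatrix,
    ref_dev: Reference,
    ref_adult: Reference,
    methods=None,
    min_support: int = 2,
) -> pd.DataFrame:
    """Two-pass annotation: all cells against the developmental reference,
    then cells called neurons re-annotated against the adult reference.

    Pass-2 consensus labels whose category is not "neuron" (discrepant
    between the references) become "no consensus". Returns a table with the
    pass-1 consensus, pass-2 consensus (NaN for cells not re-run) and the
    final label.
    """
    methods = methods or [CorrelationClassifier(), SVMClassifier()]

    def run_pass(nm: NormalizedMatrix, ref: Reference) -> VoteResult:
        shared = _shared_genes(nm, ref)
        tables = {}
        for meth in methods:
            tables[meth.name] = meth.fit(ref, shared).predict(nm)
        return vote(pd.DataFrame(tables), ref.ontology, min_support=min_support)

    def category_of(label: str, ref: Reference) -> str:
        if label in (NO_CONSENSUS, UNASSIGNED):
            return label
        if label not in ref.category:
            raise KeyError(f"label {label!r} has no category mapping")
        return ref.category[label]

    pass1 = run_pass(query, ref_dev)
    final = pass1.consensus.copy()
    cat1 = pass1.consensus.map(lambda v: category_of(v, ref_dev))
    neuron_cells = cat1.index[cat1 == "neuron"]
    pass2_consensus = pd.Series(np.nan, index=query.cells, dtype=object)
    if len(neuron_cells):
        sub_vals = query.to_frame()[neuron_cells]
        sub_nm = NormalizedMatrix(sub_vals.to_numpy(), query.genes, neuron_cells,
                                  query.scale_factor)
        pass2 = run_pass(sub_nm, ref_adult)
        pass2_consensus.loc[neuron_cells] = pass2.consensus
        for c in neuron_cells:
            lab2 = pass2.consensus[c]
            if lab2 == NO_CONSENSUS:
                final[c] = NO_CONSENSUS
            elif category_of(lab2, ref_adult) == "neuron":
                final[c] = lab2
            else:
                final[c] = NO_CONSENSUS
    return pd.DataFrame({
        "pass1": pass1.consensus,
        "pass2": pass2_consensus,
        "final": final,
    })
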