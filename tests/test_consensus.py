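import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from lineagemap.consensus import (
    NO_CONSENSUS,
    UNASSIGNED,
    CorrelationClassifier,
    Reference,
    SVMClassifier,
    correlation_classify,
    prepare_reference,
    two_step_annotate,
    vote,
    _shared_genes,
)
from lineagemap.sc_core import CellMatrix, ClusterProfile, NormalizedMatrix, normalize


def labeled_matrix(type_sizes: dict, n_genes=50, seed=0):
    rng = np.random.default_rng(seed)
    cells, labels = [], {}
    for t, n in type_sizes.items():
        for i in range(n):
            c = f"{t}_{i}"
            cells.append(c)
            labels[c] = t
    counts = rng.integers(0, 10, size=(n_genes, len(cells)))
    m = CellMatrix(counts, [f"G{i}" for i in range(n_genes)], cells)
    return m, labels


class TestPrepareReference:
    def test_floor_and_cap_boundaries(self):
        m, labels = labeled_matrix({"tiny": 99, "exact": 100, "big": 700})
        onto = {t: t for t in ("tiny", "exact", "big")}
        ref = prepare_reference(m, labels, onto, min_cells=100, max_cells=500, seed=0)
        sizes = ref.labels.value_counts()
        assert "tiny" not in sizes
        assert sizes["exact"] == 100
        assert sizes["big"] == 500

    def test_subsampling_is_seed_reproducible(self):
        m, labels = labeled_matrix({"big": 300})
        onto = {"big": "big"}
        r1 = prepare_reference(m, labels, onto, min_cells=10, max_cells=50, seed=7)
        r2 = prepare_reference(m, labels, onto, min_cells=10, max_cells=50, seed=7)
        assert list(r1.matrix.cells) == list(r2.matrix.cells)

    def test_no_surviving_type_errors(self):
        m, labels = labeled_matrix({"a": 5, "b": 5})
        with pytest.raises(ValueError, match="no cell type"):
            prepare_reference(m, labels, {"a": "a", "b": "b"}, min_cells=100)

    def test_missing_ontology_entry_errors(self):
        m, labels = labeled_matrix({"a": 120})
        with pytest.raises(KeyError, match="ontology"):
            prepare_reference(m, labels, {}, min_cells=100)


def reference_from_profiles(profiles: pd.DataFrame, ontology, category=None):
    """Reference with given per-type mean profiles (types x genes)."""
    # counts: one archetypal cell per type repeated, so SVM is trainable
    reps = 3
    counts = np.repeat(profiles.to_numpy().T, reps, axis=1)
    cells = [f"{t}_{i}" for t in profiles.index for i in range(reps)]
    m = CellMatrix(counts.astype(int), profiles.columns, cells)
    labels = pd.Series({c: c.rsplit("_", 1)[0] for c in cells})
    nm = normalize(m)
    prof = ClusterProfile(
        clusters=pd.Index(profiles.index),
        mean_expr=pd.DataFrame(
            [nm.to_dense()[:, [i * reps]].ravel() for i in range(len(profiles.index))],
            index=profiles.index, columns=profiles.columns,
        ),
        detection_rate=pd.DataFrame(0.5, index=profiles.index, columns=profiles.columns),
        n_cells=pd.Series(reps, index=profiles.index),
    )
    return Reference(matrix=m, labels=labels, profiles=prof,
                     ontology=dict(ontology), category=dict(category or {}))


class TestCorrelationClassifier:
    def setup_method(self):
        genes = [f"G{i}" for i in range(20)]
        profiles = pd.DataFrame(
            [np.arange(20), 20 - np.arange(20.0)], index=["up", "down"], columns=genes
        )
        self.ref = reference_from_profiles(profiles, {"up": "up", "down": "down"})

    def query(self, values):
        arr = np.asarray(values, dtype=float).T
        cells = [f"q{i}" for i in range(arr.shape[1])]
        return NormalizedMatrix(arr, self.ref.matrix.genes, cells, 1e4)

    def test_exact_profile_gives_correlation_one(self):
        labels, corr = correlation_classify(self.query([np.arange(20)]), self.ref)
        assert labels.iloc[0] == "up"
        assert corr.iloc[0] == pytest.approx(1.0)

    def test_rank_reversal_is_anticorrelated(self):
        labels, corr = correlation_classify(self.query([20 - np.arange(20.0)]), self.ref)
        assert labels.iloc[0] == "down"

    def test_constant_cell_unassigned(self, caplog):
        labels, corr = correlation_classify(self.query([np.ones(20)]), self.ref)
        assert labels.iloc[0] == UNASSIGNED
        assert np.isnan(corr.iloc[0])

    def test_synthetic_recovery_with_both_builtins(self):
        from lineagemap.synthetic import LineageSpec, make_reference

        spec = LineageSpec(seed=5, n_clusters_per_class=2, cells_per_cluster=(60, 80))
        ref_m = make_reference(spec)
        query_m = make_reference(spec, seed=9)
        onto = {c: c for c in spec.classes}
        ref = prepare_reference(ref_m, ref_m.cell_meta["class"], onto,
                                min_cells=50, max_cells=150, seed=0)
        qnm = normalize(query_m)
        truth = query_m.cell_meta["class"]
        labels, _ = correlation_classify(qnm, ref)
        assert (labels == truth).mean() >= 0.95
        shared = _shared_genes(qnm, ref)
        svm_labels = SVMClassifier().fit(ref, shared).predict(qnm)
        assert (svm_labels == truth).mean() >= 0.95
        # consensus does not catastrophically degrade on the best method
        v = vote(pd.DataFrame({"corr": labels, "svm": svm_labels}), onto)
        best = max((labels == truth).mean(), (svm_labels == truth).mean())
        assert (v.consensus == truth).mean() >= best - 0.02


def brute_force_vote(votes, min_support=2):
    """Oracle: unique plurality with support >= min_support."""
    counts = Counter(votes)
    if not counts:
        return NO_CONSENSUS
    best = max(counts.values())
    winners = [l for l, c in counts.items() if c == best]
    if len(winners) > 1 or best < min_support:
        return NO_CONSENSUS
    return winners[0]


class TestVote:
    ONTO = {l: l for l in "ABC"}

    def run(self, labels):
        df = pd.DataFrame([labels], index=["cell"],
                          columns=[f"m{i}" for i in range(len(labels))])
        return vote(df, self.ONTO).consensus.iloc[0]

    def test_documented_cases(self):
        assert self.run(["A", "A", "B", "C"]) == "A"
        assert self.run(["A", "A", "B", "B"]) == NO_CONSENSUS
        assert self.run(["A", "B", "C", "A"]) == "A"

    def test_all_distinct_is_no_consensus(self):
        df = pd.DataFrame([["A", "B", "C", "D"]], index=["cell"],
                          columns=list("wxyz"))
        onto = {l: l for l in "ABCD"}
        assert vote(df, onto).consensus.iloc[0] == NO_CONSENSUS

    def test_exhaustive_81_cases_match_oracle(self):
        for assignment in itertools.product("ABC", repeat=4):
            got = self.run(list(assignment))
            assert got == brute_force_vote(assignment), assignment

    def test_method_order_permutation_invariant(self):
        for assignment in itertools.product("ABC", repeat=4):
            base = self.run(list(assignment))
            for perm in itertools.permutations(assignment):
                assert self.run(list(perm)) == base

    def test_unassigned_excluded_from_support(self):
        assert self.run(["A", UNASSIGNED, UNASSIGNED, UNASSIGNED]) == NO_CONSENSUS
        assert self.run(["A", "A", UNASSIGNED, UNASSIGNED]) == "A"

    def test_ontology_aggregation_precedes_voting(self):
        onto = {"fine1": "broad", "fine2": "broad", "other": "other"}
        df = pd.DataFrame([["fine1", "fine2", "other"]], index=["c"],
                          columns=["m1", "m2", "m3"])
        assert vote(df, onto).consensus.iloc[0] == "broad"

    def test_strict_majority_flag(self):
        df = pd.DataFrame([["A", "A", "B", "C"]], index=["c"],
                          columns=list("wxyz"))
        assert vote(df, self.ONTO, strict_majority=True).consensus.iloc[0] == NO_CONSENSUS

    def test_single_method_rejected(self):
        df = pd.DataFrame({"m1": ["A"]}, index=["c"])
        with pytest.raises(ValueError, match="two methods"):
            vote(df, self.ONTO)


class TestTwoStepAnnotate:
    def build_references(self):
        genes = [f"G{i}" for i in range(40)]
        z = np.zeros(40)

        def prof(block):
            v = z.copy()
            v[block[0]:block[1]] = 50.0
            return v

        dev = pd.DataFrame([prof((0, 10)), prof((10, 20))],
                           index=["dev_neuron", "dev_glia"], columns=genes)
        ref_dev = reference_from_profiles(
            dev, {"dev_neuron": "Neuron", "dev_glia": "Glia"},
            {"Neuron": "neuron", "Glia": "glia"},
        )
        adult = pd.DataFrame(
            [prof((0, 10)) + prof((20, 30)), prof((0, 10)) + prof((30, 40))],
            index=["inhib", "astro"], columns=genes,
        )
        ref_adult = reference_from_profiles(
            adult, {"inhib": "Inhibitory", "astro": "Astrocyte"},
            {"Inhibitory": "neuron", "Astrocyte": "glia"},
        )
        return genes, ref_dev, ref_adult

    def query(self, genes, rows, names):
        return NormalizedMatrix(np.asarray(rows, dtype=float).T, pd.Index(genes),
                                pd.Index(names), 1e4)

    def test_two_step_routing(self):
        genes, ref_dev, ref_adult = self.build_references()
        v = np.zeros(40)
        glia_cell = v.copy(); glia_cell[10:20] = 40
        neuron_to_inhib = v.copy(); neuron_to_inhib[0:10] = 40; neuron_to_inhib[20:30] = 30
        neuron_to_glia = v.copy(); neuron_to_glia[0:10] = 40; neuron_to_glia[30:40] = 30
        q = self.query(genes, [glia_cell, neuron_to_inhib, neuron_to_glia],
                       ["c_glia", "c_inhib", "c_discrepant"])
        res = two_step_annotate(q, ref_dev, ref_adult)
        assert res.loc["c_glia", "final"] == "Glia"
        assert pd.isna(res.loc["c_glia", "pass2"])
        assert res.loc["c_inhib", "final"] == "Inhibitory"
        assert res.loc["c_discrepant", "final"] == NO_CONSENSUS
        assert res.loc["c_discrepant", "pass1"] == "Neuron"

    def test_missing_category_errors(self):
        genes, ref_dev, ref_adult = self.build_references()
        ref_dev.category = {}
        v = np.zeros(40); v[0:10] = 40; v[10:20] = 1
        q = self.query(genes, [v], ["c"])
        with pytest.raises(KeyError, match="category"):
            two_step_annotate(q, ref_dev, ref_adult)
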