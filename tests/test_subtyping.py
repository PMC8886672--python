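"""Consensus subtyping: stability, k selection, transfer, refinement."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import morphoctx as m
from morphoctx.subtyping import ConsensusResult

from conftest import planted_contexts


def _exp_survival(labels, hr, seed=0, censor=0.0):
    t, e = m.simulate_survival(
        labels, {1: 0.0, 2: float(np.log(hr))}, 0.1, censor, seed=seed
    )
    return pd.DataFrame({"time": t, "event": e})


class TestConsensusCluster:
    def test_point_masses_perfect_consensus(self):
        X = np.repeat(np.array([[0.0] * 8, [10.0] * 8]), 10, axis=0)
        X += np.random.default_rng(0).normal(0, 1e-6, X.shape)
        res = m.consensus_cluster(X, 2, n_boot=30, seed=0)
        mass = np.repeat([0, 1], 10)
        same = mass[:, None] == mass[None, :]
        assert np.allclose(res.consensus[same], 1.0)
        assert np.allclose(res.consensus[~same], 0.0)

    def test_planted_clusters_recovered(self):
        X, labels = planted_contexts(n_per=50, sep=6.0, seed=1)
        res = m.consensus_cluster(X, 2, n_boot=100, seed=0)
        assert adjusted_rand_score(labels, res.assignments) == 1.0

    def test_matrix_construction_invariants(self):
        X = np.random.default_rng(2).normal(size=(30, 8))
        res = m.consensus_cluster(X, 3, n_boot=40, seed=3)
        assert np.abs(res.consensus - res.consensus.T).max() < 1e-12
        assert np.array_equal(np.diag(res.consensus), np.ones(30))
        assert res.consensus.min() >= 0 and res.consensus.max() <= 1
        assert set(res.assignments) <= {1, 2, 3}

    def test_degenerate_inputs_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError):
            m.consensus_cluster(X, 1, n_boot=5)
        with pytest.raises(ValueError):
            m.consensus_cluster(X, 6, n_boot=5)

    def test_pac_stable_in_bootstrap_count(self):
        X, _ = planted_contexts(n_per=50, sep=6.0, seed=4)
        p100 = m.consensus_cluster(X, 2, n_boot=100, seed=0).pac
        p500 = m.consensus_cluster(X, 2, n_boot=500, seed=0).pac
        assert abs(p100 - p500) < 0.02


class TestComputePac:
    def test_binary_consensus_is_zero(self):
        C = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], float)
        assert m.compute_pac(C) == 0.0

    def test_maximal_ambiguity_is_one(self):
        C = np.full((5, 5), 0.5)
        np.fill_diagonal(C, 1.0)
        assert m.compute_pac(C) == 1.0

    def test_hand_counted_fraction(self):
        # 2 ambiguous of the 6 off-diagonal pairs -> PAC = 1/3
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.5
        C[2, 3] = C[3, 2] = 0.5
        C[0, 2] = C[2, 0] = 1.0
        C[0, 3] = C[3, 0] = 0.95
        C[1, 2] = C[2, 1] = 0.05
        C[1, 3] = C[3, 1] = 0.0
        assert m.compute_pac(C) == pytest.approx(1 / 3)


class TestSelectK:
    def test_recovers_planted_k(self):
        X, _ = planted_contexts(n_per=30, sep=6.0, seed=5)
        results = [m.consensus_cluster(X, k, n_boot=60, seed=k) for k in range(2, 6)]
        k, trace = m.select_k(results)
        assert k == 2
        assert trace.loc[trace["chosen"], "k"].item() == 2

    def test_tie_breaks_to_smallest_k(self):
        fake = [
            ConsensusResult(k=k, consensus=np.eye(4), assignments=np.ones(4, int), pac=0.2)
            for k in (2, 3, 4)
        ]
        assert m.select_k(fake)[0] == 2

    def test_tie_breaks_by_logrank_on_survival(self):
        labels = np.repeat([1, 2], 30)
        surv = _exp_survival(labels, hr=3.0, seed=1)
        good = ConsensusResult(k=2, consensus=np.eye(60), assignments=labels, pac=0.1)
        noise = np.resize([1, 2, 3], 60)
        bad = ConsensusResult(k=3, consensus=np.eye(60), assignments=noise, pac=0.1)
        k, trace = m.select_k([good, bad], survival=surv)
        assert k == 2
        assert trace["logrank_p"].notna().all()

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            m.select_k([])


class TestFinalizeSubtypes:
    def test_duplicate_pairs_centroids(self):
        pts = np.random.default_rng(0).normal(size=(4, 6))
        X = np.repeat(pts, 2, axis=0)
        labels = np.repeat([1, 2, 3, 4], 2)
        model = m.finalize_subtypes(X, 4, labels)
        # numbering may permute; the centroid *set* must match the points
        got = {tuple(np.round(c, 12)) for c in model.centroids}
        want = {tuple(np.round(p, 12)) for p in pts}
        assert got == want

    def test_centroids_are_group_means(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        labels = rng.integers(1, 3, 10)
        while len(set(labels)) < 2:
            labels = rng.integers(1, 3, 10)
        surv = pd.DataFrame({"time": np.arange(10, 0, -1.0), "event": np.ones(10, int)})
        model = m.finalize_subtypes(X, 2, labels, survival=surv)
        for g in (1, 2):
            sel = model.assignments == g
            assert np.allclose(model.centroids[g - 1], X[sel].mean(axis=0))

    def test_worse_survival_group_numbered_last(self):
        X = np.vstack([np.zeros((5, 4)), np.ones((5, 4))])
        labels = np.repeat([1, 2], 5)
        time = np.concatenate([np.full(5, 2.0), np.full(5, 20.0)])  # group 1 dies faster
        surv = pd.DataFrame({"time": time, "event": np.ones(10, int)})
        model = m.finalize_subtypes(X, 2, labels, survival=surv)
        # original group 1 (fast deaths) must become subtype 2
        assert (model.assignments[:5] == 2).all()
        assert (model.assignments[5:] == 1).all()

    def test_size_ordering_without_survival(self):
        X = np.vstack([np.zeros((7, 3)), np.ones((3, 3))])
        labels = np.repeat([2, 1], [7, 3])
        model = m.finalize_subtypes(X, 2, labels)
        assert (model.assignments[:7] == 1).all()  # larger cluster first

    def test_empty_subtype_rejected(self):
        with pytest.raises(ValueError):
            m.finalize_subtypes(np.zeros((4, 2)), 3, np.array([1, 1, 2, 2]))


class TestAssignSubtype:
    def _model(self, centroids):
        k = len(centroids)
        return m.SubtypeModel(
            k=k, centroids=np.asarray(centroids, float),
            assignments=np.arange(1, k + 1),
        )

    def test_centroid_identity(self):
        model = self._model(np.random.default_rng(0).normal(size=(3, 6)))
        label, dist = m.assign_subtype(model.centroids[1], model)
        assert label == 2 and dist[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        model = self._model(rng.normal(size=(3, 8)))
        X = rng.normal(size=(20, 8))
        labels, dists = m.assign_subtype(X, model)
        brute = np.array([
            int(np.argmin([np.linalg.norm(x - c) for c in model.centroids])) + 1
            for x in X
        ])
        assert np.array_equal(labels, brute)
        assert dists.shape == (20, 3)

    def test_exact_tie_goes_low(self):
        model = self._model([[1.0, 0.0], [-1.0, 0.0]])
        label, _ = m.assign_subtype(np.array([0.0, 5.0]), model)
        assert label == 1

    def test_dimension_mismatch_rejected(self):
        model = self._model(np.eye(2))
        with pytest.raises(ValueError):
            m.assign_subtype(np.zeros(5), model)

    def test_self_assignment_on_separated_clusters(self):
        X, labels = planted_contexts(n_per=40, sep=6.0, seed=6)
        model = m.finalize_subtypes(X, 2, labels)
        pred, _ = m.assign_subtype(X, model)
        assert (pred == model.assignments).all()

    def test_transfer_accuracy_on_new_draws(self):
        X, labels = planted_contexts(n_per=40, sep=6.0, seed=7)
        model = m.finalize_subtypes(X, 2, labels)
        Xnew, truth = planted_contexts(n_per=100, sep=6.0, seed=8)
        pred, _ = m.assign_subtype(Xnew, model)
        # model numbering may permute vs generator labels
        acc = max((pred == truth).mean(), (pred == 3 - truth).mean())
        assert acc >= 0.95


class TestRefineSubtypes:
    def test_self_consistency(self):
        X, labels = planted_contexts(n_per=40, sep=6.0, seed=9)
        model = m.finalize_subtypes(X, 2, labels)
        refined, report = m.refine_subtypes(X, model, n_boot=50, seed=0)
        assert report["agreement"] == 1.0
        assert report["chi2_p"] < 1e-10
        assert np.array_equal(refined.assignments, report["transferred"])

    def test_label_permutation_fully_matched(self):
        """Matching undoes any relabelling of identical partitions."""
        X, labels = planted_contexts(n_per=30, sep=10.0, seed=10)
        # train the model with flipped numbering (no survival: size ties broken
        # stably) and check refinement still reports full agreement
        model = m.finalize_subtypes(X, 2, np.where(labels == 1, 2, 1))
        _, report = m.refine_subtypes(X, model, n_boot=50, seed=1)
        assert report["agreement"] == 1.0

    def test_unstructured_cohort_low_agreement(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 8))
        model = m.finalize_subtypes(
            X, 2, np.repeat([1, 2], 50),
        )
        _, report = m.refine_subtypes(X, model, n_boot=40, seed=2)
        assert report["agreement"] < 0.9  # no structure to agree on
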