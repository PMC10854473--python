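import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from cdtl import (BackboneSpec, DecompositionMap, FeatureMatrix, TaskSpec,
                  TrainConfig, ValidationError, decompose, fit_extractor,
                  fit_reduction, make_classification_task, relabel,
                  reassemble, silhouette_by_class)


def _ids(n, prefix="s"):
    return [f"{prefix}{i}:0" for i in range(n)]


class TestReduction:
    def test_rank_two_data_needs_two_components(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 2)) @ rng.normal(size=(2, 10))
        red = fit_reduction(FeatureMatrix(X, _ids(50), ["A"] * 50), 0.99)
        assert red.n_components_ == 2

    def test_full_rank_inverse_reconstructs(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 5))
        fm = FeatureMatrix(X, _ids(20), ["A"] * 20)
        red = fit_reduction(fm, 5)
        assert np.allclose(red.inverse_transform(red.transform(fm)).X, X,
                           atol=1e-8)

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 6)) * np.array([5, 3, 2, 1, 0.5, 0.1])
        red = fit_reduction(FeatureMatrix(X, _ids(200), ["A"] * 200), 6)
        cov = np.cov(X - X.mean(axis=0), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(red.explained_variance_ratio_, eig / eig.sum(),
                           atol=1e-9)

    def test_fit_twice_rejected(self):
        fm = FeatureMatrix(np.eye(4), _ids(4), ["A"] * 4)
        red = fit_reduction(fm, 2)
        with pytest.raises(ValidationError):
            red.fit(fm)

    def test_more_components_than_samples_rejected(self):
        fm = FeatureMatrix(np.eye(3), _ids(3), ["A"] * 3)
        with pytest.raises(ValidationError):
            fit_reduction(fm, 5)


def _toy_features(seed=0, sep=10.0, n_per=20):
    """Two classes, two planted blobs each, in 3D."""
    rng = np.random.default_rng(seed)
    X, labels, truth = [], [], []
    for ci, cls in enumerate(("A", "B")):
        for sub in (0, 1):
            pts = rng.normal(size=(n_per, 3))
            pts[:, 0] += ci * 4 * sep
            pts[:, 1] += sub * sep
            X.append(pts)
            labels += [cls] * n_per
            truth += [sub] * n_per
    X = np.vstack(X)
    ids = _ids(len(X))
    return FeatureMatrix(X, ids, labels), np.array(truth)


class TestDecompose:
    def test_two_classes_k2_gives_four_subclasses(self):
        fm, _ = _toy_features()
        dmap = decompose(fm, 2, seed=0)
        assert sorted(dmap.subclass_of) == ["A#0", "A#1", "B#0", "B#1"]
        assert dmap.k_per_class == {"A": 2, "B": 2}

    def test_k1_is_identity_up_to_suffix(self):
        fm, _ = _toy_features()
        dmap = decompose(fm, 1, seed=0)
        for sid, lbl in zip(fm.sample_ids, fm.labels):
            assert dmap.assignments[sid] == f"{lbl}#0"

    def test_planted_blobs_recovered(self):
        fm, truth = _toy_features(seed=5)
        dmap = decompose(fm, 2, seed=0)
        for cls in ("A", "B"):
            idx = [i for i, l in enumerate(fm.labels) if l == cls]
            got = [dmap.assignments[fm.sample_ids[i]] for i in idx]
            assert adjusted_rand_score(truth[idx], got) >= 0.99

    def test_parent_consistency_invariant(self):
        fm, _ = _toy_features()
        dmap = decompose(fm, 2, seed=3)
        for sid, lbl in zip(fm.sample_ids, fm.labels):
            assert dmap.parent(dmap.assignments[sid]) == lbl

    def test_deterministic_given_seed(self):
        fm, _ = _toy_features()
        d1 = decompose(fm, 2, seed=42)
        d2 = decompose(fm, 2, seed=42)
        assert d1.assignments == d2.assignments

    def test_small_class_falls_back_to_k1(self, caplog):
        X = np.vstack([np.zeros((1, 2)), np.ones((5, 2))])
        fm = FeatureMatrix(X, _ids(6), ["A"] + ["B"] * 5)
        dmap = decompose(fm, 2, seed=0)
        assert dmap.k_per_class["A"] == 1

    def test_small_class_errors_without_fallback(self):
        X = np.vstack([np.zeros((1, 2)), np.ones((5, 2))])
        fm = FeatureMatrix(X, _ids(6), ["A"] + ["B"] * 5)
        with pytest.raises(ValidationError):
            decompose(fm, 2, seed=0, allow_fallback=False)

    def test_json_round_trip(self):
        fm, _ = _toy_features()
        dmap = decompose(fm, 2, seed=1)
        back = DecompositionMap.from_json(dmap.to_json())
        assert back.assignments == dmap.assignments
        assert back.subclass_of == dmap.subclass_of

    def test_recovery_degrades_gracefully_with_separation(self):
        """Mean ARI is monotonically nonincreasing as planted separation
        shrinks (seeded sweep)."""
        seps = [8.0, 4.0, 2.0, 1.0, 0.5]
        mean_ari = []
        for sep in seps:
            aris = []
            for seed in range(3):
                task = make_classification_task(
                    TaskSpec(seed=seed, subcluster_separation=sep,
                             slices_per_subject=3))
                ext = fit_extractor(BackboneSpec(name="deterministic_texture"),
                                    task.slices, TrainConfig())
                fm = ext.transform(task.slices)
                rfm = fit_reduction(fm, 0.95).transform(fm)
                dmap = decompose(rfm, 2, seed=seed)
                truth = task.slice_subclusters()
                for cls in ("A", "B"):
                    idx = [i for i, l in enumerate(rfm.labels) if l == cls]
                    got = [dmap.assignments[rfm.sample_ids[i]] for i in idx]
                    want = [truth[rfm.sample_ids[i]] for i in idx]
                    aris.append(adjusted_rand_score(want, got))
            mean_ari.append(np.mean(aris))
        # allow tiny numerical jitter between adjacent separations
        assert all(mean_ari[i] >= mean_ari[i + 1] - 0.05
                   for i in range(len(seps) - 1))
        assert mean_ari[0] >= 0.99


class TestRelabel:
    def test_feature_matrix_relabels_and_recovers(self):
        fm, _ = _toy_features()
        dmap = decompose(fm, 2, seed=0)
        rl = relabel(fm, dmap)
        assert rl.n_samples == fm.n_samples
        assert [dmap.parent(l) for l in rl.labels] == fm.labels

    def test_unknown_sample_rejected(self):
        fm, _ = _toy_features()
        dmap = decompose(fm, 2, seed=0)
        stranger = FeatureMatrix(np.zeros((1, 3)), ["ghost:0"], ["A"])
        with pytest.raises(ValidationError):
            relabel(stranger, dmap)

    def test_toy_lookup(self):
        fm = FeatureMatrix(np.arange(12).reshape(6, 2), _ids(6),
                           ["A", "A", "A", "B", "B", "B"])
        dmap = decompose(fm, 1, seed=0)
        rl = relabel(fm, dmap)
        assert rl.labels == [dmap.assignments[s] for s in fm.sample_ids]


def _four_subclass_map():
    return DecompositionMap(
        k_per_class={"A": 2, "B": 2},
        subclass_of={"A#0": "A", "A#1": "A", "B#0": "B", "B#1": "B"},
        assignments={}, centroids={}, seed=0)


class TestReassemble:
    def test_hand_computed_scores_agree_case(self):
        dmap = _four_subclass_map()
        scores = np.array([[0.3, 0.4, 0.2, 0.1]])
        labels, ps = reassemble(scores, dmap, "argmax_map")
        assert labels == ["A"]
        labels, ps = reassemble(scores, dmap, "prob_sum")
        assert labels == ["A"]
        assert np.allclose(ps, [[0.7, 0.3]])

    def test_hand_computed_modes_disagree_case(self):
        dmap = _four_subclass_map()
        scores = np.array([[0.35, 0.05, 0.30, 0.30]])
        labels, _ = reassemble(scores, dmap, "argmax_map")
        assert labels == ["A"]
        labels, ps = reassemble(scores, dmap, "prob_sum")
        assert labels == ["B"]
        assert np.allclose(ps, [[0.40, 0.60]])

    def test_hard_labels_map_to_parents(self):
        dmap = _four_subclass_map()
        labels, ps = reassemble(["A#1", "B#0", "A#0"], dmap)
        assert labels == ["A", "B", "A"]
        assert ps is None

    def test_parent_scores_sum_to_one(self):
        dmap = _four_subclass_map()
        rng = np.random.default_rng(0)
        raw = rng.uniform(size=(50, 4))
        scores = raw / raw.sum(axis=1, keepdims=True)
        for mode in ("argmax_map", "prob_sum"):
            _, ps = reassemble(scores, dmap, mode)
            assert np.abs(ps.sum(axis=1) - 1).max() < 1e-9

    def test_unknown_subclass_rejected(self):
        dmap = _four_subclass_map()
        with pytest.raises(ValidationError):
            reassemble(["C#0"], dmap)

    def test_perfect_subclass_predictions_reassemble_perfectly(self):
        fm, _ = _toy_features()
        dmap = decompose(fm, 2, seed=0)
        true_sub = [dmap.assignments[s] for s in fm.sample_ids]
        labels, _ = reassemble(true_sub, dmap)
        assert labels == fm.labels


def _silhouette_oracle(X, labels):
    """Brute-force pairwise-distance silhouette."""
    X = np.asarray(X)
    labels = np.asarray(labels)
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        same = labels == labels[i]
        a = D[i][same & (np.arange(n) != i)].mean()
        b = min(D[i][labels == c].mean() for c in set(labels) if c != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestSilhouette:
    def test_matches_brute_force_oracle(self):
        fm, _ = _toy_features(seed=7, sep=3.0)
        dmap = decompose(fm, 2, seed=0)
        got = silhouette_by_class(fm, dmap)
        for cls in ("A", "B"):
            idx = [i for i, l in enumerate(fm.labels) if l == cls]
            subs = [dmap.assignments[fm.sample_ids[i]] for i in idx]
            assert abs(got[cls] - _silhouette_oracle(fm.X[idx], subs)) < 1e-9

    def test_tends_to_one_with_separation(self):
        prev = 0.0
        for sep in (2.0, 20.0, 400.0):
            fm, _ = _toy_features(seed=1, sep=sep)
            dmap = decompose(fm, 2, seed=0)
            score = min(silhouette_by_class(fm, dmap).values())
            assert score >= prev
            prev = score
        assert prev > 0.98

    def test_single_subclass_reported_undefined(self):
        fm, _ = _toy_features()
        dmap = decompose(fm, {"A": 1, "B": 2}, seed=0)
        got = silhouette_by_class(fm, dmap)
        assert got["A"] is None
        assert got["B"] is not None
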