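"""Feature selection, repeated clustering, certainty and quality indices."""

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from dfcsubtype import cluster_ensemble, forward_select_features, silhouette_index
from dfcsubtype.subtype import _align_to_reference, certainty_from_runs, kmeans_lloyd


def _blobs(rng, n_per=50, gap=10.0, n_noise=0):
    x = rng.standard_normal((2 * n_per, 2 + n_noise))
    x[n_per:, 0] += gap
    labels = np.r_[np.zeros(n_per, dtype=int), np.ones(n_per, dtype=int)]
    return x, labels


class TestSilhouette:
    def test_two_tight_far_pairs(self):
        x = np.array([[0.0, 0], [0.01, 0], [50, 0], [50.01, 0]])
        assert silhouette_index(x, [0, 0, 1, 1]) > 0.99

    def test_null_overlapping_clouds_near_zero(self, rng):
        x = rng.standard_normal((400, 3))
        labels = rng.integers(0, 2, 400)
        assert abs(silhouette_index(x, labels)) < 0.05

    def test_matches_brute_force_per_point(self, rng):
        x = rng.standard_normal((30, 4))
        labels = rng.integers(0, 3, 30)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, 30)
        svals = []
        for i in range(30):
            d = np.linalg.norm(x - x[i], axis=1)
            own = labels == labels[i]
            if own.sum() == 1:
                svals.append(0.0)
                continue
            a = d[own & (np.arange(30) != i)].mean()
            b = min(d[labels == c].mean() for c in np.unique(labels) if c != labels[i])
            svals.append((b - a) / max(a, b))
        # summation order differs between the vectorised path and the
        # per-point oracle, so agreement is to accumulation precision
        assert silhouette_index(x, labels) == pytest.approx(np.mean(svals), abs=1e-9)

    def test_matches_sklearn(self, rng):
        x, labels = _blobs(rng, gap=3.0)
        assert silhouette_index(x, labels) == pytest.approx(
            silhouette_score(x, labels), abs=1e-10
        )

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette_index(rng.standard_normal((10, 2)), np.zeros(10, dtype=int))


class TestKMeans:
    def test_matches_sklearn_on_separated_blobs(self, rng):
        x, planted = _blobs(rng)
        labels, centers = kmeans_lloyd(x, 2, np.random.default_rng(0))
        sk = KMeans(2, n_init=10, random_state=0).fit(x)
        assert adjusted_rand_score(labels, sk.labels_) == 1.0
        assert centers.shape == (2, x.shape[1])

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError):
            kmeans_lloyd(rng.standard_normal((2, 2)), 2, np.random.default_rng(0))


class TestCertainty:
    def test_direct_formula_97_of_100(self):
        runs = np.zeros((100, 3), dtype=int)
        runs[:, 1] = 1  # subject 1 always labelled 1
        runs[:3, 0] = 1  # subject 0: 97 x label 0, 3 x label 1
        certainty, final = certainty_from_runs(runs)
        assert certainty[0] == pytest.approx(0.97)
        assert final[0] == 0
        assert certainty[1] == 1.0 and final[1] == 1

    def test_argmax_tie_breaks_low_label(self):
        runs = np.array([[0, 1], [1, 0]])
        certainty, final = certainty_from_runs(runs)
        assert certainty.tolist() == [0.5, 0.5]
        assert final.tolist() == [0, 0]

    def test_alignment_invariance(self, rng):
        ref = rng.integers(0, 2, 40)
        labels = rng.integers(0, 2, 40)
        aligned = _align_to_reference(labels, ref, 2)
        flipped = _align_to_reference(1 - labels, ref, 2)
        assert np.array_equal(aligned, flipped)


class TestClusterEnsemble:
    def test_perfect_separation(self, rng):
        x, planted = _blobs(rng)
        ens = cluster_ensemble(x, k=2, runs=50, seed=0)
        assert np.all(ens.certainty == 1.0)
        assert adjusted_rand_score(ens.final_labels, planted) == 1.0
        assert ens.mean_stability == 1.0
        assert ens.excluded_subjects == []
        assert ens.silhouette > 0.8
        assert ens.center_instability < 1e-9
        assert ens.labels_per_run.shape == (50, 100)

    def test_low_certainty_subjects_flagged(self, rng):
        x, _ = _blobs(rng, n_per=30, gap=8.0)
        # a point exactly between the clusters flips across runs
        x = np.vstack([x, [[4.0, 0.0]]])
        ens = cluster_ensemble(x, k=2, runs=60, certainty_threshold=0.95, seed=1)
        if ens.certainty[-1] < 0.95:
            assert 60 in ens.excluded_subjects
            assert not ens.retained_mask[60]


class TestForwardSelection:
    def test_single_perfect_feature_always_selected(self, rng):
        labels = np.r_[np.zeros(50), np.ones(50)]
        x = (labels * 6 + rng.standard_normal(100))[:, None]
        sel = forward_select_features(x, runs=50, seed=3)
        assert sel.frequencies[0] == 1.0
        assert sel.informative_features == ["f0"]

    def test_deterministic_given_seed(self, rng):
        x, _ = _blobs(rng, n_per=40, gap=6.0, n_noise=6)
        a = forward_select_features(x, runs=20, seed=9)
        b = forward_select_features(x, runs=20, seed=9)
        assert np.array_equal(a.frequencies, b.frequencies)

    def test_rejects_degenerate_inputs(self, rng):
        with pytest.raises(ValueError):
            forward_select_features(rng.standard_normal((2, 3)), k=2)
        with pytest.raises(ValueError):
            forward_select_features(rng.standard_normal((10, 3)), criterion="nope")

    def test_informative_set_matches_threshold(self, rng):
        x, _ = _blobs(rng, n_per=50, gap=6.0, n_noise=8)
        sel = forward_select_features(x, runs=40, seed=4)
        expected = {sel.feature_names[j] for j in np.flatnonzero(sel.frequencies > 0.8)}
        assert set(sel.informative_features) == expected
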