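"""Decoding unit tests, including brute-force SVM and permutation oracles."""

import itertools

import numpy as np
import pytest

from precon_mvpa.decode import (
    DecodeError, DecodeSpec, SubjectPatterns, cross_set_decode,
    empirical_chance, rank_voxels, searchlight_map, select_voxel_count,
    sphere_indices, svm_decode, svm_predict,
)
from precon_mvpa.ioconfig.volumes import RoiMask


def cube_mask(side=13, voxel_mm=2.0, name="cube"):
    idx = np.array([(i, j, k) for i in range(side)
                    for j in range(side) for k in range(side)])
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return RoiMask(name=name, shape=(side, side, side), affine=affine,
                   indices=idx)


# ---------------------------------------------------------------------------
# voxel ranking
# ---------------------------------------------------------------------------

class TestRankVoxels:
    def test_signal_voxel_ranked_first(self, rng):
        X = rng.standard_normal((6, 5)) * 0.01
        y = np.array([1, 1, 1, -1, -1, -1])
        X[:, 3] += y * 10.0
        assert rank_voxels(X, y)[0] == 3

    def test_hand_computed_two_voxel_t(self):
        """Oracle: explicit pooled-variance t on a 6-exemplar fixture."""
        a = np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 4.0]])
        b = np.array([[0.0, 1.0], [1.0, 0.0], [-1.0, 2.0]])
        X = np.vstack([a, b])
        y = np.array([1, 1, 1, -1, -1, -1])

        ts = []
        for v in range(2):
            va = a[:, v].var(ddof=1)
            vb = b[:, v].var(ddof=1)
            sp = np.sqrt((2 * va + 2 * vb) / 4)
            ts.append((a[:, v].mean() - b[:, v].mean())
                      / (sp * np.sqrt(1 / 3 + 1 / 3)))
        expected = np.argsort(-np.abs(np.asarray(ts)), kind="stable")
        np.testing.assert_array_equal(rank_voxels(X, y), expected)

    def test_equal_t_tie_breaks_to_lower_index(self, rng):
        col = rng.standard_normal(6)
        y = np.array([1, 1, 1, -1, -1, -1])
        X = np.column_stack([col, col, col])
        np.testing.assert_array_equal(rank_voxels(X, y), [0, 1, 2])

    def test_zero_variance_voxel_gets_t_zero(self, rng):
        X = np.column_stack([np.ones(6), rng.standard_normal(6)])
        y = np.array([1, 1, 1, -1, -1, -1])
        assert rank_voxels(X, y)[-1] == 0


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

def hard_margin_oracle(X, y):
    """Enumerate support-vector subsets and solve the KKT system.

    Returns (w, b) of the maximum-margin separator for a separable,
    small problem — independent of any SVM library.
    """
    n = len(y)
    best = None
    for size in range(2, n + 1):
        for subset in itertools.combinations(range(n), size):
            ys = y[list(subset)]
            if len(np.unique(ys)) < 2:
                continue
            # unknowns: alpha_i (i in subset), b
            # equations: sum_i alpha_i y_i = 0 ; for j in subset:
            #   y_j (sum_i alpha_i y_i x_i . x_j + b) = 1
            k = len(subset)
            A = np.zeros((k + 1, k + 1))
            rhs = np.zeros(k + 1)
            A[0, :k] = ys
            for row, j in enumerate(subset, start=1):
                for col, i in enumerate(subset):
                    A[row, col] = y[i] * X[i] @ X[j]
                A[row, k] = 1.0
                rhs[row] = y[j]          # divide constraint by y_j
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            alpha, b = sol[:k], sol[k]
            if np.any(alpha < -1e-9):
                continue
            w = sum(alpha[c] * y[i] * X[i] for c, i in enumerate(subset))
            margins = y * (X @ w + b)
            if np.all(margins >= 1 - 1e-7):
                norm2 = float(w @ w)
                if best is None or norm2 < best[0] - 1e-12:
                    best = (norm2, w, b)
    assert best is not None, "oracle found no feasible separator"
    return best[1], best[2]


class TestSvm:
    def test_train_equals_test_separable_100(self, rng):
        X = np.vstack([rng.standard_normal((4, 3)) + 5,
                       rng.standard_normal((4, 3)) - 5])
        y = np.array([1] * 4 + [-1] * 4)
        assert svm_decode(X, y, X, y) == 100.0

    def test_label_flip_symmetry(self, rng):
        Xtr = rng.standard_normal((6, 4))
        ytr = np.array([1, 1, 1, -1, -1, -1])
        Xte = rng.standard_normal((10, 4))
        yte = np.array([1, -1] * 5)
        acc = svm_decode(Xtr, ytr, Xte, yte)
        flipped = svm_decode(Xtr, ytr, Xte, -yte)
        assert flipped == pytest.approx(100.0 - acc)

    def test_matches_kkt_enumeration_oracle(self):
        """4-point separable fixture: margin and predictions vs. brute force.

        With a wide margin the soft-margin solution at C=1 coincides with
        the hard-margin one (all alphas < C)."""
        X = np.array([[4.0, 4.0], [5.0, 3.0], [-4.0, -3.0], [-5.0, -5.0]])
        y = np.array([1, 1, -1, -1])
        w, b = hard_margin_oracle(X, y)

        from sklearn.svm import SVC
        clf = SVC(kernel="linear", C=1.0).fit(X, y)
        np.testing.assert_allclose(clf.coef_.ravel(), w, atol=1e-6)
        assert clf.intercept_[0] == pytest.approx(b, abs=1e-6)

        test_pts = np.array([[1.0, 1.0], [-1.0, -0.5], [6.0, 2.0]])
        oracle_pred = np.where(test_pts @ w + b >= 0, 1, -1)
        np.testing.assert_array_equal(
            svm_predict(X, y, test_pts), oracle_pred)

    def test_zero_decision_value_predicts_reward_class(self):
        # symmetric training set; test point at the exact boundary
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, -1])
        pred = svm_predict(X, y, np.array([[0.0, 0.0]]))
        assert pred[0] == 1

    def test_single_class_training_rejected(self):
        with pytest.raises(DecodeError):
            svm_predict(np.ones((3, 2)), np.ones(3), np.ones((1, 2)))

    def test_empty_voxel_subset_rejected(self, rng):
        X = rng.standard_normal((4, 3))
        y = np.array([1, 1, -1, -1])
        with pytest.raises(DecodeError):
            svm_decode(X, y, X, y, voxels=np.array([], dtype=int))


# ---------------------------------------------------------------------------
# empirical chance
# ---------------------------------------------------------------------------

class TestEmpiricalChance:
    def test_exact_enumeration_oracle_4_items(self):
        """Oracle: average accuracy over all distinct label arrangements."""
        labels = np.array([1, 1, -1, -1])
        predictions = np.array([1, -1, -1, -1])
        arrangements = sorted(set(itertools.permutations(labels)))
        assert len(arrangements) == 6
        exact = np.mean([np.mean(predictions == np.array(a))
                         for a in arrangements]) * 100
        mc = empirical_chance(predictions, labels, n_perm=40_000, seed=3)
        assert mc == pytest.approx(exact, abs=0.5)

    def test_balanced_labels_expectation_50(self):
        labels = np.array([1] * 8 + [-1] * 8)
        predictions = np.array([1] * 3 + [-1] * 13)   # arbitrary
        chance = empirical_chance(predictions, labels, n_perm=30_000, seed=0)
        assert chance == pytest.approx(50.0, abs=0.5)

    def test_deterministic_in_seed(self):
        labels = np.array([1, 1, -1, -1])
        predictions = np.array([1, 1, 1, -1])
        a = empirical_chance(predictions, labels, 500, seed=7)
        b = empirical_chance(predictions, labels, 500, seed=7)
        assert a == b


# ---------------------------------------------------------------------------
# nested feature-count selection
# ---------------------------------------------------------------------------

def make_cohort(rng, n_subjects=4, n_vox=100, signal_voxels=10,
                adversarial=True):
    """Cohort where the top-ranked voxels generalize but later ones hurt."""
    data = {}
    for s in range(n_subjects):
        ytr = np.array([1, 1, 1, -1, -1, -1])
        yte = np.array([1] * 8 + [-1] * 8)
        Xtr = rng.standard_normal((6, n_vox)) * 0.05
        Xte = rng.standard_normal((16, n_vox)) * 0.05
        Xtr[:, :signal_voxels] += ytr[:, None] * 2.0
        Xte[:, :signal_voxels] += yte[:, None] * 2.0
        if adversarial:
            # mid-ranked voxels: consistent in training, reversed at test
            sl = slice(signal_voxels, signal_voxels + 30)
            Xtr[:, sl] += ytr[:, None] * 1.0
            Xte[:, sl] -= yte[:, None] * 5.0
        data[s] = SubjectPatterns(train_X=Xtr, train_y=ytr,
                                  test_X=Xte, test_y=yte)
    return data


class TestSelectVoxelCount:
    def test_flat_accuracy_returns_step(self, rng):
        data = make_cohort(rng, adversarial=False)
        spec = DecodeSpec(feature_step=20, n_permutations=10)
        # signal lives in the 10 top-ranked voxels; every count includes
        # them, accuracies tie, smallest count wins
        assert select_voxel_count(data, spec, left_out=0) == 20

    def test_adversarial_midrank_voxels_cap_the_count(self, rng):
        data = make_cohort(rng, adversarial=True)
        spec = DecodeSpec(feature_step=20, n_permutations=10)
        assert select_voxel_count(data, spec, left_out=0) == 20

    def test_left_out_subject_never_influences_choice(self, rng):
        data = make_cohort(rng)
        spec = DecodeSpec(feature_step=20, n_permutations=10)
        before = select_voxel_count(data, spec, left_out=2)
        corrupted = dict(data)
        corrupted[2] = SubjectPatterns(
            train_X=rng.standard_normal((6, 100)) * 1e6,
            train_y=data[2].train_y,
            test_X=rng.standard_normal((16, 100)) * 1e6,
            test_y=data[2].test_y)
        after = select_voxel_count(corrupted, spec, left_out=2)
        assert before == after

    def test_step_larger_than_roi_uses_whole_roi(self, rng):
        data = make_cohort(rng, n_vox=30, signal_voxels=5, adversarial=False)
        spec = DecodeSpec(feature_step=40, n_permutations=10)
        assert select_voxel_count(data, spec, left_out=0) == 30


# ---------------------------------------------------------------------------
# cross-cue-set decoding
# ---------------------------------------------------------------------------

class TestCrossSetDecode:
    def _sets(self, rng, shared_axis, n_sets=8, n_vox=60, amp=1.0):
        v = rng.standard_normal(n_vox)
        v /= np.linalg.norm(v)
        train, test = {}, {}
        for s in range(1, n_sets + 1):
            def pats(n_items, labels):
                X = rng.standard_normal((n_items, n_vox)) * 0.8
                if shared_axis:
                    X += amp * np.outer(labels, v)
                else:
                    ident = rng.standard_normal(n_vox)
                    X += np.outer(labels, ident) * 0.0
                return X
            ytr = np.array([1, -1] * 3)
            yte = np.array([1, -1])
            train[s] = (pats(6, ytr), ytr)
            test[s] = (pats(2, yte), yte)
        return train, test

    def test_fold_count_is_number_of_sets(self, rng):
        train, test = self._sets(rng, shared_axis=True)
        _, folds, _, _ = cross_set_decode(train, test, DecodeSpec())
        assert len(folds) == 8

    def test_shared_value_axis_above_chance(self, rng):
        accs = []
        for _ in range(10):
            train, test = self._sets(rng, shared_axis=True, amp=2.0)
            acc, _, _, _ = cross_set_decode(train, test, DecodeSpec())
            accs.append(acc)
        assert np.mean(accs) > 75.0

    def test_identity_only_code_at_chance(self, rng):
        accs = []
        for _ in range(40):
            train, test = self._sets(rng, shared_axis=False)
            acc, _, _, _ = cross_set_decode(train, test, DecodeSpec())
            accs.append(acc)
        se = np.std(accs) / np.sqrt(len(accs))
        assert np.mean(accs) == pytest.approx(50.0, abs=4 * se + 1.0)

    def test_missing_set_rejected(self, rng):
        train, test = self._sets(rng, shared_axis=True)
        del test[3]
        with pytest.raises(DecodeError):
            cross_set_decode(train, test, DecodeSpec())


# ---------------------------------------------------------------------------
# searchlight geometry
# ---------------------------------------------------------------------------

class TestSphereIndices:
    def test_8mm_radius_on_2mm_lattice_has_251_voxels(self):
        mask = cube_mask(side=13)
        center = (6, 6, 6)
        assert len(sphere_indices(center, mask, 8.0)) == 251

    def test_2p1mm_radius_center_plus_face_neighbors(self):
        mask = cube_mask(side=5)
        assert len(sphere_indices((2, 2, 2), mask, 2.1)) == 7

    def test_radius_below_voxel_size_is_single_voxel(self):
        mask = cube_mask(side=5)
        assert len(sphere_indices((2, 2, 2), mask, 1.0)) == 1

    def test_truncated_at_mask_edge(self):
        mask = cube_mask(side=5)
        corner = len(sphere_indices((0, 0, 0), mask, 8.0))
        assert corner < 251

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(DecodeError):
            sphere_indices((0, 0, 0), cube_mask(5), 0.0)


class TestSearchlightMap:
    @staticmethod
    def _contrast_stat(labels):
        def stat(p):
            return abs(p[labels == 1].mean() - p[labels == -1].mean())
        return stat

    def test_blob_signal_peaks_near_blob(self, rng):
        mask = cube_mask(side=9)
        labels = np.array([1, -1] * 6)
        patterns = rng.standard_normal((12, mask.n_voxels)) * 0.1
        blob = [np.ravel_multi_index((4, 4, k), mask.shape) for k in (3, 4)]
        # mask voxel order equals C order for the full cube
        for v in blob:
            patterns[:, v] += labels * 5.0
        out = searchlight_map(patterns, mask, self._contrast_stat(labels),
                              radius_mm=4.0)
        peak = np.unravel_index(np.nanargmax(out), out.shape)
        dist_mm = np.linalg.norm((np.array(peak) - (4, 4, 3.5)) * 2.0)
        assert dist_mm <= 4.0

    def test_null_map_mean_near_zero_contrast(self, rng):
        mask = cube_mask(side=5)
        labels = np.array([1, -1] * 8)
        patterns = rng.standard_normal((16, mask.n_voxels))
        out = searchlight_map(patterns, mask, self._contrast_stat(labels),
                              radius_mm=4.0)
        assert np.nanmean(out) < 1.5          # pure noise contrast is small

    def test_map_only_depends_on_mask_voxels(self, rng):
        side = 5
        full = cube_mask(side=side)
        half_idx = full.indices[full.indices[:, 0] < 3]
        mask = RoiMask(name="half", shape=full.shape, affine=full.affine,
                       indices=half_idx)
        labels = np.array([1, -1] * 4)
        vol = rng.standard_normal((8,) + full.shape)
        patterns = np.stack([vol[e][tuple(mask.indices.T)]
                             for e in range(8)])
        out1 = searchlight_map(patterns, mask, self._contrast_stat(labels), 4.0)
        vol2 = vol.copy()
        vol2[:, 4, :, :] += 100.0            # outside the half mask
        patterns2 = np.stack([vol2[e][tuple(mask.indices.T)]
                              for e in range(8)])
        out2 = searchlight_map(patterns2, mask, self._contrast_stat(labels), 4.0)
        np.testing.assert_allclose(out1, out2)
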