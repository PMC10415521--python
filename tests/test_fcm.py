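"""Fuzzy c-means correctness and fibro-glandular segmentation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from mrbpe import FuzzyCMeans, VolumeGrid, compute_density, fit_fcm, segment_fgt
from mrbpe.fcm import DegenerateDataError, fcm_objective, select_clusters
from mrbpe.masking import BreastMask


def brute_force_objective(x, u, centers, m=2.0):
    """Independent objective evaluator: explicit double loop."""
    total = 0.0
    for i, xi in enumerate(x):
        for k, ck in enumerate(centers):
            total += u[i, k] ** m * (xi - ck) ** 2
    return total


class TestFuzzyCMeans:
    def test_two_point_masses_recover_class_means(self):
        x = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        model = fit_fcm(x, n_clusters=2)
        np.testing.assert_allclose(model.cluster_centers_, [0.0, 10.0],
                                   atol=1e-6)

    def test_membership_rows_sum_to_one(self, rng):
        model = fit_fcm(rng.normal(size=500), n_clusters=7)
        np.testing.assert_allclose(model.memberships_.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert np.all(model.memberships_ >= 0)
        assert np.all(model.memberships_ <= 1)

    def test_objective_trace_nonincreasing(self, rng):
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=300) ** 2
            model = fit_fcm(x, n_clusters=5)
            trace = np.asarray(model.objective_trace_)
            assert np.all(np.diff(trace) <= 1e-12 * trace[:-1] + 1e-15)

    def test_final_objective_beats_random_memberships(self, rng):
        """The converged fit must beat 1000 random row-normalised membership
        matrices evaluated by a brute-force objective calculator."""
        x = rng.normal(5.0, 2.0, size=20)
        model = fit_fcm(x, n_clusters=3)
        j_fit = fcm_objective(x, model.memberships_, model.cluster_centers_)
        assert j_fit == pytest.approx(
            brute_force_objective(x, model.memberships_,
                                  model.cluster_centers_), rel=1e-12)
        for _ in range(1000):
            u = rng.random((x.size, 3))
            u /= u.sum(axis=1, keepdims=True)
            w = u**2
            centers = (w * x[:, None]).sum(axis=0) / w.sum(axis=0)
            assert j_fit <= brute_force_objective(x, u, centers) + 1e-12

    def test_centroids_returned_ascending(self, rng):
        model = fit_fcm(rng.normal(size=400), n_clusters=6)
        assert np.all(np.diff(model.cluster_centers_) >= 0)

    def test_degenerate_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_fcm(np.array([1.0, 1.0, 2.0, 2.0, 2.0, 1.0]), n_clusters=3)

    def test_sample_on_centroid_gets_full_membership(self):
        x = np.array([0.0, 0.0, 5.0, 10.0, 10.0])
        model = fit_fcm(x, n_clusters=2)
        u = model.soft_predict(model.cluster_centers_)
        np.testing.assert_allclose(np.diag(u), 1.0)

    def test_sklearn_param_round_trip(self):
        est = FuzzyCMeans(n_clusters=4, m=1.7)
        params = est.get_params()
        est2 = FuzzyCMeans().set_params(**params)
        assert est2.get_params() == params

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=stn.floats(0.1, 10), b=stn.floats(-5, 5))
    def test_hard_labels_invariant_to_affine_rescaling(self, a, b):
        rng = np.random.default_rng(77)
        x = rng.normal(size=200)
        base = FuzzyCMeans(n_clusters=4).fit(x)
        scaled = FuzzyCMeans(n_clusters=4).fit(a * x + b)
        np.testing.assert_array_equal(base.predict(x),
                                      scaled.predict(a * x + b))

    def test_ties_break_toward_lower_cluster_index(self):
        est = FuzzyCMeans(n_clusters=2)
        est.cluster_centers_ = np.array([0.0, 2.0])
        assert est.predict(np.array([1.0]))[0] == 0  # equidistant -> lower


class TestClusterSelection:
    def test_lowest_and_highest_rules(self):
        c = np.arange(7.0)
        np.testing.assert_array_equal(select_clusters("lowest:3", c), [0, 1, 2])
        np.testing.assert_array_equal(select_clusters("highest:2", c), [5, 6])

    def test_gap_rule_splits_at_largest_gap(self):
        c = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
        np.testing.assert_array_equal(select_clusters("gap", c), [0, 1, 2])
        np.testing.assert_array_equal(select_clusters("gap-high", c),
                                      [3, 4, 5, 6])

    def test_explicit_set_and_errors(self):
        c = np.arange(5.0)
        np.testing.assert_array_equal(select_clusters([3, 1], c), [1, 3])
        with pytest.raises(ValueError):
            select_clusters([9], c)
        with pytest.raises(ValueError):
            select_clusters("weird", c)


def _two_tissue_volume():
    """Crafted two-tissue scene whose intensity bands put three of seven
    clusters on the dark (fibro-glandular) side."""
    rng = np.random.default_rng(8)
    shape = (20, 20, 10)
    mask = np.zeros(shape, dtype=bool)
    mask[2:18, 2:18, 1:9] = True
    n = mask.sum()
    vals = np.zeros(shape)
    # dark tissue in three narrow bands (3/7 of the mass), fat in four
    labels = rng.permutation(np.arange(n) % 7)
    band_values = np.array([78.0, 80.0, 82.0, 196.0, 200.0, 204.0, 208.0])
    vals[mask] = band_values[labels] + rng.uniform(-0.5, 0.5, size=n)
    fgt_truth = np.zeros(shape, dtype=bool)
    fgt_truth[mask] = labels < 3
    return VolumeGrid(vals, np.eye(4)), BreastMask(mask, np.eye(4), "right"), fgt_truth


class TestSegmentFgt:
    def test_default_rule_recovers_two_tissue_truth_exactly(self):
        vol, mask, fgt_truth = _two_tissue_volume()
        seg = segment_fgt(vol, mask)  # default: 7 clusters, lowest:3
        np.testing.assert_array_equal(seg.fgt_mask, fgt_truth)

    def test_gap_rule_matches_on_bimodal_data(self):
        vol, mask, fgt_truth = _two_tissue_volume()
        seg = segment_fgt(vol, mask, assignment="gap")
        np.testing.assert_array_equal(seg.fgt_mask, fgt_truth)

    def test_selecting_all_clusters_returns_whole_breast(self):
        vol, mask, _ = _two_tissue_volume()
        seg = segment_fgt(vol, mask, assignment=list(range(7)))
        np.testing.assert_array_equal(seg.fgt_mask, mask.values)

    def test_fixed_seed_is_bit_reproducible(self):
        vol, mask, _ = _two_tissue_volume()
        a = segment_fgt(vol, mask, rng_seed=3, init="quantile")
        b = segment_fgt(vol, mask, rng_seed=3, init="quantile")
        np.testing.assert_array_equal(a.fgt_mask, b.fgt_mask)

    def test_empty_mask_rejected(self):
        vol, _, _ = _two_tissue_volume()
        with pytest.raises(ValueError):
            segment_fgt(vol, BreastMask(np.zeros(vol.shape, bool), np.eye(4)))


class TestComputeDensity:
    def test_direct_arithmetic(self):
        shape = (10, 10, 10)
        breast = np.zeros(shape, dtype=bool)
        breast.ravel()[:1000] = True
        fgt = np.zeros(shape, dtype=bool)
        fgt.ravel()[:250] = True
        from mrbpe.fcm import TissueSegmentation
        seg = TissueSegmentation(fgt, np.array([0]), "left")
        dm = compute_density(seg, BreastMask(breast, np.eye(4), "left"), 1.0)
        assert dm.fgt_volume_cc == pytest.approx(0.25)
        assert dm.mrbd_pct == pytest.approx(25.0)
        assert dm.breast_volume_cc == pytest.approx(1.0)

    def test_no_fgt_gives_zero_density(self):
        breast = np.ones((5, 5, 5), dtype=bool)
        from mrbpe.fcm import TissueSegmentation
        seg = TissueSegmentation(np.zeros_like(breast), np.array([0]), "left")
        dm = compute_density(seg, BreastMask(breast, np.eye(4)), 8.0)
        assert dm.mrbd_pct == 0.0

    def test_empty_breast_mask_is_explicit_error(self):
        from mrbpe.fcm import TissueSegmentation
        seg = TissueSegmentation(np.zeros((3, 3, 3), bool), np.array([0]), "left")
        with pytest.raises(ZeroDivisionError):
            compute_density(seg, BreastMask(np.zeros((3, 3, 3), bool), np.eye(4)), 1.0)

    def test_phantom_density_recovery(self, noiseless_case):
        from mrbpe.pipeline import RunConfig, analyse_subject_volumes
        t2w, _, truth = noiseless_case
        recs = analyse_subject_volumes(t2w, None, RunConfig(), "density")
        for rec in recs:
            assert rec["mrbd_pct"] == pytest.approx(truth.true_mrbd_pct, abs=2.0)
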