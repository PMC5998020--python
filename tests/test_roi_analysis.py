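import numpy as np
import pytest

from netlyze import roi_analysis
from netlyze.io_events import LocalizationSet
from netlyze.partition import Roi
from netlyze.registry import ROI_MEASURES


def make_roi(pts, cell_id="c", roi_index=0):
    pts = np.asarray(pts, dtype=float)
    return Roi(bounds=np.array([pts.min(axis=0) - 1, pts.max(axis=0) + 1]),
               points=LocalizationSet(points=pts),
               cell_id=cell_id, roi_index=roi_index)


class TestThresholdGrid:
    def test_24_values(self):
        assert len(roi_analysis.threshold_grid()) == 24

    def test_endpoints(self):
        grid = roi_analysis.threshold_grid()
        assert grid[0] == 20.0
        assert grid[-1] == 250.0

    def test_uniform_step(self):
        assert set(np.diff(roi_analysis.threshold_grid())) == {10.0}


class TestRoiFeatures:
    def test_vector_length_768(self, triangle_points):
        fv = roi_analysis.roi_features(make_roi(triangle_points))
        assert len(fv) == 768
        assert fv.values.shape == (32, 24)
        assert len(ROI_MEASURES) == 32

    def test_triangle_degree_vs_threshold(self, triangle_points):
        fv = roi_analysis.roi_features(make_roi(triangle_points))
        row = list(fv.measure_names).index("uwAvgDeg")
        grid = fv.thresholds_nm
        for j, t in enumerate(grid):
            expected = 2.0 if t >= 50.0 else 0.0
            assert fv.values[row, j] == pytest.approx(expected), t

    def test_degenerate_roi_flagged_missing(self):
        fv = roi_analysis.roi_features(make_roi(np.zeros((1, 3))))
        assert fv.missing
        assert np.all(fv.values == 0)
        assert np.all(np.isfinite(fv.values))

    def test_deterministic(self, rng):
        pts = rng.uniform(0, 600, size=(40, 3))
        a = roi_analysis.roi_features(make_roi(pts))
        b = roi_analysis.roi_features(make_roi(pts))
        np.testing.assert_array_equal(a.values, b.values)

    def test_all_entries_finite(self, rng):
        pts = rng.uniform(0, 400, size=(30, 3))
        fv = roi_analysis.roi_features(make_roi(pts))
        assert np.all(np.isfinite(fv.values))


class TestMwTest:
    def test_identical_samples(self):
        assert roi_analysis.mw_test([1, 2, 3], [1, 2, 3]) == pytest.approx(
            1.0, abs=0.1)

    def test_all_constant_p_one(self):
        assert roi_analysis.mw_test([5, 5, 5], [5, 5]) == 1.0

    def test_exact_small_sample_value(self):
        # U = 0 at n = m = 3: exact two-sided p = 2 * 1/20 = 0.1
        p = roi_analysis.mw_test([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_symmetry(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(1.0, size=12)
        assert roi_analysis.mw_test(a, b) == pytest.approx(
            roi_analysis.mw_test(b, a))

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            roi_analysis.mw_test([], [1.0])


class TestAggregatePvalues:
    def test_l2_of_three(self):
        p = np.full((32, 24), 0.01)
        sig = roi_analysis.aggregate_pvalues([p, p, p])
        assert sig.p_combined[0, 0] == pytest.approx(np.sqrt(3) * 0.01)

    def test_large_p_dominates(self):
        small = np.full((2, 2), 1e-9)
        big = np.ones((2, 2))
        sig = roi_analysis.aggregate_pvalues([small, small, big])
        assert np.all(sig.p_combined >= 1.0 - 1e-12)
        assert not sig.significant_mask.any()

    def test_single_experiment_identity(self):
        p = np.random.default_rng(0).uniform(size=(32, 24))
        sig = roi_analysis.aggregate_pvalues([p])
        np.testing.assert_allclose(sig.p_combined, p)

    def test_bonferroni_threshold(self):
        p = np.full((32, 24), 1.0)
        p[3, 5] = 1e-6
        sig = roi_analysis.aggregate_pvalues([p])
        assert sig.n_comparisons == 768
        assert sig.significant_mask[3, 5]
        assert sig.significant_mask.sum() == 1

    def test_monotone_in_each_entry(self, rng):
        p1 = rng.uniform(size=(4, 4))
        p2 = rng.uniform(size=(4, 4))
        base = roi_analysis.aggregate_pvalues([p1, p2]).p_combined
        bumped = roi_analysis.aggregate_pvalues(
            [np.minimum(p1 * 1.5, 1.0), p2]).p_combined
        assert np.all(bumped >= base - 1e-15)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            roi_analysis.aggregate_pvalues([np.ones((2, 2)),
                                            np.ones((3, 2))])


def _two_population_features(rng, n_cells=3, rois_per_cell=4, n_pts=120):
    """Clustered vs uniform ROIs: strongly separable populations."""
    fvs, labels = [], []
    for pop, clustered in (("A", True), ("B", False)):
        for c in range(n_cells):
            for r in range(rois_per_cell):
                if clustered:
                    centers = rng.uniform(200, 2800, size=(4, 3))
                    centers[:, 2] = rng.uniform(200, 800, size=4)
                    pts = np.vstack([
                        ctr + rng.normal(0, 30, size=(n_pts // 4, 3))
                        for ctr in centers])
                else:
                    pts = rng.uniform(0, [3000, 3000, 1000],
                                      size=(n_pts, 3))
                fv = roi_analysis.roi_features(
                    make_roi(pts, cell_id=f"{pop}{c}", roi_index=r))
                fvs.append(fv)
                labels.append(pop)
    return roi_analysis.features_frame(fvs), np.array(labels)


@pytest.fixture(scope="module")
def separable_features():
    rng = np.random.default_rng(99)
    return _two_population_features(rng)


class TestRfValidate:
    def test_separable_populations_perfect_cell_accuracy(
            self, separable_features):
        df, labels = separable_features
        res = roi_analysis.rf_validate(df, labels, thresholds=[80.0],
                                       seed=0, n_estimators=200)
        assert res.loc[80.0, "cell_accuracy"] == 1.0
        assert res.loc[80.0, "roi_accuracy"] >= 0.9

    def test_permuted_labels_near_chance(self, separable_features):
        df, labels = separable_features
        rng = np.random.default_rng(5)
        accs = []
        for _ in range(8):
            # permute at the cell level (labels constant within a cell)
            cells = df["cell_id"].unique()
            perm = dict(zip(cells, rng.permutation(
                [labels[df["cell_id"] == c][0] for c in cells])))
            permuted = df["cell_id"].map(perm).to_numpy()
            res = roi_analysis.rf_validate(df, permuted, thresholds=[80.0],
                                           seed=1, n_estimators=100)
            accs.append(res.loc[80.0, "cell_accuracy"])
        assert 0.25 <= np.mean(accs) <= 0.75

    def test_majority_vote(self):
        # 20/36 ROI votes for A predicts the cell as A: implicit in the
        # vote rule; spot-check via a constructed frame
        rng = np.random.default_rng(2)
        df, labels = _two_population_features(rng, n_cells=2,
                                              rois_per_cell=3, n_pts=60)
        res = roi_analysis.rf_validate(df, labels, thresholds=[80.0], seed=0,
                                       n_estimators=50)
        assert set(res.columns) == {"roi_accuracy", "cell_accuracy"}

    def test_degree_significance_scale(self):
        # populations that differ only at the 150 nm dimer scale: degree
        # is significant near T ~ 150 and carries no signal at T << 150
        rng = np.random.default_rng(17)
        fvs, labels = [], []
        for pop in ("dimers", "singles"):
            for c in range(3):
                for r in range(4):
                    if pop == "dimers":
                        anchors = rng.uniform(200, 2800, size=(40, 3))
                        offs = rng.normal(size=(40, 3))
                        offs /= np.linalg.norm(offs, axis=1, keepdims=True)
                        pts = np.vstack([anchors, anchors + 150.0 * offs])
                    else:
                        pts = rng.uniform(200, 2800, size=(80, 3))
                    fvs.append(roi_analysis.roi_features(
                        make_roi(pts, cell_id=f"{pop}{c}", roi_index=r)))
                    labels.append(pop)
        df = roi_analysis.features_frame(fvs)
        labels = np.array(labels)
        pmat = roi_analysis.mw_map(df[labels == "dimers"],
                                   df[labels == "singles"])
        row = list(ROI_MEASURES).index("uwAvgDeg")
        grid = list(roi_analysis.threshold_grid())
        assert pmat[row, grid.index(150.0)] < 1e-3
        assert pmat[row, grid.index(20.0)] > 0.05
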