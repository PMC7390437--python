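import numpy as np
import pytest

from fibray import (
    AngularGrid,
    ComplexityParams,
    Orientation,
    OrientationField,
    PhantomSpec,
    angular_errors,
    evaluate_field,
    generate_phantom,
    match_field_to_truth,
    op_count_raycast,
    op_count_tensor,
    orientation_histograms,
    polar_heatmap,
    predict_window_px,
    to_odd,
    unify_windows,
    window_radius_factor,
    window_sweep,
)
from fibray.evaluate import table1_experiment


class TestAngularErrors:
    @pytest.mark.parametrize(
        "est,truth,expected",
        [
            ((30, 50), (30, 50), (0, 0)),
            ((-88, 45), (88, 45), (4, 0)),   # period-180 wrap across the boundary
            ((30, 50), (40, 70), (10, 20)),
        ],
    )
    def test_examples(self, est, truth, expected):
        got = angular_errors(Orientation(*est), Orientation(*truth))
        assert got == pytest.approx(expected)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = Orientation(rng.uniform(-90, 90), rng.uniform(0, 90))
            b = Orientation(rng.uniform(-90, 90), rng.uniform(0, 90))
            ea = angular_errors(a, b)
            eb = angular_errors(b, a)
            assert ea == pytest.approx(eb)
            assert 0 <= ea[0] <= 90 and 0 <= ea[1] <= 90


class TestEvaluateField:
    def _field(self, angles, truth):
        n = len(angles)
        return OrientationField(np.zeros((n, 3), dtype=int), np.asarray(angles, float),
                                truth=np.asarray(truth, float))

    def test_exact_sites_zero_mean(self):
        f = self._field([[10, 20], [30, 40]], [[10, 20], [30, 40]])
        r = evaluate_field(f)
        assert r.mean_azimuth == 0 and r.mean_elevation == 0

    def test_hand_built_mean(self):
        f = self._field([[0, 0], [10, 0], [20, 0]], [[0, 0], [0, 0], [0, 0]])
        r = evaluate_field(f)
        assert r.mean_azimuth == pytest.approx(10.0)
        assert r.sum_azimuth == pytest.approx(30.0)
        assert r.n_sites == 3

    def test_unmatched_sites_excluded_but_counted(self):
        f = self._field([[0, 0], [45, 45]], [[0, 0], [np.nan, np.nan]])
        r = evaluate_field(f)
        assert r.n_sites == 1 and r.n_excluded == 1

    def test_missing_truth_rejected(self):
        f = OrientationField(np.zeros((2, 3), dtype=int), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            evaluate_field(f)


class TestMatching:
    def test_sites_match_nearest_fiber_within_radius(self, small_phantom):
        vol, fibers = small_phantom
        coords = fibers[0].axis_voxels[:5]
        angles = np.tile(fibers[0].orientation.as_tuple(), (5, 1))
        f = OrientationField(coords, angles)
        matched, n_un = match_field_to_truth(f, fibers)
        assert n_un == 0
        r = evaluate_field(matched)
        assert r.mean_azimuth == pytest.approx(0.0) and r.mean_elevation == pytest.approx(0.0)

    def test_far_site_unmatched(self, small_phantom):
        vol, fibers = small_phantom
        from scipy import ndimage

        edt = ndimage.distance_transform_edt(vol.data == 0)
        far = np.unravel_index(np.argmax(edt), edt.shape)
        f = OrientationField(np.array([far]), np.array([[0.0, 0.0]]))
        _, n_un = match_field_to_truth(f, fibers)
        assert n_un == 1


class TestPolarHeatmap:
    def test_single_cell_zero(self):
        f = OrientationField(np.zeros((4, 3), int), np.zeros((4, 2)), truth=np.zeros((4, 2)))
        hm = polar_heatmap(f)
        nonempty = np.isfinite(hm.values)
        assert nonempty.sum() == 1
        assert hm.values[nonempty][0] == 0.0

    def test_two_bins_hand_computed(self):
        angles = np.array([[2.0, 2.0], [4.0, 2.0], [-30.0, 50.0]])
        truth = np.array([[0.0, 0.0], [0.0, 0.0], [-32.0, 47.0]])
        f = OrientationField(np.zeros((3, 3), int), angles, truth=truth)
        hm = polar_heatmap(f)
        # bin (az 0..5, el 0..5): mean az err (2+4)/2 = 3, mean el err 2 -> 5
        assert hm.values[0, 18] == pytest.approx(5.0)
        # bin (az -35..-30, el 45..50): 2 + 3 = 5
        assert hm.values[9, 11] == pytest.approx(5.0)
        assert np.isfinite(hm.values).sum() == 2

    def test_bin_edges_are_multiples_of_5(self):
        f = OrientationField(np.zeros((1, 3), int), np.zeros((1, 2)), truth=np.zeros((1, 2)))
        hm = polar_heatmap(f)
        assert (np.mod(hm.azimuth_edges, 5) == 0).all()
        assert (np.mod(hm.elevation_edges, 5) == 0).all()


class TestHistograms:
    def test_all_pole_single_bin(self):
        f = OrientationField(np.zeros((7, 3), int), np.zeros((7, 2)))
        az, el = orientation_histograms(f)
        assert az.sum() == 7 and el.sum() == 7
        assert az.max() == 7 and el.max() == 7

    def test_counts_conserved(self):
        rng = np.random.default_rng(1)
        n = 500
        angles = np.column_stack([rng.uniform(-90, 90, n), rng.uniform(0, 90, n)])
        f = OrientationField(np.zeros((n, 3), int), angles)
        az, el = orientation_histograms(f)
        assert az.sum() == n and el.sum() == n

    def test_uniform_angles_nearly_flat(self):
        rng = np.random.default_rng(2)
        n = 10_000
        angles = np.column_stack([rng.uniform(-90, 90, n), rng.uniform(0, 90, n)])
        f = OrientationField(np.zeros((n, 3), int), angles)
        az, el = orientation_histograms(f)
        assert az.max() / az.min() < 2
        assert el.max() / el.min() < 2


class TestOperationCounts:
    def test_raycast_printed_formula(self):
        p = ComplexityParams(n_theta=180, n_phi=90, n_w=33)
        assert op_count_raycast(p) == pytest.approx(180 * 90 * np.sqrt(2 * 33**2))
        assert op_count_raycast(p) == pytest.approx(7.56e5, rel=0.01)

    def test_raycast_unit_case_sqrt2(self):
        assert op_count_raycast(ComplexityParams(1, 1, 1, 1)) == pytest.approx(np.sqrt(2))

    def test_raycast_linear_in_angles(self):
        p1 = ComplexityParams(n_theta=180, n_phi=90, n_w=33)
        p2 = ComplexityParams(n_theta=360, n_phi=90, n_w=33)
        assert op_count_raycast(p2) == pytest.approx(2 * op_count_raycast(p1))

    def test_tensor_printed_value(self):
        assert op_count_tensor(ComplexityParams(n_w=33, n_d=3)) == pytest.approx(107_868)

    def test_tensor_unit_case(self):
        assert op_count_tensor(ComplexityParams(1, 1, 1, 1)) == pytest.approx(10 / 3 + 1 + 7)

    def test_tensor_monotone_in_window(self):
        counts = [op_count_tensor(ComplexityParams(n_w=w)) for w in range(3, 40, 2)]
        assert all(b > a for a, b in zip(counts, counts[1:]))


class TestWindowChain:
    def test_factor_and_prediction(self):
        factor = window_radius_factor(33, 9.5)
        assert factor == pytest.approx(1.73, abs=0.01)
        assert predict_window_px(33.0, 1.8, 1.73) == 32
        assert unify_windows([34, 32]) == 33

    def test_to_odd(self):
        assert to_odd(32) == 33
        assert to_odd(33) == 33


class TestWindowSweep:
    def test_single_window_series(self, small_phantom, coarse_grid):
        vol, fibers = small_phantom
        res = window_sweep(vol, fibers, "raycast", [15], grid=coarse_grid)
        assert len(res["reports"]) == 1
        assert res["best_window"] == 15

    def test_even_windows_mapped_to_next_odd(self, small_phantom, coarse_grid):
        vol, fibers = small_phantom
        res = window_sweep(vol, fibers, "raycast", [8, 12], grid=coarse_grid)
        assert res["windows_odd"] == [9, 13]
        assert all(r.config["window"] % 2 == 1 for r in res["reports"])

    def test_unsorted_windows_rejected(self, small_phantom):
        vol, fibers = small_phantom
        with pytest.raises(ValueError):
            window_sweep(vol, fibers, "raycast", [15, 9])

    def test_error_shrinks_then_flattens_with_window(self, coarse_grid):
        """Summed error falls as the window grows past the fiber diameter and
        then stays low (single straight fiber)."""
        spec = PhantomSpec(volume_size=72, n_fibers=1, radius_range=(3, 3), gap_range=(3, 3),
                           elevation_range=(30, 60), seed=4)
        vol, fibers = generate_phantom(spec)
        res = window_sweep(vol, fibers, "raycast", [5, 9, 17, 25, 33], grid=coarse_grid)
        summed = [r.mean_azimuth + r.mean_elevation for r in res["reports"]]
        assert summed[-1] <= summed[0]
        assert max(summed[-2:]) <= max(summed[:2])


class TestTable1Experiment:
    def test_shape_and_difference_identity(self, coarse_grid):
        spec = PhantomSpec(volume_size=48, n_fibers=2, radius_range=(3, 4), gap_range=(3, 4), seed=6)
        res = table1_experiment([0.0], spec, window=9, grid=coarse_grid, seeds=(6,))
        table = res["table"]
        assert len(table) == 1
        cols = ["raycast_azimuth", "raycast_elevation", "tensor_azimuth",
                "tensor_elevation", "diff_azimuth", "diff_elevation"]
        assert all(c in table.columns for c in cols)
        assert table["diff_azimuth"].iloc[0] == pytest.approx(
            table["tensor_azimuth"].iloc[0] - table["raycast_azimuth"].iloc[0]
        )
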